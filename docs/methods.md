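# Methods

`steeproot` reimplements, as a tested library plus narrative analysis
scripts, the computational chain of a forward-genetics study of root
growth angle in a cereal: a recessive mutant with steeper seminal roots
is mapped by bulked-segregant analysis, the causal gene is nominated by
filtering a panel of independently mutagenized lines and intersecting
two independent alleles, natural coding variation is organised into a
haplotype network and associated with root angle, and two bespoke
phenotype quantifiers (3D polyline root angle, AFM force-curve
stiffness) are reproduced. Every stage runs on synthetic data with
known ground truth, so recovery can be asserted, not assumed.

## Bulked-segregant delta-theta mapping

**Model.** An F2 of mutant × wild-type segregates a single recessive
locus. At a bi-allelic array marker, the normalized allele signal theta
of a DNA pool approximates the mutant-allele fraction of the pool. For
the steep-phenotype bulk (all `aa` at the causal locus) a fully linked
marker sits at θ → 1; the wild-type bulk is a 1 `AA` : 2 `Aa` mixture,
θ → 1/3; unlinked markers give θ ≈ 1/2 in both. The mapping statistic
is Δθ = (θ_wt − θ_mut)², which peaks at (1 − 1/3)² ≈ 0.444 over the
causal locus and is ≈ 0 elsewhere. At recombination fraction r from the
causal locus the expected bulk frequencies are 1 − r (steep) and
(1 + r)/3 (wild-type), so E[Δθ] ≈ ((2 − 4r)/3)² decays smoothly with
distance — the signal is a broad hill, not a spike.

**Interval calling.** The Δθ profile is smoothed per chromosome with a
centered moving average (default window 5 markers; edges use shrunk
windows), and the called interval is the maximal run of contiguous
markers, containing the genome-wide peak, whose smoothed Δθ strictly
exceeds the genome-wide quantile threshold (default 0.90). Peak ties
resolve to the smallest chromosome in natural order, then position, so
output is deterministic. A perfectly flat profile returns a no-linkage
sentinel. Two numerical notes: run membership is strictly
greater-than, so on a profile that is mostly zero a threshold landing
exactly on zero does not absorb the whole genome; and because the run
must contain the peak, raising the quantile can only shrink the
interval (a property the tests assert).

**Why the 0.90 default.** The interval should cover the *linkage
region*, not just the noisy argmax. With 15-plant bulks the binomial
sampling noise of θ is large relative to the Δθ gradient near the
peak, so the argmax wanders tens of Mb around the causal position
(publications from such designs report intervals of ~100 Mb for the
same reason). A power analysis at the default design (75 plants,
15-plant bulks, θ noise SD 0.05, 0.5 cM/Mb, 1 Mb marker spacing, 100
seeded runs) gives: quantile 0.99 → ~4 Mb intervals containing the
causal position in ~28% of runs; quantile 0.90 → ~60 Mb intervals
containing it in ≥ 98% while still occupying less than a tenth of the
genome. 0.90 is therefore the default; both knobs are exposed.

**Segregation test.** χ² goodness-of-fit of phenotype class counts to a
stated ratio (e.g. 3:1), χ² = Σ(O−E)²/E with df = classes − 1, through
`scipy.stats.chisquare`.

## Panel filtering and allelic intersection

Each mutagenized line carries private homozygous induced SNVs. At such
a site the non-reference read fraction DV/DP is ≈ 1 in the carrier and
≈ the base error rate elsewhere. A variant is retained for a focal line
iff its quality strictly exceeds 40 (PHRED), every panel sample has
depth ≥ 5 (depth 0 makes the ratio undefined; the site is untestable
and rejected with a reason code rather than raising), DV/DP ≥ 0.8 in
the focal sample and ≤ 0.2 in every other sample. Depth and ratio
bounds are inclusive ("minimum"/"maximum"); the quality bound is strict
(the wording is "quality > 40"). The gates apply per tested sample.

Retained variants are classified against single-transcript gene models
on either strand: CDS SNVs are translated with the standard genetic
code on the coding strand (missense / synonymous / stop gained, with
protein notation like `G395E`); intronic positions within 2 bp of the
intron's transcription-order 3′ end are splice-acceptor, within 2 bp of
its 5′ end splice-donor; exonic non-CDS is UTR; everything else in the
gene is intronic, outside it intergenic. Only SNVs are modeled; one
transcript per gene.

A broken splice acceptor re-routed to a downstream cryptic acceptor
deletes `shift` coding nucleotides; when `shift` is a multiple of 3 the
protein loses `shift/3` residues starting at the exon-junction codon
(e.g. a 27-nt shift at codon 129 deletes residues 129–137 in frame).
The cryptic acceptor is supplied, not scanned: de novo splice-site
prediction is out of scope and was experimentally resolved in the
motivating study.

Candidate nomination intersects, across ≥ 2 independent mutants, the
genes inside the mapped interval that carry a coding-impact variant
(missense, stop gained, splice donor/acceptor) in every mutant, sorted
by position.

## Haplotype network and phenotype contrast

Equal-length pre-aligned CDS sequences are collapsed by identity. `N`
is missing data: accessions above the missing fraction (default 10%)
are dropped with a reason; an N-containing sequence joins an N-free
haplotype only when compatible with exactly one of them, otherwise it
forms its own haplotype keyed by its literal sequence. This rule is
deliberately conservative because greedy N-matching depends on input
order; the chosen rule makes the partition invariant to row
permutations (asserted by a test). IDs are Roman numerals by
descending count, ties by first occurrence.

The network is a minimum spanning network over pairwise Hamming
distances (N excluded pairwise): an edge of weight w is kept iff its
endpoints are disconnected in the graph of all strictly lighter kept
edges — exactly the set of edges belonging to at least one minimum
spanning tree, so equally parsimonious alternatives are retained. This
is *not* a statistical-parsimony (TCS-style) network: no connection
probability is computed; an optional integer connection limit drops
heavier edges and may disconnect components. Tests validate the MSN
against exhaustive MST enumeration on small instances rather than
against any published network topology.

Group phenotype contrasts report median, SD and n per group and a
two-sided Mann–Whitney U p-value (`scipy.stats.mannwhitneyu`); the
test choice follows the skew implied by median ± SD reporting, since
the motivating analysis does not name its test. Identical constant
groups return p = 1 instead of failing the tie correction.

## Root geometry

A root polyline is an ordered 3D point list, first point uppermost
(z up, soil surface z = 0). Its vertical angle is the angle between the
downward plumb vector and the unit vector from the uppermost to the
terminal point: 0° is plumb-steep, 90° horizontal. Directions with an
upward component (possible only within the uppermost-point tolerance)
are folded through the horizontal plane and flagged, keeping the range
[0, 90]. The uppermost→terminal convention is one documented choice
among several the source description permits; it is robust to waviness
because intermediate points do not enter. The angle is invariant to
rotation about the vertical axis and to uniform scaling (asserted to
1e-9°).

Measurement stops at the pot wall: the prefix of points strictly
inside radius − ε is kept (ε default 0.5 mm, the contact resolution of
~150 µm voxel CT traces), the first contacting point and everything
after it dropped. Truncation is idempotent; a one-point remainder makes
the downstream angle computation raise "degenerate polyline". Lateral
roots are measured with the same plumb-vector rule relative to their
insertion point.

Gravitropic kinetics use time-indexed 2D midlines with gravity along
−y. The tip angle is the angle between gravity and the total
least-squares direction (SVD) of the terminal quarter of arc length
(configurable), oriented base→tip; the bending rate is the OLS slope of
tip angle against time, optionally within a window after the stimulus.

## AFM stiffness

An approach curve is force (pN) against displacement (nm), flat before
tip–sample contact and rising after. The contact point is the first
sample whose force exceeds baseline mean + 3 SD (baseline = first 30%
of approach points) for at least 5 consecutive samples; the sustained
run rejects isolated spikes, and a curve that never crosses is excluded
with a "no contact" reason. Apparent stiffness is the OLS slope of
force vs indentation over (contact, contact + 200 nm]; the depth
default keeps the fit inside the small-indentation regime where a
linear force model is adequate, and the free intercept makes the slope
exactly invariant to constant force offsets. No contact-mechanics model
(Hertz/Sneddon) is applied — the estimate is an apparent stiffness in
pN/nm, as in the motivating measurements.

Group comparisons report means ± SD, percent change
100·(mean_ref − mean_alt)/mean_ref, and a two-sided Wilcoxon rank-sum
p-value; "rank-sum" rather than signed-rank because the groups are
unpaired. Tissue stratification maps each 3×3 grid cell to stele or
cortex and reports per-stratum comparisons plus the pooled one, with
stratum sizes summing to the pooled n by construction.

## Synthetic-data generator

The generator emulates the study's inputs with known truth. All
randomness flows from one integer seed through named, CRC-keyed child
generators (`SimConfig.rng("panel")`, …); identical configs give
byte-identical outputs, and no global RNG state is touched.

Defaults mirror the study design where stated: F2 of 75 plants,
15-plant bulks prepared in duplicate (replicate bulk measurements are
averaged before Δθ), sequencing depth ~24× (DP ~ Poisson(24), DV ~
Binomial(DP, f) with f = 1 − e for the carrier and f = e = 0.01
otherwise), wild-type stiffness 7.6 pN/nm, contact at 500 nm, baseline
noise 0.5 pN. Where the study states no value, a choice was made once:
background mutation density 3.0/Mb (chemical-mutagenesis scale),
transition fraction 0.9 (alkylating agents predominantly induce
G:C→A:T), a uniform 0.5 cM/Mb genetic map (Haldane model,
r = (1 − e^(−2d))/2), genome of 7 × 100 Mb with one array marker per
Mb, and θ noise SD 0.05. F2 draws with fewer steep segregants than the
bulk size are redrawn with a derived seed — the bench experiment
likewise proceeds only once enough segregants of each class exist (the
motivating study had 16 of 75).

What the generator does *not* emulate: real Illumina theta is an
arctan-transformed intensity ratio, here θ is linear in allele dosage
with additive Gaussian noise; recombination is uniform, with no
pericentromeric suppression; sequencing error is a flat per-base rate
with no context effects; force baselines have no drift or adhesion;
root polylines have stationary angular waviness and never revert
upward. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated models, not robustness to every artifact
of real instruments.

Problem sizes in the tests and scripts (2 × 1 Mb genomes for
sequence-level stages, 100-seed power loops, 300-curve recovery runs)
are desk-scale choices that keep the full suite fast while leaving
every statistical conclusion comfortably away from its acceptance
margin.

## Numerical and degenerate-input conventions

- θ validated to [0, 1] with the offending marker named; Δθ is exact
  squared difference, symmetric under bulk swap.
- Flat Δθ profile → no-linkage sentinel, never a fabricated interval.
- DP = 0 → ratio undefined → variant rejected with reason, no division.
- Coincident polyline endpoints and one-point wall-truncation stubs
  raise "degenerate polyline".
- Identical constant groups in rank tests → p = 1, U = n₁n₂/2.
- Reference-mismatch between a variant's stated ref base and the genome
  raises immediately rather than silently mis-translating.

## Known limitations

Single transcript per gene; SNVs only (no indels); no raw intensity
normalization for array data; no TCS connection probability; no
Hertzian contact mechanics; splice consequences assume a supplied
cryptic acceptor. These bounds match the scope of the pipeline the
package reproduces.
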