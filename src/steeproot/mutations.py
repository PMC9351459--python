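"""Candidate-mutation isolation from a multi-mutant variant panel.

Independently mutagenized lines share the genetic background but carry
private induced SNVs. A variant private and homozygous in one (focal)
line shows a non-reference read fraction DV/DP near 1 in that line and
near the sequencing error rate everywhere else; the panel filter turns
this into a hard predicate. Retained variants are then classified
against gene models (missense / synonymous / stop gained / splice site)
and candidate genes are nominated by intersecting the coding-impact
gene sets of independent allelic mutants inside the mapped interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

CODING_IMPACT = frozenset({"missense", "stop_gained", "splice_acceptor", "splice_donor"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the unique-mutation panel filter.

    Depth and ratio bounds are inclusive; the quality bound is strict
    (quality must exceed ``min_qual``).
    """

    min_dp: int = 5
    min_qual: float = 40.0
    min_focal_ratio: float = 0.8
    max_other_ratio: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_other_ratio < self.min_focal_ratio <= 1.0):
            raise ValueError(
                "require 0 <= max_other_ratio < min_focal_ratio <= 1, got "
                f"{self.max_other_ratio} / {self.min_focal_ratio}"
            )
        if self.min_dp < 1:
            raise ValueError("min_dp must be >= 1")


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNV with per-sample (DP, DV) depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    samples: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for name, (dp, dv) in self.samples.items():
            if not (0 <= dv <= dp):
                raise ValueError(f"sample {name}: require 0 <= DV <= DP, got DV={dv} DP={dp}")


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model: ordered exons and CDS on a strand.

    Intervals are 1-based closed, stored in genomic (ascending) order;
    transcription order is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 - e1 > 1
        )

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        """CDS sequence in transcription order (reverse-complemented on -)."""
        seq = genome[self.chrom]
        parts = [seq[s - 1 : e] for s, e in self.cds]
        if self.strand == "-":
            return _revcomp("".join(parts))
        return "".join(parts)

    def cds_index(self, pos: int) -> int | None:
        """0-based position of a genomic coordinate within the spliced CDS."""
        offset = 0
        intervals = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        for s, e in intervals:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None


@dataclass(frozen=True)
class EffectCall:
    variant: VariantRecord
    gene_id: str | None
    effect: str  # missense | synonymous | stop_gained | splice_acceptor | splice_donor | intronic | intergenic | UTR
    protein_change: str | None = None
    codon_pos: int | None = None


@dataclass(frozen=True)
class SpliceConsequence:
    """Protein consequence of re-routing splicing to a downstream cryptic acceptor."""

    deletion_nt: int
    in_frame: bool
    deleted_residues: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.deletion_nt < 0:
            raise ValueError("deletion_nt must be >= 0")


# ---------------------------------------------------------------------------
# panel filter
# ---------------------------------------------------------------------------

def filter_unique_mutations(
    panel: pd.DataFrame,
    focal_samples: Sequence[str],
    config: FilterConfig = FilterConfig(),
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain variants private to the focal line(s) of a mutant panel.

    A variant is retained iff its quality exceeds ``min_qual`` and, in
    every panel sample, DP >= ``min_dp`` (DP = 0 makes the ratio
    undefined and the site untestable, hence rejected), DV/DP >=
    ``min_focal_ratio`` in every focal sample, and DV/DP <=
    ``max_other_ratio`` in every other sample.

    Parameters
    ----------
    panel
        One row per variant with columns ``chrom, pos, ref, alt, qual``
        plus per-sample ``DP_<name>`` and ``DV_<name>`` columns.
    focal_samples
        Sample name(s) in which the mutation must be (near-)homozygous.
    samples
        Panel sample names; inferred from ``DP_*`` columns if omitted.

    Returns
    -------
    (retained, rejected)
        ``retained`` is the passing subset of ``panel``; ``rejected``
        carries a ``reject_reason`` column with the first failing gate.
    """
    if samples is None:
        samples = [c[3:] for c in panel.columns if c.startswith("DP_")]
    focal = list(focal_samples)
    if not set(focal) <= set(samples):
        raise ValueError(f"focal samples {focal} not all in panel samples")
    others = [s for s in samples if s not in focal]
    if not others:
        raise ValueError("need at least one non-focal sample")

    n = len(panel)
    reason = np.full(n, "", dtype=object)
    ok = np.ones(n, dtype=bool)

    qual_ok = panel["qual"].to_numpy(float) > config.min_qual
    reason[~qual_ok & ok] = "low_qual"
    ok &= qual_ok

    for s in samples:
        dp = panel[f"DP_{s}"].to_numpy(float)
        dv = panel[f"DV_{s}"].to_numpy(float)
        undef = dp == 0
        reason[undef & ok] = f"ratio_undefined:{s}"
        ok &= ~undef
        shallow = dp < config.min_dp
        reason[shallow & ok] = f"low_depth:{s}"
        ok &= ~shallow
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dp > 0, dv / np.where(dp > 0, dp, 1), np.nan)
        if s in focal:
            bad = ~(ratio >= config.min_focal_ratio)
            tag = f"focal_ratio:{s}"
        else:
            bad = ~(ratio <= config.max_other_ratio)
            tag = f"other_ratio:{s}"
        reason[bad & ok] = tag
        ok &= ~bad

    retained = panel.loc[ok].copy()
    rejected = panel.loc[~ok].copy()
    rejected["reject_reason"] = reason[~ok]
    return retained, rejected


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

_SPLICE_WINDOW = 2  # bases of intron flanking each junction


def classify_effect(
    variant: VariantRecord,
    gene: GeneModel,
    genome: Mapping[str, str],
) -> EffectCall:
    """Classify an SNV against a single gene model.

    CDS variants are translated with the standard genetic code on the
    coding strand. Intronic positions within 2 bp of the intron's 3'
    end (transcription order) are splice-acceptor sites; within 2 bp of
    its 5' end, splice-donor sites. Exonic non-CDS positions are UTR.
    """
    pos = variant.pos
    if variant.chrom != gene.chrom or not (gene.start <= pos <= gene.end):
        return EffectCall(variant, None, "intergenic")

    for s, e in gene.introns:
        if s <= pos <= e:
            # genomic-left end of the intron is the 5' (donor) side on +, 3' (acceptor) on -
            near_left = pos - s < _SPLICE_WINDOW
            near_right = e - pos < _SPLICE_WINDOW
            if gene.strand == "+":
                if near_left:
                    return EffectCall(variant, gene.gene_id, "splice_donor")
                if near_right:
                    return EffectCall(variant, gene.gene_id, "splice_acceptor")
            else:
                if near_left:
                    return EffectCall(variant, gene.gene_id, "splice_acceptor")
                if near_right:
                    return EffectCall(variant, gene.gene_id, "splice_donor")
            return EffectCall(variant, gene.gene_id, "intronic")

    idx = gene.cds_index(pos)
    if idx is None:
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        return EffectCall(variant, gene.gene_id, "UTR" if in_exon else "intronic")

    cds = gene.spliced_cds(genome)
    ref_base = variant.ref if gene.strand == "+" else _revcomp(variant.ref)
    alt_base = variant.alt if gene.strand == "+" else _revcomp(variant.alt)
    if cds[idx] != ref_base:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{pos} — genome has {cds[idx]} "
            f"on the coding strand, variant ref is {ref_base}"
        )
    codon_i = idx // 3
    within = idx % 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    else:
        effect = "missense"
    return EffectCall(variant, gene.gene_id, effect, change, codon_i + 1)


def classify_effects(
    variants: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[EffectCall]:
    """Classify each variant against the gene (if any) containing it."""
    calls = []
    for v in variants:
        hit = None
        for g in genes:
            if g.chrom == v.chrom and g.start <= v.pos <= g.end:
                hit = g
                break
        if hit is None:
            calls.append(EffectCall(v, None, "intergenic"))
        else:
            calls.append(classify_effect(v, hit, genome))
    return calls


def splice_consequence(acceptor_shift_nt: int, junction_codon: int) -> SpliceConsequence:
    """Consequence of an acceptor-site SNV re-routed to a cryptic acceptor.

    ``acceptor_shift_nt`` is the distance from the broken canonical
    acceptor to the cryptic acceptor actually used, i.e. the number of
    coding nucleotides lost from the mature transcript. When that loss
    is a multiple of 3 the protein simply lacks ``shift/3`` residues
    starting at the exon-junction codon; otherwise the downstream frame
    is shifted.
    """
    if acceptor_shift_nt < 0:
        raise ValueError("acceptor shift must be >= 0")
    if junction_codon < 1:
        raise ValueError("junction codon must be >= 1")
    in_frame = acceptor_shift_nt % 3 == 0
    if in_frame and acceptor_shift_nt > 0:
        n_res = acceptor_shift_nt // 3
        residues = (junction_codon, junction_codon + n_res - 1)
    else:
        residues = None
    return SpliceConsequence(acceptor_shift_nt, in_frame, residues)


# ---------------------------------------------------------------------------
# allelic intersection
# ---------------------------------------------------------------------------

def intersect_allelic_candidates(
    calls_by_mutant: Mapping[str, Sequence[EffectCall]],
    interval,
) -> list[str]:
    """Genes in the mapped interval hit by a coding-impact variant in every mutant.

    ``interval`` needs ``chrom``, ``start`` and ``end`` attributes (a
    :class:`steeproot.bsa.LinkageInterval`); ``None`` yields ``[]``.
    Result is sorted by genomic position of the earliest supporting
    variant.
    """
    if len(calls_by_mutant) < 2:
        raise ValueError("allelic intersection needs >= 2 mutants")
    if interval is None:
        return []

    def in_interval(v: VariantRecord) -> bool:
        return v.chrom == interval.chrom and interval.start <= v.pos <= interval.end

    gene_sets: list[set[str]] = []
    min_pos: dict[str, int] = {}
    for calls in calls_by_mutant.values():
        hit = set()
        for c in calls:
            if c.gene_id and c.effect in CODING_IMPACT and in_interval(c.variant):
                hit.add(c.gene_id)
                min_pos[c.gene_id] = min(min_pos.get(c.gene_id, c.variant.pos), c.variant.pos)
        gene_sets.append(hit)
    shared = set.intersection(*gene_sets)
    return sorted(shared, key=lambda g: (min_pos[g], g))


def substitution_offset(pos_a: int, pos_b: int) -> int:
    """Residue separation between two protein substitutions."""
    if pos_a < 1 or pos_b < 1:
        raise ValueError("protein residue positions are 1-based (>= 1)")
    return abs(pos_a - pos_b)
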