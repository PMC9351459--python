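"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the data a recessive root-angle mutant study produces:

* a panel of independently mutagenized lines carrying transition-biased
  private background SNVs plus one shared causal gene, sequenced at
  moderate depth (per-sample DP/DV via Poisson/Binomial sampling);
* an F2 of mutant x wild-type genotyped on a bi-allelic array, with
  Haldane-model recombination and bulk theta signals;
* 3D root polylines descending at a set vertical angle with waviness;
* AFM approach curves: flat baseline then a linear contact regime.

All randomness flows from one seed through numpy Generators spawned per
artifact; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mutations import GeneModel

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class ForceCurveParams:
    """Generating parameters of one AFM approach curve."""

    true_slope: float = 7.6  # pN/nm
    contact_z: float = 500.0  # nm
    baseline_noise_sd: float = 0.5  # pN
    n_points: int = 500
    z_max: float = 1000.0  # nm


@dataclass(frozen=True)
class RootSimParams:
    """Generating parameters of one 3D root polyline."""

    true_vertical_angle: float = 30.0  # deg from plumb; 0 = straight down
    length_mm: float = 100.0
    waviness_sd: float = 2.0  # deg, per-step jitter
    n_points: int = 50
    slice_spacing: int = 3  # XY slices between stored points (provenance metadata)


@dataclass(frozen=True)
class SimConfig:
    """Study-level configuration; defaults mirror the mapping-study design
    (F2 of 75 plants, 15-plant bulks, ~24x sequencing depth)."""

    seed: int = 0
    n_chromosomes: int = 7
    chrom_length_bp: int = 100_000_000
    marker_spacing_bp: int = 1_000_000
    n_mutant_lines: int = 10
    n_focal_lines: int = 2
    background_mutation_rate: float = 3.0  # mutations per Mb per line
    transition_fraction: float = 0.9
    causal_gene: tuple[str, int, int] = ("chr6", 50_000_000, 50_002_999)
    f2_size: int = 75
    bulk_size: int = 15
    n_replicate_bulks: int = 2
    theta_noise_sd: float = 0.05
    mean_depth: float = 24.0
    base_error_rate: float = 0.01
    cm_per_mb: float = 0.5
    force_curve: ForceCurveParams = field(default_factory=ForceCurveParams)
    root_sim: RootSimParams = field(default_factory=RootSimParams)

    def __post_init__(self) -> None:
        for name in ("transition_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.f2_size < 2 * self.bulk_size:
            raise ValueError("f2_size must be >= 2 * bulk_size")
        if self.n_mutant_lines < self.n_focal_lines:
            raise ValueError("need n_mutant_lines >= n_focal_lines")
        chrom, start, end = self.causal_gene
        if chrom not in self.chromosomes:
            raise ValueError(f"causal gene chromosome {chrom!r} not in genome")
        if not (1 <= start <= end <= self.chrom_length_bp):
            raise ValueError("causal gene outside chromosome bounds")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def line_names(self) -> tuple[str, ...]:
        return tuple(f"line{i + 1:02d}" for i in range(self.n_mutant_lines))

    @property
    def focal_lines(self) -> tuple[str, ...]:
        return self.line_names[: self.n_focal_lines]

    def rng(self, stream: str) -> np.random.Generator:
        """A named child generator; streams are independent and reproducible."""
        key = zlib.crc32(stream.encode())
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth behind one simulated study."""

    causal_positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    background_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    causal_gene_id: str | None = None
    f2_causal_genotypes: np.ndarray | None = None  # 0/1/2 mutant-allele count
    phenotypes: np.ndarray | None = None  # 'wild-type' | 'steep'
    true_angles: np.ndarray | None = None
    true_stiffness: np.ndarray | None = None


# ---------------------------------------------------------------------------
# genome, gene models, mutant panel
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random genome sequence, one string per chromosome.

    Intended for desk-scale configs (<= ~10 Mb total); the mapping-scale
    config does not need sequence because theta mapping is sequence-free.
    """
    rng = rng if rng is not None else config.rng("genome")
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        c: ascii_bases[rng.integers(0, 4, size=config.chrom_length_bp)].tobytes().decode()
        for c in config.chromosomes
    }


def simulate_gene_models(
    config: SimConfig,
    n_decoy_genes: int = 8,
    rng: np.random.Generator | None = None,
) -> list[GeneModel]:
    """The causal gene (two exons, one intron) plus single-exon decoys.

    The causal gene spans exactly ``config.causal_gene``; decoys are
    placed uniformly, non-overlapping, across the genome.
    """
    rng = rng if rng is not None else config.rng("genes")
    chrom, start, end = config.causal_gene
    span = end - start + 1
    if span < 60:
        raise ValueError("causal gene span too short for a two-exon model")
    intron_len = max(20, span // 10)
    exon1_len = (span - intron_len) // 2
    exon1_len -= (span - intron_len) % 3  # keep total CDS length % 3 == 0
    e1 = (start, start + exon1_len - 1)
    e2 = (start + exon1_len + intron_len, end)
    genes = [GeneModel("causal_gene", chrom, "+", (e1, e2), (e1, e2))]

    occupied = [(chrom, start, end)]
    i = 0
    while i < n_decoy_genes:
        c = config.chromosomes[rng.integers(config.n_chromosomes)]
        length = 3 * int(rng.integers(200, 500))
        s = int(rng.integers(1, max(2, config.chrom_length_bp - length)))
        e = s + length - 1
        if any(cc == c and not (e < ss or s > ee) for cc, ss, ee in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"decoy_{i + 1:02d}", c, strand, ((s, e),), ((s, e),)))
        occupied.append((c, s, e))
        i += 1
    return genes


def _draw_alt(ref: str, rng: np.random.Generator, transition_fraction: float) -> str:
    if rng.random() < transition_fraction:
        return _TRANSITION[ref]
    tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return tv[rng.integers(2)]


def _missense_substitution(
    gene: GeneModel, genome: Mapping[str, str], rng: np.random.Generator
) -> tuple[int, str, str]:
    """A (pos, ref, alt) inside the gene's CDS that changes the protein."""
    from .mutations import VariantRecord, classify_effect

    cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
    for _ in range(200):
        pos = int(cds_positions[rng.integers(len(cds_positions))])
        ref = genome[gene.chrom][pos - 1]
        alt = _draw_alt(ref, rng, transition_fraction=0.9)
        call = classify_effect(VariantRecord(gene.chrom, pos, ref, alt, 60.0), gene, genome)
        if call.effect in ("missense", "stop_gained"):
            return pos, ref, alt
    raise RuntimeError("could not place a protein-changing substitution")


def simulate_mutant_panel(
    config: SimConfig,
    genome: Mapping[str, str] | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Variant panel across independently mutagenized lines.

    Each line carries Poisson(rate x genome Mb) private background SNVs
    with a transition-biased spectrum; the focal lines additionally each
    carry one distinct protein-changing SNV inside the causal gene (when
    gene models and genome are supplied) or a uniform position within
    the causal interval otherwise. Per variant and line, DP ~
    Poisson(mean_depth) and DV ~ Binomial(DP, f) with f = 1 - e for the
    line owning a homozygous mutation and f = e (the base error rate)
    elsewhere.

    Returns the panel as a DataFrame (chrom, pos, ref, alt, qual and
    per-line DP_/DV_ columns, position-sorted) plus the ground truth.
    """
    rng = rng if rng is not None else config.rng("panel")
    truth = SimTruth()
    genome_mb = config.n_chromosomes * config.chrom_length_bp / 1e6
    lam = config.background_mutation_rate * genome_mb

    causal_gene = None
    if gene_models is not None:
        causal_gene = next(g for g in gene_models if g.gene_id == "causal_gene")
        truth.causal_gene_id = causal_gene.gene_id

    rows: list[tuple[str, int, str, str, str]] = []  # chrom,pos,ref,alt,owner
    chrom_c, start_c, end_c = config.causal_gene
    used_causal: set[int] = set()
    for line in config.line_names:
        truth.background_positions[line] = []
        n_bg = rng.poisson(lam)
        for _ in range(n_bg):
            c = config.chromosomes[rng.integers(config.n_chromosomes)]
            pos = int(rng.integers(1, config.chrom_length_bp + 1))
            ref = genome[c][pos - 1] if genome is not None else str(rng.choice(_BASES))
            alt = _draw_alt(ref, rng, config.transition_fraction)
            rows.append((c, pos, ref, alt, line))
            truth.background_positions[line].append((c, pos))
        if line in config.focal_lines:
            if causal_gene is not None and genome is not None:
                while True:
                    pos, ref, alt = _missense_substitution(causal_gene, genome, rng)
                    if pos not in used_causal:
                        break
            else:
                while True:
                    pos = int(rng.integers(start_c, end_c + 1))
                    if pos not in used_causal:
                        break
                ref = genome[chrom_c][pos - 1] if genome is not None else str(rng.choice(_BASES))
                alt = _draw_alt(ref, rng, config.transition_fraction)
            used_causal.add(pos)
            rows.append((chrom_c, pos, ref, alt, line))
            truth.causal_positions[line] = (chrom_c, pos)

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "owner"])
    n = len(df)
    df["qual"] = np.round(rng.uniform(45.0, 60.0, size=n), 1)
    for line in config.line_names:
        dp = rng.poisson(config.mean_depth, size=n)
        owner = (df["owner"] == line).to_numpy()
        f = np.where(owner, 1.0 - config.base_error_rate, config.base_error_rate)
        dv = rng.binomial(dp, f)
        df[f"DP_{line}"] = dp
        df[f"DV_{line}"] = dv
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cols = ["chrom", "pos", "ref", "alt", "qual", "owner"] + [
        f"{k}_{l}" for l in config.line_names for k in ("DP", "DV")
    ]
    return df[cols], truth


# ---------------------------------------------------------------------------
# F2 cross, bulks, theta
# ---------------------------------------------------------------------------

def marker_map(config: SimConfig) -> pd.DataFrame:
    """Array marker grid: one marker every marker_spacing_bp per chromosome."""
    rows = []
    for c in config.chromosomes:
        for pos in range(config.marker_spacing_bp, config.chrom_length_bp + 1, config.marker_spacing_bp):
            rows.append((f"mk_{c}_{pos}", c, pos))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"])


def _haldane_r(d_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Recombination fraction between adjacent loci under the Haldane map."""
    d_morgans = d_bp / 1e6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def simulate_f2(
    config: SimConfig,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """F2 of a recessive mutant x wild-type cross.

    Gametes recombine between adjacent loci with the Haldane fraction
    derived from physical distance through a uniform cM/Mb constant.
    Marker and causal-locus genotypes are mutant-allele counts (0/1/2);
    the phenotype is 'steep' iff the causal genotype is 2 (recessive).

    Returns (marker table, genotype table with plants as rows and
    markers as columns, truth with genotypes/phenotypes filled in).
    """
    rng = rng if rng is not None else config.rng("f2")
    truth = truth if truth is not None else SimTruth()
    markers = marker_map(config)
    chrom_c, start_c, end_c = config.causal_gene
    causal_pos = (start_c + end_c) // 2

    n_gam = 2 * config.f2_size
    geno_cols: dict[str, np.ndarray] = {}
    causal_geno = None
    for c in config.chromosomes:
        pos = markers.loc[markers["chrom"] == c, "pos"].to_numpy()
        names = markers.loc[markers["chrom"] == c, "marker"].tolist()
        is_marker = np.ones(len(pos), dtype=bool)
        if c == chrom_c:
            insert = int(np.searchsorted(pos, causal_pos))
            pos = np.insert(pos, insert, causal_pos)
            is_marker = np.insert(is_marker, insert, False)
            names = names[:insert] + ["__causal__"] + names[insert:]
        r = _haldane_r(np.diff(pos).astype(float), config.cm_per_mb)
        start_allele = rng.integers(0, 2, size=(n_gam, 1))
        switches = rng.random((n_gam, len(pos) - 1)) < r
        alleles = (start_allele + np.concatenate(
            [np.zeros((n_gam, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
        geno = alleles[0::2] + alleles[1::2]  # f2_size x loci
        for j, name in enumerate(names):
            if name == "__causal__":
                causal_geno = geno[:, j]
            else:
                geno_cols[name] = geno[:, j]

    genotypes = pd.DataFrame(geno_cols, columns=markers["marker"].tolist())
    genotypes.index.name = "plant"
    truth.f2_causal_genotypes = causal_geno
    truth.phenotypes = np.where(causal_geno == 2, "steep", "wild-type")
    return markers, genotypes, truth


def simulate_bsa_inputs(
    config: SimConfig,
    max_redraws: int = 20,
) -> tuple[pd.DataFrame, SimTruth]:
    """Theta table of one complete bulked-segregant experiment.

    Simulates the F2, redrawing (with a derived seed) when a phenotype
    class has fewer plants than the bulk size — the bench experiment is
    likewise only run once enough segregants of each class exist — then
    samples the bulks and measures replicate-averaged theta per marker.
    """
    last_err: Exception | None = None
    for attempt in range(max_redraws):
        sub = replace(config, seed=config.seed + 1_000_003 * attempt)
        markers, genotypes, truth = simulate_f2(sub)
        rng = sub.rng("bulks")
        try:
            bulk_wt, bulk_mut = make_bulks(truth.phenotypes, config.bulk_size, rng)
        except ValueError as err:
            last_err = err
            continue
        thetas = simulate_bulk_theta(
            markers, genotypes, bulk_wt, bulk_mut,
            config.theta_noise_sd, rng, config.n_replicate_bulks,
        )
        return thetas, truth
    raise RuntimeError(f"no F2 with enough segregants after {max_redraws} draws: {last_err}")


def make_bulks(
    phenotypes: np.ndarray,
    bulk_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample disjoint wild-type and steep bulks of ``bulk_size`` plants each."""
    wt = np.flatnonzero(phenotypes == "wild-type")
    mut = np.flatnonzero(phenotypes == "steep")
    if len(wt) < bulk_size or len(mut) < bulk_size:
        raise ValueError(
            f"not enough plants per class for bulks of {bulk_size} "
            f"(wild-type {len(wt)}, steep {len(mut)})"
        )
    return rng.choice(wt, bulk_size, replace=False), rng.choice(mut, bulk_size, replace=False)


def simulate_bulk_theta(
    markers: pd.DataFrame,
    genotypes: pd.DataFrame,
    bulk_wt: np.ndarray,
    bulk_mut: np.ndarray,
    theta_noise_sd: float,
    rng: np.random.Generator,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Array theta per marker and bulk.

    theta = (mutant-allele dosage sum) / (2 x bulk size) plus Gaussian
    noise, clipped to [0, 1]; replicate bulk measurements are averaged.
    """
    if len(bulk_wt) == 0 or len(bulk_mut) == 0:
        raise ValueError("bulks must be non-empty")
    if set(bulk_wt) & set(bulk_mut):
        raise ValueError("bulks must be disjoint plant sets")
    out = markers.copy()
    for name, bulk in (("theta_bulk_wt", bulk_wt), ("theta_bulk_mut", bulk_mut)):
        base = genotypes.iloc[bulk].sum(axis=0).to_numpy(float) / (2.0 * len(bulk))
        reps = np.clip(
            base[None, :] + rng.normal(0.0, theta_noise_sd, size=(n_replicates, len(base))),
            0.0, 1.0,
        )
        out[name] = reps.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# phenotyping instruments
# ---------------------------------------------------------------------------

def simulate_root_polyline(
    params: RootSimParams,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """3D polyline descending at a set vertical angle with angular waviness.

    Each step's polar angle is the target angle plus Gaussian jitter
    (clipped below horizontal so z decreases monotonically); the azimuth
    wanders around a random heading. The first point is the uppermost
    (z = 0 at the soil surface, z positive up).
    """
    if params.length_mm <= 0:
        raise ValueError("root length must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = params.n_points
    step = params.length_mm / (n - 1)
    polar = np.radians(
        np.clip(
            params.true_vertical_angle + rng.normal(0.0, params.waviness_sd, size=n - 1),
            0.0, 89.9,
        )
    )
    heading = rng.uniform(0.0, 2.0 * np.pi)
    azim = heading + np.radians(rng.normal(0.0, params.waviness_sd, size=n - 1))
    dx = step * np.sin(polar) * np.cos(azim)
    dy = step * np.sin(polar) * np.sin(azim)
    dz = -step * np.cos(polar)
    pts = np.zeros((n, 3))
    pts[1:, 0] = np.cumsum(dx)
    pts[1:, 1] = np.cumsum(dy)
    pts[1:, 2] = np.cumsum(dz)
    return pd.DataFrame(pts, columns=["x", "y", "z"])


def simulate_force_curve(
    params: ForceCurveParams,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """AFM approach curve: flat noisy baseline, then a linear contact regime."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not (0.0 < params.contact_z < params.z_max):
        raise ValueError("contact_z must lie inside the sampled displacement range")
    z = np.linspace(0.0, params.z_max, params.n_points)
    force = np.where(z < params.contact_z, 0.0, params.true_slope * (z - params.contact_z))
    if params.baseline_noise_sd > 0:
        force = force + rng.normal(0.0, params.baseline_noise_sd, size=params.n_points)
    return pd.DataFrame({"z_nm": z, "force_pN": force})


# ---------------------------------------------------------------------------
# CDS panels
# ---------------------------------------------------------------------------

def mutate_cds(reference: str, substitutions: Sequence[tuple[int, str]]) -> str:
    """Apply (1-based position, new base) substitutions to a CDS string."""
    if len(reference) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    seq = list(reference)
    for pos, base in substitutions:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"substitution position {pos} outside CDS of length {len(seq)}")
        seq[pos - 1] = base
    return "".join(seq)


def build_cds_panel(
    reference: str,
    patterns: Sequence[tuple[Sequence[tuple[int, str]], int]],
    prefix: str = "acc",
) -> dict[str, str]:
    """Accession panel from substitution patterns.

    ``patterns`` is a list of (substitution list, accession count); each
    pattern yields that many identical accessions, so collapsing the
    panel recovers exactly the designed haplotype structure.
    """
    panel: dict[str, str] = {}
    i = 0
    for subs, count in patterns:
        seq = mutate_cds(reference, subs)
        for _ in range(count):
            i += 1
            panel[f"{prefix}{i:03d}"] = seq
    return panel


def random_cds(length_codons: int, rng: np.random.Generator | int) -> str:
    """Random CDS without internal stop codons, starting ATG."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < length_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)
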