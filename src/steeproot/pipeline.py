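"""End-to-end drivers combining simulation, mapping and mutation calling."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

import numpy as np

from . import afm, bsa, mutations, simulate


@dataclass
class MutationStudyResult:
    panel: pd.DataFrame
    truth: simulate.SimTruth
    retained_by_focal: dict[str, pd.DataFrame]
    calls_by_focal: dict[str, list[mutations.EffectCall]]
    candidate_genes: list[str]


def run_bsa_mapping(
    config: simulate.SimConfig,
    smoothing_window: int = 5,
    threshold_quantile: float = 0.90,
) -> tuple[pd.DataFrame, bsa.LinkageInterval | None, simulate.SimTruth]:
    """Simulate one bulked-segregant experiment and call the linked interval."""
    thetas, truth = simulate.simulate_bsa_inputs(config)
    profile = bsa.compute_delta_theta(thetas)
    interval = bsa.call_linkage_interval(profile, smoothing_window, threshold_quantile)
    return profile, interval, truth


def run_mutation_study(
    config: simulate.SimConfig,
    interval: bsa.LinkageInterval,
    filter_config: mutations.FilterConfig = mutations.FilterConfig(),
    n_decoy_genes: int = 8,
) -> MutationStudyResult:
    """Simulate a mutant panel and nominate the causal gene.

    For each focal line the panel is filtered for variants private to
    that line (DV/DP predicate), retained variants are classified
    against the gene models, and the coding-impact gene sets of the
    focal lines are intersected inside the mapped interval.
    """
    genome = simulate.simulate_genome(config)
    genes = simulate.simulate_gene_models(config, n_decoy_genes=n_decoy_genes)
    panel, truth = simulate.simulate_mutant_panel(config, genome=genome, gene_models=genes)

    retained_by_focal: dict[str, pd.DataFrame] = {}
    calls_by_focal: dict[str, list[mutations.EffectCall]] = {}
    for focal in config.focal_lines:
        retained, _ = mutations.filter_unique_mutations(
            panel, [focal], filter_config, samples=list(config.line_names)
        )
        records = [
            mutations.VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, float(r.qual))
            for r in retained.itertuples()
        ]
        retained_by_focal[focal] = retained
        calls_by_focal[focal] = mutations.classify_effects(records, genes, genome)

    candidates = mutations.intersect_allelic_candidates(calls_by_focal, interval)
    return MutationStudyResult(panel, truth, retained_by_focal, calls_by_focal, candidates)


def stiffness_recovery_experiment(
    true_slope: float,
    n_curves: int = 300,
    seed: int = 42,
    n_points: int = 500,
    contact_range: tuple[float, float] = (300.0, 700.0),
    noise_sd: float = 0.5,
    fit_depth_nm: float = 200.0,
) -> tuple[float, list[float]]:
    """Recover a known stiffness from synthetic force curves.

    Generates ``n_curves`` approach curves with the given contact slope
    (contact point uniform over ``contact_range``), runs contact-point
    detection plus the linear fit on each, and returns the sample mean
    of the estimates together with the per-curve values.
    """
    rng = np.random.default_rng(seed)
    slopes: list[float] = []
    for _ in range(n_curves):
        params = simulate.ForceCurveParams(
            true_slope=true_slope,
            contact_z=float(rng.uniform(*contact_range)),
            baseline_noise_sd=noise_sd,
            n_points=n_points,
        )
        curve = simulate.simulate_force_curve(params, rng)
        z = curve["z_nm"].to_numpy()
        f = curve["force_pN"].to_numpy()
        contact = afm.detect_contact_point(z, f)
        if contact is None:
            continue
        slopes.append(afm.fit_linear_stiffness(z, f, contact, fit_depth_nm).slope)
    return float(np.mean(slopes)), slopes
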