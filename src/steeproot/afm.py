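"""Apparent stiffness from AFM force-distance curves.

An approach curve records cantilever force against displacement: a flat
noisy baseline before the tip touches the sample, then a rising contact
regime. The contact point is detected where the force sustainedly
exceeds the baseline noise band; apparent stiffness (pN/nm) is the
ordinary least-squares slope of force against indentation over a fixed
depth past contact, where a linear force model is adequate. Genotype
groups are compared with a two-sided Wilcoxon rank-sum test, pooled and
stratified by tissue (stele vs cortex) via the 3x3 measurement grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StiffnessEstimate:
    curve_id: str
    contact_z: float  # nm
    slope: float  # pN/nm
    fit_r2: float
    n_fit_points: int


@dataclass(frozen=True)
class GridComparison:
    stratum: str  # all | stele | cortex
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    percent_change: float  # 100 * (mean_a - mean_b) / mean_a
    statistic: float
    p_value: float


def _validate_curve(z, force) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float)
    force = np.asarray(force, dtype=float)
    if z.shape != force.shape or z.ndim != 1:
        raise ValueError("z and force must be 1-D arrays of equal length")
    if len(z) < 50:
        raise ValueError("force curve too short (< 50 samples)")
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("z must be strictly monotone")
    if dz[0] < 0:
        z, force = z[::-1], force[::-1]
    return z, force


def detect_contact_point(
    z,
    force,
    baseline_frac: float = 0.3,
    k_sigma: float = 3.0,
    min_run: int = 5,
) -> float | None:
    """Contact displacement, or ``None`` when the tip never touches.

    The baseline mean and SD come from the first ``baseline_frac`` of
    approach points; contact is the first sample where the force exceeds
    mean + ``k_sigma``*SD for at least ``min_run`` consecutive samples —
    the sustained-exceedance guard keeps single noise spikes from
    triggering a false contact.
    """
    if not 0.0 < baseline_frac <= 0.5:
        raise ValueError("baseline_frac must be in (0, 0.5]")
    z, force = _validate_curve(z, force)
    nb = max(int(len(z) * baseline_frac), 2)
    mu = force[:nb].mean()
    sd = force[:nb].std(ddof=1)
    above = force > mu + k_sigma * sd
    run = np.convolve(above.astype(int), np.ones(min_run, dtype=int), mode="valid")
    hits = np.flatnonzero(run == min_run)
    if len(hits) == 0:
        return None
    return float(z[hits[0]])


def fit_linear_stiffness(
    z,
    force,
    contact_z: float,
    fit_depth_nm: float = 200.0,
    curve_id: str = "curve",
    min_points: int = 10,
) -> StiffnessEstimate:
    """OLS slope of force vs indentation over (contact, contact + depth].

    The free intercept absorbs any constant force offset, so the slope
    is invariant to baseline shifts.
    """
    z, force = _validate_curve(z, force)
    mask = (z > contact_z) & (z <= contact_z + fit_depth_nm)
    if mask.sum() < min_points:
        raise ValueError(
            f"{curve_id}: only {int(mask.sum())} points within {fit_depth_nm} nm past contact "
            f"(need {min_points})"
        )
    x = z[mask] - contact_z
    y = force[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return StiffnessEstimate(
        curve_id=curve_id,
        contact_z=float(contact_z),
        slope=float(slope),
        fit_r2=float(r2),
        n_fit_points=int(mask.sum()),
    )


def analyze_curves(
    curves: Mapping[str, pd.DataFrame],
    baseline_frac: float = 0.3,
    k_sigma: float = 3.0,
    fit_depth_nm: float = 200.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Estimate stiffness for every curve; report excluded curves with reasons.

    ``curves`` maps curve_id to a DataFrame with ``z_nm`` and
    ``force_pN`` columns. Curves without a detectable contact point or
    with too few post-contact points are excluded, not fatal.
    """
    rows, excluded = [], []
    for cid, df in curves.items():
        z, f = df["z_nm"].to_numpy(float), df["force_pN"].to_numpy(float)
        contact = detect_contact_point(z, f, baseline_frac, k_sigma)
        if contact is None:
            excluded.append((cid, "no_contact"))
            continue
        try:
            est = fit_linear_stiffness(z, f, contact, fit_depth_nm, curve_id=cid)
        except ValueError:
            excluded.append((cid, "too_few_post_contact_points"))
            continue
        rows.append((cid, est.contact_z, est.slope, est.fit_r2, est.n_fit_points))
    out = pd.DataFrame(
        rows, columns=["curve_id", "contact_z_nm", "slope_pN_per_nm", "fit_r2", "n_fit_points"]
    )
    return out, excluded


def percent_change(mean_ref: float, mean_alt: float) -> float:
    """Relative change of the alternative group mean vs the reference, in %."""
    if mean_ref == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_ref - mean_alt) / mean_ref


def compare_groups(
    stiffness_a: Sequence[float],
    stiffness_b: Sequence[float],
    stratum: str = "all",
) -> GridComparison:
    """Group means/SDs, percent change and a two-sided rank-sum test.

    Group A is the reference: percent_change > 0 means group B is
    softer. Identical constant groups return p = 1 rather than failing
    the tie correction.
    """
    a = np.asarray(stiffness_a, dtype=float)
    b = np.asarray(stiffness_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 curves")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        stat, p = len(a) * len(b) / 2.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GridComparison(
        stratum=stratum,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        percent_change=float(percent_change(a.mean(), b.mean())),
        statistic=float(stat),
        p_value=float(p),
    )


def stratify_by_tissue(
    estimates_a: pd.DataFrame,
    estimates_b: pd.DataFrame,
    tissue_map: Mapping[int, str],
) -> dict[str, GridComparison]:
    """Per-tissue comparisons via the 3x3 grid, plus the pooled stratum.

    Each estimates frame needs ``slope_pN_per_nm`` and ``grid_cell``
    (1-9) columns; ``tissue_map`` assigns every observed grid cell to a
    tissue (e.g. stele vs cortex). Stratum sample sizes sum to the
    pooled n by construction.
    """
    for df in (estimates_a, estimates_b):
        unknown = set(df["grid_cell"]) - set(tissue_map)
        if unknown:
            raise ValueError(f"grid cells without a tissue assignment: {sorted(unknown)}")
    out = {
        "all": compare_groups(
            estimates_a["slope_pN_per_nm"], estimates_b["slope_pN_per_nm"], stratum="all"
        )
    }
    for tissue in sorted(set(tissue_map.values())):
        cells = {c for c, t in tissue_map.items() if t == tissue}
        a = estimates_a.loc[estimates_a["grid_cell"].isin(cells), "slope_pN_per_nm"]
        b = estimates_b.loc[estimates_b["grid_cell"].isin(cells), "slope_pN_per_nm"]
        out[tissue] = compare_groups(a, b, stratum=tissue)
    return out
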