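"""Bulked-segregant mapping on array theta signals.

At each bi-allelic array marker, theta approximates the mutant-allele
fraction of a DNA pool. For an F2 segregating a recessive locus, the
steep-phenotype bulk is fixed for the mutant allele at fully linked
markers (theta -> 1) while the wild-type bulk, a 1 AA : 2 Aa mixture,
sits at theta -> 1/3; unlinked markers give ~0.5 in both. The squared
difference of the two bulk thetas (delta-theta) therefore peaks at the
causal locus, with an expected maximum of (1 - 1/3)^2 ~ 0.444.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LinkageInterval:
    """Contiguous marker run flagged as linked to the causal locus."""

    chrom: str
    start: int
    end: int
    peak_marker_id: str
    peak_delta_theta: float

    def __post_init__(self) -> None:
        if not self.start <= self.end:
            raise ValueError("interval start must be <= end")


@dataclass(frozen=True)
class SegregationTestResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def n(self) -> int:
        return int(sum(self.observed))


def _natural_chrom_key(chrom: str) -> tuple:
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def compute_delta_theta(thetas: pd.DataFrame) -> pd.DataFrame:
    """Delta-theta per marker: squared difference of the two bulk thetas.

    Expects columns ``marker, chrom, pos`` plus ``theta_bulk_wt*`` and
    ``theta_bulk_mut*`` (replicate bulk columns sharing a prefix are
    averaged first). Returns the input with a ``delta_theta`` column,
    marker order preserved.
    """
    wt_cols = [c for c in thetas.columns if c.startswith("theta_bulk_wt")]
    mut_cols = [c for c in thetas.columns if c.startswith("theta_bulk_mut")]
    if not wt_cols or not mut_cols:
        raise ValueError("need theta_bulk_wt* and theta_bulk_mut* columns")
    for col in wt_cols + mut_cols:
        vals = thetas[col].to_numpy(float)
        bad = (vals < 0) | (vals > 1) | ~np.isfinite(vals)
        if bad.any():
            marker = thetas.loc[np.flatnonzero(bad)[0], "marker"]
            raise ValueError(f"theta outside [0,1] at marker {marker!r} (column {col})")
    wt = thetas[wt_cols].mean(axis=1).to_numpy(float)
    mut = thetas[mut_cols].mean(axis=1).to_numpy(float)
    out = thetas.copy()
    out["delta_theta"] = (wt - mut) ** 2
    return out


def call_linkage_interval(
    profile: pd.DataFrame,
    smoothing_window: int = 5,
    threshold_quantile: float = 0.90,
) -> LinkageInterval | None:
    """Call the linked interval from a delta-theta profile.

    The profile is smoothed per chromosome with a centered moving
    average (edges use shrunk windows); the interval is the maximal run
    of contiguous markers on the peak chromosome whose smoothed value
    exceeds the genome-wide ``threshold_quantile``, always containing
    the peak marker. A flat profile returns ``None`` (no linkage). Peak
    ties resolve to the smallest chromosome (natural order) then
    position.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    df = profile.copy()
    df["_ckey"] = df["chrom"].map(_natural_chrom_key)
    df = df.sort_values(["_ckey", "pos"], kind="mergesort").reset_index(drop=True)
    if df.groupby("chrom")["pos"].apply(lambda s: s.is_unique).eq(False).any():
        raise ValueError("duplicate marker positions within a chromosome")

    delta = df["delta_theta"].to_numpy(float)
    if np.ptp(delta) == 0.0:
        return None
    smoothed = (
        df.groupby("chrom", sort=False)["delta_theta"]
        .transform(lambda s: s.rolling(smoothing_window, center=True, min_periods=1).mean())
        .to_numpy(float)
    )
    threshold = float(np.quantile(smoothed, threshold_quantile))
    peak_i = int(np.argmax(smoothed))  # argmax is first max -> leftmost tie-break
    peak_chrom = df.loc[peak_i, "chrom"]

    on_chrom = (df["chrom"] == peak_chrom).to_numpy()
    above = (smoothed > threshold) & on_chrom
    above[peak_i] = True
    lo = peak_i
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi + 1 < len(df) and above[hi + 1]:
        hi += 1
    return LinkageInterval(
        chrom=str(peak_chrom),
        start=int(df.loc[lo, "pos"]),
        end=int(df.loc[hi, "pos"]),
        peak_marker_id=str(df.loc[peak_i, "marker"]),
        peak_delta_theta=float(smoothed[peak_i]),
    )


def chi_square_segregation(
    observed: Sequence[int],
    ratio: Sequence[int],
) -> SegregationTestResult:
    """Goodness-of-fit of observed class counts to a Mendelian ratio.

    chi2 = sum (O - E)^2 / E with E from the stated ratio; p from the
    chi-square distribution with (classes - 1) degrees of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if len(obs) != len(rat):
        raise ValueError("observed and ratio must have the same number of classes")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if (rat <= 0).any():
        raise ValueError("every expected class proportion must be positive")
    expected = rat / rat.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    return SegregationTestResult(
        observed=tuple(int(o) for o in observed),
        expected_ratio=tuple(int(r) for r in ratio),
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )
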