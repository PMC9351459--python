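"""Vertical root angles from 3D polylines and tip-bending kinetics.

A root traced in a CT volume is an ordered 3D polyline whose first
point is the uppermost (e.g. at the soil surface). Its vertical angle
is measured between the plumb (downward) vector and the direction from
the uppermost to the terminal point: steep roots score low angles and
shallow roots high angles, on [0, 90] degrees. Measurement stops where
the root meets the pot wall, so wall-following segments cannot distort
the angle. Gravitropic kinetics are quantified on time series of 2D
midlines (gravity along -y) as the angle of the fitted tip segment to
the gravity vector and its rate of change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PotGeometry:
    """Vertical cylindrical pot: axis through (cx, cy), radius in mm."""

    cx: float = 0.0
    cy: float = 0.0
    radius: float = 40.0
    height: float = 200.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pot radius must be positive")


@dataclass(frozen=True)
class RootAngleRecord:
    root_id: str
    root_class: str
    vertical_angle: float  # deg; 0 = plumb-vertical (steep), 90 = horizontal
    n_points_used: int
    folded: bool = False  # direction had an upward component, reflected down


def _as_points(polyline) -> np.ndarray:
    if isinstance(polyline, pd.DataFrame):
        pts = polyline[["x", "y", "z"]].to_numpy(float)
    else:
        pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (n, 3) array of x, y, z")
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if pts[0, 2] < pts[:, 2].max() - 1e-9:
        raise ValueError("first polyline point must be the uppermost (max z)")
    return pts


def vertical_angle(
    polyline,
    root_id: str = "root",
    root_class: str = "seminal",
) -> RootAngleRecord:
    """Angle between the plumb vector and the uppermost-to-terminal direction.

    0 deg is a plumb-vertical (steep) root, 90 deg horizontal. A
    direction with an upward component is folded through the horizontal
    plane (flagged), keeping the angle in [0, 90].
    """
    pts = _as_points(polyline)
    d = pts[-1] - pts[0]
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError("degenerate polyline: endpoints coincide")
    d = d / norm
    folded = d[2] > 0
    if folded:
        d = d * np.array([1.0, 1.0, -1.0])
    cos_a = np.clip(-d[2], -1.0, 1.0)  # dot with the downward vertical (0,0,-1)
    return RootAngleRecord(
        root_id=root_id,
        root_class=root_class,
        vertical_angle=float(np.degrees(np.arccos(cos_a))),
        n_points_used=len(pts),
        folded=bool(folded),
    )


def truncate_at_wall(polyline, pot: PotGeometry, eps: float = 0.5):
    """Drop the first wall-contacting point and everything after it.

    A point contacts the wall when its radial distance from the pot axis
    reaches ``radius - eps`` (eps defaults to 0.5 mm, the contact
    resolution). The first point must lie inside the pot.
    """
    pts = _as_points(polyline)
    r = np.hypot(pts[:, 0] - pot.cx, pts[:, 1] - pot.cy)
    contact = r >= pot.radius - eps
    if contact[0]:
        raise ValueError("first polyline point lies outside the pot")
    if not contact.any():
        return polyline
    cut = int(np.argmax(contact))
    if isinstance(polyline, pd.DataFrame):
        return polyline.iloc[:cut].reset_index(drop=True)
    return pts[:cut]


def lateral_insertion_angle(lateral, root_id: str = "lateral") -> RootAngleRecord:
    """Vertical angle of a lateral root measured from its insertion point.

    The first polyline point is the insertion on the parent root; the
    measurement is the same plumb-vector angle, taken relative to that
    origin.
    """
    pts = _as_points(lateral)
    shifted = pts - pts[0]
    return vertical_angle(shifted, root_id=root_id, root_class="lateral")


def _tip_direction(points: np.ndarray, tip_fraction: float) -> np.ndarray:
    """Least-squares direction of the terminal ``tip_fraction`` of arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("degenerate midline: zero arc length")
    from_tip = np.concatenate([[0.0], np.cumsum(seg[::-1])])[::-1]
    keep = from_tip <= tip_fraction * total + 1e-9
    tip = points[keep]
    if len(tip) < 2:
        tip = points[-2:]
    centered = tip - tip.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, tip[-1] - tip[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def tip_bending_series(
    midlines: dict[float, np.ndarray],
    tip_fraction: float = 0.25,
    stimulus_angle: float | None = None,
) -> pd.DataFrame:
    """Tip angle to the gravity vector over time.

    ``midlines`` maps time (h) to an ordered (n, 2) midline from base to
    tip, with gravity along -y. The tip angle at each time is the angle
    between the direction fitted through the terminal ``tip_fraction``
    of arc length and the gravity vector (0 = tip pointing straight
    down). Returns a DataFrame with ``time_h`` strictly increasing and
    ``tip_angle_deg``.
    """
    if not 0.0 < tip_fraction <= 0.5:
        raise ValueError("tip_fraction must be in (0, 0.5]")
    times = sorted(midlines)
    gravity = np.array([0.0, -1.0])
    rows = []
    for t in times:
        pts = np.asarray(midlines[t], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("each midline must be an (n >= 3, 2) array")
        d = _tip_direction(pts, tip_fraction)
        angle = np.degrees(np.arccos(np.clip(np.dot(d, gravity), -1.0, 1.0)))
        rows.append((float(t), float(angle)))
    out = pd.DataFrame(rows, columns=["time_h", "tip_angle_deg"])
    if stimulus_angle is not None:
        out["stimulus_angle_deg"] = stimulus_angle
    return out


def bending_rate(series: pd.DataFrame, window: float | None = None) -> float:
    """Least-squares slope of tip angle vs time, in deg/h.

    With ``window`` set, the fit uses points within ``window`` hours of
    the first time point (the response phase right after the
    gravistimulus); otherwise the whole series.
    """
    t = series["time_h"].to_numpy(float)
    a = series["tip_angle_deg"].to_numpy(float)
    if window is not None:
        keep = t <= t[0] + window
        t, a = t[keep], a[keep]
    if len(t) < 2:
        raise ValueError("need at least 2 time points in the window")
    return float(np.polyfit(t, a, 1)[0])
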