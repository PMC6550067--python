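"""Finder-grid relocation arithmetic and LM/EM landmark shift analysis.

2-D points in this module are ``(x, y)`` in µm (image-plane coordinates).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class GridLabelError(ValueError):
    """A coordinate label could not be parsed or addressed."""


_LABEL_RE = re.compile(r"^(?:(?P<num1>\d+)(?P<let1>[A-Z])|(?P<let2>[A-Z])(?P<num2>\d+))$")


def parse_grid_label(label: str) -> tuple[int, int]:
    """Parse a finder-grid label into ``(number, letter_index)``.

    Labels are one numeric run and one single-letter run in either order
    ("4M" or "M4"); letters A-Z map to indices 0-25.
    """
    m = _LABEL_RE.match(label.strip().upper())
    if not m:
        raise GridLabelError(
            f"label {label!r} must combine one number and one letter A-Z (e.g. '4M')"
        )
    number = int(m.group("num1") or m.group("num2"))
    letter = m.group("let1") or m.group("let2")
    return number, ord(letter) - ord("A")


def offset_label(label: str, d_number: int, d_letter: int) -> str:
    """Label at an integer grid offset; the letter axis does not wrap.

    Stepping past 'Z' or 'A' (or below number 0) raises
    :class:`GridLabelError` -- there is no wraparound on a finder grid.
    """
    number, letter = parse_grid_label(label)
    number += d_number
    letter += d_letter
    if number < 0:
        raise GridLabelError(f"offset leaves the grid: number {number} < 0")
    if not 0 <= letter <= 25:
        raise GridLabelError(
            "offset leaves the letter range A-Z (finder grids do not wrap)"
        )
    return f"{number}{chr(ord('A') + letter)}"


@dataclass(frozen=True)
class GridMap:
    """Anchors a finder grid in physical space.

    The anchor label's cell center is at ``anchor_center_um`` (x, y); cells
    are ``pitch_um`` apart.  Convention: numbers advance along x (rows of the
    etched grid), letters along y (columns).
    """

    anchor_label: str
    anchor_center_um: tuple[float, float] = (0.0, 0.0)
    pitch_um: float = 500.0

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")
        parse_grid_label(self.anchor_label)  # validate


def predict_grid_coordinates(gmap: GridMap, labels: list[str]) -> np.ndarray:
    """Predicted cell centers ``(x, y)`` µm for target labels.

    ``center(label) = anchor + pitch * (delta_number, delta_letter)``.
    """
    n0, l0 = parse_grid_label(gmap.anchor_label)
    out = np.empty((len(labels), 2), dtype=float)
    ax, ay = gmap.anchor_center_um
    for i, label in enumerate(labels):
        n, l = parse_grid_label(label)
        out[i] = (ax + gmap.pitch_um * (n - n0), ay + gmap.pitch_um * (l - l0))
    return out


def assign_rings(points_um: np.ndarray, center_um, spacing_um: float) -> np.ndarray:
    """Concentric-ring index per point: ``ceil(distance / spacing)``.

    Ring boundaries are closed on the outside (a point exactly on a ring
    belongs to the inner annulus); the center itself is ring 1.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    points = np.atleast_2d(np.asarray(points_um, dtype=float))
    d = np.linalg.norm(points - np.asarray(center_um, dtype=float), axis=1)
    rings = np.ceil(d / spacing_um - 1e-9).astype(int)
    return np.maximum(rings, 1)


@dataclass
class CorrespondenceSet:
    """Paired LM/EM landmark points ``(x, y)`` µm with a shared origin landmark."""

    lm_points_um: np.ndarray
    em_points_um: np.ndarray
    origin_index: int
    landmark_classes: list[str] = field(default_factory=list)
    landmark_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lm_points_um = np.atleast_2d(np.asarray(self.lm_points_um, dtype=float))
        self.em_points_um = np.atleast_2d(np.asarray(self.em_points_um, dtype=float))
        if self.lm_points_um.shape != self.em_points_um.shape:
            raise ValueError("LM and EM point counts must match")
        if self.lm_points_um.shape[1] != 2:
            raise ValueError("points must be (N, 2) arrays of (x, y) µm")
        n = self.lm_points_um.shape[0]
        if not 0 <= self.origin_index < n:
            raise ValueError(f"origin_index {self.origin_index} out of range for {n} points")
        if not self.landmark_classes:
            self.landmark_classes = ["myelin"] * n
        if not self.landmark_ids:
            self.landmark_ids = [f"p{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.lm_points_um.shape[0]


@dataclass
class ShiftResult:
    """Per-landmark LM->EM displacement statistics."""

    dx_um: np.ndarray
    dy_um: np.ndarray
    shift_um: np.ndarray
    r_um: np.ndarray              # distance from origin (mean of centred positions)
    angle_arcsin_rad: np.ndarray  # arcsin(dy / shift), as reported convention
    angle_full_rad: np.ndarray    # atan2(dy, dx), quadrant-resolved
    ring: np.ndarray
    mean_shift_um: float = 0.0
    sd_shift_um: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dx_um": self.dx_um,
                "dy_um": self.dy_um,
                "shift_um": self.shift_um,
                "r_um": self.r_um,
                "angle_arcsin_rad": self.angle_arcsin_rad,
                "angle_full_rad": self.angle_full_rad,
                "ring": self.ring,
            }
        )

    def summary(self) -> dict:
        return {
            "n": int(self.shift_um.size),
            "mean_shift_um": self.mean_shift_um,
            "sd_shift_um": self.sd_shift_um,
        }


def compute_shifts(cset: CorrespondenceSet, ring_spacing_um: float = 6.5) -> ShiftResult:
    """Per-point displacement between modalities after origin centring.

    Both point sets are re-centred on the shared origin landmark (removing
    any common rigid translation), then ``(dx, dy) = EM - LM`` per point.
    The origin landmark itself is the reference, not a measurement -- its
    shift is zero by construction -- so it is excluded from the per-point
    output and the summary statistics.  ``r`` is the distance from the
    origin of the mean centred position, the ring index follows the
    concentric-ring convention, and the direction is reported both as
    ``arcsin(dy/shift)`` and as a full atan2 angle.
    """
    if cset.n < 2:
        raise ValueError("need at least 2 correspondences (origin + 1 landmark)")
    keep = np.arange(cset.n) != cset.origin_index
    lm = (cset.lm_points_um - cset.lm_points_um[cset.origin_index])[keep]
    em = (cset.em_points_um - cset.em_points_um[cset.origin_index])[keep]
    delta = em - lm
    dx, dy = delta[:, 0], delta[:, 1]
    shift = np.hypot(dx, dy)
    mid = 0.5 * (lm + em)
    r = np.linalg.norm(mid, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(shift > 0, dy / np.where(shift > 0, shift, 1.0), 0.0)
    angle_arcsin = np.arcsin(np.clip(ratio, -1.0, 1.0))
    angle_full = np.arctan2(dy, dx)
    rings = assign_rings(mid, (0.0, 0.0), ring_spacing_um)
    return ShiftResult(
        dx_um=dx,
        dy_um=dy,
        shift_um=shift,
        r_um=r,
        angle_arcsin_rad=angle_arcsin,
        angle_full_rad=angle_full,
        ring=rings,
        mean_shift_um=float(shift.mean()),
        sd_shift_um=float(shift.std(ddof=1)) if shift.size > 1 else 0.0,
    )


@dataclass
class TrendReport:
    """Pearson trends of shift vs distance-from-origin and vs direction."""

    r_vs_distance: float
    p_vs_distance: float
    r_vs_angle: float
    p_vs_angle: float
    verdict: str
    zero_variance: bool = False

    def summary(self) -> dict:
        return {
            "r_vs_distance": self.r_vs_distance,
            "p_vs_distance": self.p_vs_distance,
            "r_vs_angle": self.r_vs_angle,
            "p_vs_angle": self.p_vs_angle,
            "verdict": self.verdict,
            "zero_variance": self.zero_variance,
            "test": "pearson, two-sided t-based p",
        }


def shift_trend(result: ShiftResult, alpha: float = 0.05) -> TrendReport:
    """Correlate per-point shift against r and against direction angle.

    Verdict is "isotropic" when neither correlation is significant at
    ``alpha``.  Zero-variance shifts (e.g. a pure common translation) have
    no measurable trend: coefficients are reported as 0 with undefined p.
    """
    if result.shift_um.size < 3:
        raise ValueError("need at least 3 points for a trend")
    shift = result.shift_um
    scale = max(float(np.abs(shift).max()), 1e-30)
    if float(np.ptp(shift)) <= 1e-9 * scale or float(np.ptp(result.r_um)) <= 1e-12:
        return TrendReport(
            r_vs_distance=0.0,
            p_vs_distance=float("nan"),
            r_vs_angle=0.0,
            p_vs_angle=float("nan"),
            verdict="isotropic",
            zero_variance=True,
        )
    rd, pd_ = stats.pearsonr(shift, result.r_um)
    if float(np.var(result.angle_arcsin_rad)) == 0.0:
        ra, pa = 0.0, float("nan")
    else:
        ra, pa = stats.pearsonr(shift, result.angle_arcsin_rad)
    significant = (pd_ <= alpha) or (not math.isnan(pa) and pa <= alpha)
    return TrendReport(
        r_vs_distance=float(rd),
        p_vs_distance=float(pd_),
        r_vs_angle=float(ra),
        p_vs_angle=float(pa),
        verdict="anisotropic" if significant else "isotropic",
        zero_variance=False,
    )


def correspondences_to_dataframe(cset: CorrespondenceSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "landmark_id": cset.landmark_ids,
            "class": cset.landmark_classes,
            "lm_x_um": cset.lm_points_um[:, 0],
            "lm_y_um": cset.lm_points_um[:, 1],
            "em_x_um": cset.em_points_um[:, 0],
            "em_y_um": cset.em_points_um[:, 1],
            "is_origin": [i == cset.origin_index for i in range(cset.n)],
        }
    )


def correspondences_from_dataframe(df: pd.DataFrame) -> CorrespondenceSet:
    origin_rows = np.nonzero(df["is_origin"].to_numpy())[0]
    if len(origin_rows) != 1:
        raise ValueError("correspondence table must flag exactly one origin landmark")
    return CorrespondenceSet(
        lm_points_um=df[["lm_x_um", "lm_y_um"]].to_numpy(float),
        em_points_um=df[["em_x_um", "em_y_um"]].to_numpy(float),
        origin_index=int(origin_rows[0]),
        landmark_classes=df["class"].astype(str).tolist(),
        landmark_ids=df["landmark_id"].astype(str).tolist(),
    )
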