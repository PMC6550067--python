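"""Line-scan morphometry: diameters, g-ratio estimators and group statistics.

Diameters come from intensity profiles across a fibre ("pixel density
scans").  In EM the myelin sheath is the darkest structure, so the profile
shows two troughs; in fluorescence images of a myelin dye it shows two
peaks.  The fibre diameter D spans the *outer* half-amplitude crossings of
the two myelin extrema and the axon diameter d the *inner* crossings, with
half levels computed between the local background/lumen plateau and each
extremum and crossing positions refined by linear sub-sample interpolation.

Three estimators of g = d/D are provided: per-scan diameters, square root of
paired cross-sectional area ratios, and square root of per-fibre volume
ratios -- so all three estimate the same dimensionless quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats


class MeasurementError(RuntimeError):
    """A scan did not yield a usable diameter pair (reported, not imputed)."""


@dataclass
class LineProfile:
    """Intensity samples along a scan at uniform physical spacing."""

    positions_um: np.ndarray
    intensities: np.ndarray
    modality: str = "em"
    polarity: str = "dark-myelin"

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.ndim != 1 or self.positions_um.size < 2:
            raise ValueError("profile needs >= 2 samples")
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match")
        steps = np.diff(self.positions_um)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("positions must be uniformly spaced")
        if self.polarity not in ("dark-myelin", "bright-myelin"):
            raise ValueError("polarity must be 'dark-myelin' or 'bright-myelin'")

    @property
    def spacing_um(self) -> float:
        return float(self.positions_um[1] - self.positions_um[0])


@dataclass(frozen=True)
class DiameterPair:
    """One (d, D) measurement along a fibre."""

    d_um: float
    D_um: float
    orientation: str = "orthogonal"  # 'longitudinal' | 'orthogonal'
    position_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.d_um < self.D_um:
            raise ValueError(f"need 0 < d < D, got d={self.d_um}, D={self.D_um}")

    @property
    def g(self) -> float:
        return self.d_um / self.D_um


@dataclass
class GRatioResult:
    """Per-sample g values and summary statistics for one estimator."""

    method: str  # 'diameter' | 'area' | 'volume'
    values: np.ndarray
    n: int = 0
    mean: float = 0.0
    sd: float = 0.0
    sem: float = 0.0

    @classmethod
    def from_values(cls, method: str, values) -> "GRatioResult":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("need at least one g value")
        n = int(values.size)
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        return cls(
            method=method,
            values=values,
            n=n,
            mean=float(values.mean()),
            sd=sd,
            sem=sd / np.sqrt(n) if n > 1 else 0.0,
        )

    def summary(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "sem": self.sem,
        }


def line_scan(
    image: np.ndarray,
    p0_um: tuple[float, float],
    p1_um: tuple[float, float],
    n_samples: int,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    origin_um: tuple[float, float] = (0.0, 0.0),
    modality: str = "em",
    polarity: str = "dark-myelin",
) -> LineProfile:
    """Bilinear intensity profile between two physical points ``(y, x)`` µm."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("line_scan operates on 2-D images")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValueError("scan endpoints coincide (zero-length scan)")
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = (pts - np.asarray(origin_um)) / np.asarray(pixel_size_um) - 0.5
    limits = np.asarray(image.shape) - 1
    if np.any(idx < -1e-9) or np.any(idx > limits + 1e-9):
        raise ValueError("scan endpoints outside the interpolable image area")
    values = ndimage.map_coordinates(
        image, idx.T, order=1, mode="nearest"
    )
    return LineProfile(
        positions_um=ts * length,
        intensities=values,
        modality=modality,
        polarity=polarity,
    )


def _half_crossing(
    x: np.ndarray, s: np.ndarray, i_from: int, i_to: int, level: float
) -> float:
    """Sub-sample position where ``s`` first drops below ``level`` walking
    from ``i_from`` toward ``i_to`` (exclusive); ``s[i_from]`` >= level."""
    step = 1 if i_to >= i_from else -1
    prev = i_from
    for i in range(i_from + step, i_to + step, step):
        if s[i] < level:
            frac = (s[prev] - level) / (s[prev] - s[i])
            return float(x[prev] + frac * (x[i] - x[prev]))
        prev = i
    raise MeasurementError("no half-amplitude crossing found")


def profile_to_diameters(
    profile: LineProfile,
    prominence_fraction: float = 0.2,
    orientation: str = "orthogonal",
    position_um: float = 0.0,
) -> DiameterPair:
    """Extract (d, D) from a profile crossing the full fibre.

    Requires two myelin extrema (troughs for dark-myelin EM, peaks for
    bright-myelin LM) with background on both ends.  Raises
    :class:`MeasurementError` when the scan cannot be measured, mirroring
    real scans that fail in noisy data and are skipped rather than imputed.
    """
    x = profile.positions_um
    intens = profile.intensities
    rng = float(intens.max() - intens.min())
    if rng <= 0:
        raise MeasurementError("flat profile")
    # sign-normalize so myelin extrema are maxima of s
    s = intens.copy() if profile.polarity == "bright-myelin" else -intens
    peaks, _ = signal.find_peaks(s, prominence=prominence_fraction * rng)
    if len(peaks) < 2:
        raise MeasurementError(
            f"found {len(peaks)} myelin extrema, need 2 (noisy or incomplete scan)"
        )
    iL, iR = int(peaks[0]), int(peaks[-1])

    base_outer_L = float(s[: iL + 1].min())
    base_outer_R = float(s[iR:].min())
    base_lumen = float(s[iL : iR + 1].min())

    lvl_oL = 0.5 * (s[iL] + base_outer_L)
    lvl_oR = 0.5 * (s[iR] + base_outer_R)
    lvl_iL = 0.5 * (s[iL] + base_lumen)
    lvl_iR = 0.5 * (s[iR] + base_lumen)

    x_oL = _half_crossing(x, s, iL, 0, lvl_oL)
    x_oR = _half_crossing(x, s, iR, len(s) - 1, lvl_oR)
    x_iL = _half_crossing(x, s, iL, iR, lvl_iL)
    x_iR = _half_crossing(x, s, iR, iL, lvl_iR)

    D = x_oR - x_oL
    d = x_iR - x_iL
    if not 0 < d < D:
        raise MeasurementError(f"inconsistent edges (d={d:.4f}, D={D:.4f})")
    return DiameterPair(d_um=d, D_um=D, orientation=orientation, position_um=position_um)


def g_ratio_diameter(pairs: list[DiameterPair]) -> GRatioResult:
    """Per-pair g = d/D."""
    if not pairs:
        raise ValueError("need at least one diameter pair")
    return GRatioResult.from_values("diameter", [p.g for p in pairs])


def g_ratio_area(axon_areas_um2, fibre_areas_um2) -> GRatioResult:
    """Per-pair g = sqrt(axon area / fibre area).

    The square root maps the paired cross-sectional-area ratio onto the
    d/D scale so all estimators target the same quantity.
    """
    ca = np.asarray(axon_areas_um2, dtype=float)
    CA = np.asarray(fibre_areas_um2, dtype=float)
    if ca.shape != CA.shape or ca.size == 0:
        raise ValueError("paired nonempty area lists required")
    if np.any(ca <= 0) or np.any(CA <= 0) or np.any(ca >= CA):
        raise ValueError("areas must be positive with axon < fibre")
    return GRatioResult.from_values("area", np.sqrt(ca / CA))


def g_ratio_volume(axon_volumes_um3, fibre_volumes_um3) -> GRatioResult:
    """Per-fibre g = sqrt(axon volume / fibre volume) over a shared extent."""
    va = np.atleast_1d(np.asarray(axon_volumes_um3, dtype=float))
    vf = np.atleast_1d(np.asarray(fibre_volumes_um3, dtype=float))
    if va.shape != vf.shape or va.size == 0:
        raise ValueError("paired nonempty volume lists required")
    if np.any(va <= 0) or np.any(vf <= 0) or np.any(va >= vf):
        raise ValueError("volumes must be positive with axon < fibre")
    return GRatioResult.from_values("volume", np.sqrt(va / vf))


def count_lamellae(profile: LineProfile, prominence_fraction: float = 0.2) -> int:
    """Count myelin lamellae crossed by a radial profile through a paranode.

    Counts local extrema of the myelin polarity whose prominence exceeds
    ``prominence_fraction`` x the profile's dynamic range.  A flat profile
    counts zero.
    """
    intens = profile.intensities
    rng = float(intens.max() - intens.min())
    if rng <= 0:
        return 0
    s = intens if profile.polarity == "bright-myelin" else -intens
    peaks, _ = signal.find_peaks(s, prominence=prominence_fraction * rng)
    return int(len(peaks))


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA across named groups."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_table: pd.DataFrame  # group, n, mean, sem
    note: str | None = None

    def summary(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p_value,
            "note": self.note,
            "groups": self.group_table.to_dict(orient="records"),
        }


def compare_gratio_groups(groups: dict[str, GRatioResult]) -> AnovaResult:
    """One-way ANOVA over named g-ratio groups, from group sums of squares."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = {name: np.asarray(g.values, dtype=float) for name, g in groups.items()}
    if any(v.size < 2 for v in samples.values()):
        raise ValueError("each group needs n >= 2")
    all_values = np.concatenate(list(samples.values()))
    grand = all_values.mean()
    k = len(samples)
    N = all_values.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in samples.values())
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in samples.values())
    df_b, df_w = k - 1, N - k
    note = None
    if ss_within == 0.0 and ss_between == 0.0:
        f = float("nan")
        p = float("nan")
        note = "all observations identical; F undefined"
    elif ss_within == 0.0:
        f = float("inf")
        p = 0.0
        note = "zero within-group variance"
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    table = pd.DataFrame(
        [
            {
                "group": name,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            }
            for name, v in samples.items()
        ]
    )
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_table=table,
        note=note,
    )


def pairs_to_dataframe(pairs: list[DiameterPair], fibre_id: str = "fibre", modality: str = "em") -> pd.DataFrame:
    """Tidy measurement table (one row per scan)."""
    return pd.DataFrame(
        [
            {
                "fibre_id": fibre_id,
                "position_um": p.position_um,
                "orientation": p.orientation,
                "modality": modality,
                "d_um": p.d_um,
                "D_um": p.D_um,
                "g": p.g,
            }
            for p in pairs
        ]
    )
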