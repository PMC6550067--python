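"""Ground-truthed synthetic volumes of myelinated fibres.

Builds label volumes of axon + myelin annulus fibres, nodal gaps flanked by
terminating paranodal lamellae, and ellipsoidal soma/nucleus fiducials, then
renders them as EM-like (dark myelin, Gaussian noise) and LM-like
(PSF-blurred dye channels, Poisson-Gaussian noise) image stacks.  A
configurable affine transform between the two modalities emulates the
anisotropic distortions seen between matched datasets.

Rasterization rule: a voxel belongs to a region iff its *center* lies inside
the analytic region.  This keeps voxel-count volumes unbiased and testable
against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    AXON,
    BACKGROUND,
    LOOP,
    MATERIALS,
    MYELIN,
    NUCLEUS,
    SOMA,
    GridSpec,
    ImageStack,
    LabelVolume,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Default EM contrast means on a 0-255 scale.  Myelin is the darkest
#: material, axoplasm intermediate, embedding background brightest.
DEFAULT_EM_CONTRAST: dict[int, float] = {
    BACKGROUND: 200.0,
    AXON: 150.0,
    MYELIN: 40.0,
    LOOP: 60.0,
    SOMA: 120.0,
    NUCLEUS: 90.0,
}


class PhantomBoundsError(ValueError):
    """Requested geometry does not fit inside the target grid."""


class PlacementError(RuntimeError):
    """Fiducial placement failed after bounded retries."""


@dataclass(frozen=True)
class FibreSpec:
    """Geometry of one myelinated fibre.

    ``centerline`` is an ``(N, 3)`` polyline of physical ``(z, y, x)`` points
    in µm, N >= 2 with positive segment lengths.  ``axon_diameter_um`` (d) and
    ``fibre_diameter_um`` (D) satisfy 0 < d < D.
    """

    centerline: np.ndarray
    axon_diameter_um: float
    fibre_diameter_um: float
    axon_label: int = AXON
    myelin_label: int = MYELIN

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centerline must be an (N>=2, 3) array of (z, y, x) µm")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) <= 0):
            raise ValueError("centerline segments must have positive length")
        object.__setattr__(self, "centerline", pts)
        d, D = float(self.axon_diameter_um), float(self.fibre_diameter_um)
        if not 0 < d < D:
            raise ValueError(f"need 0 < d < D, got d={d}, D={D}")

    @property
    def g_true(self) -> float:
        return self.axon_diameter_um / self.fibre_diameter_um

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))


@dataclass(frozen=True)
class NodeSpec:
    """Nodal gap and paranodal lamella geometry.

    The myelin sheath is absent over an axial window of ``gap_length_um``
    centred on the fibre midpoint.  On either side, ``n_lamellae_per_side``
    concentric shells spaced ``lamellar_period_um`` apart terminate
    sequentially toward the node (innermost shell closest to the gap) over an
    axial span of ``paranode_length_um``.
    """

    gap_length_um: float
    n_lamellae_per_side: int = 10
    lamellar_period_um: float = 0.016
    paranode_length_um: float = 0.5
    loop_label: int = LOOP

    def __post_init__(self) -> None:
        if self.gap_length_um <= 0:
            raise ValueError("gap_length_um must be > 0")
        if self.n_lamellae_per_side < 1:
            raise ValueError("n_lamellae_per_side must be >= 1")
        if self.lamellar_period_um <= 0:
            raise ValueError("lamellar_period_um must be > 0")
        if self.paranode_length_um <= 0:
            raise ValueError("paranode_length_um must be > 0")

    def validate_against(self, fibre: FibreSpec) -> None:
        thickness = (fibre.fibre_diameter_um - fibre.axon_diameter_um) / 2.0
        need = self.n_lamellae_per_side * self.lamellar_period_um
        if need > thickness + 1e-12:
            raise ValueError(
                f"{self.n_lamellae_per_side} lamellae at period "
                f"{self.lamellar_period_um} µm need {need:.4f} µm but the myelin "
                f"is only {thickness:.4f} µm thick"
            )


@dataclass(frozen=True)
class PSFModel:
    """Separable Gaussian PSF parameterised by lateral/axial FWHM in µm."""

    modality: str = "ideal"
    fwhm_lateral_um: float = 0.0
    fwhm_axial_um: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_lateral_um < 0 or self.fwhm_axial_um < 0:
            raise ValueError("FWHMs must be >= 0")

    @classmethod
    def preset(cls, name: str) -> "PSFModel":
        presets = {
            "ideal": (0.0, 0.0),
            "airyscan": (0.14, 0.35),
            "confocal": (0.25, 0.6),
        }
        if name not in presets:
            raise KeyError(f"unknown PSF preset {name!r}; choose from {sorted(presets)}")
        lat, ax = presets[name]
        return cls(modality=name, fwhm_lateral_um=lat, fwhm_axial_um=ax)

    def sigmas_vox(self, voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
        """Gaussian sigmas in voxel units for a (plane,row,col) grid."""
        s_ax = self.fwhm_axial_um * _FWHM_TO_SIGMA
        s_lat = self.fwhm_lateral_um * _FWHM_TO_SIGMA
        return (s_ax / voxel_size[0], s_lat / voxel_size[1], s_lat / voxel_size[2])


@dataclass(frozen=True)
class ModalityTransform:
    """In-plane affine distortion between modalities.

    Points ``p`` (x, y[, z]) are mapped ``scale @ rotation @ (p + translation)``
    -- translate first, then rotate about the plane normal, then apply
    per-axis anisotropic scaling about the origin.  The identity transform
    maps every point to itself exactly.
    """

    translation: tuple[float, ...] = (0.0, 0.0)
    scale: tuple[float, ...] = (1.0, 1.0)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale factors must be > 0")
        if len(self.translation) not in (2, 3) or len(self.scale) not in (2, 3):
            raise ValueError("translation and scale must have 2 or 3 components")

    @property
    def is_identity(self) -> bool:
        return (
            all(t == 0 for t in self.translation)
            and all(s == 1 for s in self.scale)
            and self.rotation_deg == 0
        )

    def _dim(self, points: np.ndarray) -> int:
        dim = points.shape[-1]
        if dim not in (2, 3):
            raise ValueError("points must be (..., 2) or (..., 3)")
        return dim

    def _params(self, dim: int) -> tuple[np.ndarray, np.ndarray, float]:
        t = np.zeros(dim)
        t[: len(self.translation)] = self.translation[:dim]
        s = np.ones(dim)
        s[: len(self.scale)] = self.scale[:dim]
        return t, s, math.radians(self.rotation_deg)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        dim = self._dim(points)
        if self.is_identity:
            return points.copy()
        t, s, theta = self._params(dim)
        out = points + t
        if theta != 0.0:
            c, sn = math.cos(theta), math.sin(theta)
            x = out[..., 0] * c - out[..., 1] * sn
            y = out[..., 0] * sn + out[..., 1] * c
            out = out.copy()
            out[..., 0], out[..., 1] = x, y
        return out * s

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        dim = self._dim(points)
        if self.is_identity:
            return points.copy()
        t, s, theta = self._params(dim)
        out = points / s
        if theta != 0.0:
            c, sn = math.cos(-theta), math.sin(-theta)
            x = out[..., 0] * c - out[..., 1] * sn
            y = out[..., 0] * sn + out[..., 1] * c
            out = out.copy()
            out[..., 0], out[..., 1] = x, y
        return out - t


def apply_modality_transform(points: np.ndarray, transform: ModalityTransform) -> np.ndarray:
    """Map physical points through a :class:`ModalityTransform`."""
    return transform.apply(points)


@dataclass
class Fiducial:
    center_um: tuple[float, float, float]  # (z, y, x)
    material: str
    semi_axes_um: tuple[float, float, float]


@dataclass
class FibreTruth:
    axon_diameter_um: float
    fibre_diameter_um: float
    g: float
    axon_label: int
    myelin_label: int
    length_um: float


@dataclass
class GroundTruth:
    """True geometry and voxel-count volumes of a generated phantom."""

    fibres: list[FibreTruth] = field(default_factory=list)
    volumes_um3: dict[str, float] = field(default_factory=dict)
    fiducials: list[Fiducial] = field(default_factory=list)
    transform: ModalityTransform | None = None
    meta: dict = field(default_factory=dict)

    def with_volumes_from(self, labels: LabelVolume) -> "GroundTruth":
        vv = labels.grid.voxel_volume_um3
        vols = {
            labels.materials[i]: c * vv for i, c in labels.counts().items()
        }
        self.volumes_um3 = vols
        return self


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _polyline_fields(
    grid: GridSpec, polyline: np.ndarray, chunk: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (radial distance, arc-length position) relative to a polyline.

    Radial distance uses the *capped* convention: for each segment only
    points whose axial projection falls within the segment are considered,
    so a straight polyline rasterizes to a flat-capped cylinder (voxel-count
    volume converges to pi r^2 L, no spherical end caps).  Interior vertices
    are bridged so gently bent fibres stay gap-free on the outside of bends.
    """
    pts = np.asarray(polyline, dtype=float)
    seg_vec = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_dir = seg_vec / seg_len[:, None]
    seg_start_s = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]

    nz, ny, nx = grid.shape
    yc = grid.axis_centers(1)
    xc = grid.axis_centers(2)
    Y, X = np.meshgrid(yc, xc, indexing="ij")

    radial = np.full(grid.shape, np.inf, dtype=np.float32)
    arcpos = np.zeros(grid.shape, dtype=np.float32)

    zc_all = grid.axis_centers(0)
    for z0 in range(0, nz, chunk):
        z1 = min(z0 + chunk, nz)
        zc = zc_all[z0:z1]
        # voxel centers for this chunk: (nzc, ny, nx, 3)
        P = np.empty((z1 - z0, ny, nx, 3), dtype=float)
        P[..., 0] = zc[:, None, None]
        P[..., 1] = Y[None]
        P[..., 2] = X[None]
        best_r = np.full(P.shape[:3], np.inf)
        best_s = np.zeros(P.shape[:3])
        for a, u, L, s0 in zip(pts[:-1], seg_dir, seg_len, seg_start_s):
            rel = P - a
            t = rel @ u
            inside = (t >= 0.0) & (t <= L)
            perp = rel - t[..., None] * u
            r = np.linalg.norm(perp, axis=-1)
            r = np.where(inside, r, np.inf)
            take = r < best_r
            best_s = np.where(take, s0 + np.clip(t, 0.0, L), best_s)
            best_r = np.where(take, r, best_r)
        # bridge interior vertices (outside of bends) with spherical joints
        for vi in range(1, len(pts) - 1):
            r = np.linalg.norm(P - pts[vi], axis=-1)
            take = r < best_r
            best_s = np.where(take, seg_start_s[vi], best_s)
            best_r = np.where(take, r, best_r)
        radial[z0:z1] = best_r
        arcpos[z0:z1] = best_s
    return radial, arcpos


def _check_fibre_bounds(spec: FibreSpec, grid: GridSpec) -> None:
    pts = spec.centerline
    r = spec.fibre_diameter_um / 2.0
    # per-segment bounding box of a flat-capped cylinder: transverse padding
    # is r * sqrt(1 - u_ax^2) along each axis; interior vertices get full r
    seg_dir = np.diff(pts, axis=0)
    seg_dir = seg_dir / np.linalg.norm(seg_dir, axis=1, keepdims=True)
    pad = r * np.sqrt(np.clip(1.0 - seg_dir**2, 0.0, 1.0))
    lo = np.minimum(pts[:-1] - pad, pts[1:] - pad).min(axis=0)
    hi = np.maximum(pts[:-1] + pad, pts[1:] + pad).max(axis=0)
    if len(pts) > 2:
        lo = np.minimum(lo, (pts[1:-1] - r).min(axis=0))
        hi = np.maximum(hi, (pts[1:-1] + r).max(axis=0))
    for ax in range(3):
        margin = grid.voxel_size[ax]
        ax_lo = grid.origin[ax] + margin
        ax_hi = grid.origin[ax] + grid.extent_um[ax] - margin
        if lo[ax] < ax_lo - 1e-9 or hi[ax] > ax_hi + 1e-9:
            raise PhantomBoundsError(
                f"fibre exceeds volume bounds along the {_axis_name(ax)} axis: "
                f"needs [{lo[ax]:.3f}, {hi[ax]:.3f}] µm, available "
                f"[{ax_lo:.3f}, {ax_hi:.3f}] µm"
            )


def _axis_name(ax: int) -> str:
    return ("plane", "row", "col")[ax]


def build_fibre_phantom(spec: FibreSpec, grid: GridSpec) -> tuple[LabelVolume, GroundTruth]:
    """Rasterize one myelinated fibre into a label volume.

    Voxels whose centers lie within d/2 of the centerline are labelled axon;
    within (d/2, D/2] myelin.  Ground-truth volumes come from voxel counts
    times the voxel volume.
    """
    _check_fibre_bounds(spec, grid)
    radial, _ = _polyline_fields(grid, spec.centerline)
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[radial <= spec.fibre_diameter_um / 2.0] = spec.myelin_label
    labels[radial <= spec.axon_diameter_um / 2.0] = spec.axon_label
    vol = LabelVolume(labels, grid)
    truth = GroundTruth(
        fibres=[
            FibreTruth(
                axon_diameter_um=spec.axon_diameter_um,
                fibre_diameter_um=spec.fibre_diameter_um,
                g=spec.g_true,
                axon_label=spec.axon_label,
                myelin_label=spec.myelin_label,
                length_um=spec.length_um,
            )
        ],
        meta={"centerline_um": spec.centerline.tolist()},
    ).with_volumes_from(vol)
    return vol, truth


def build_node_phantom(
    fibre: FibreSpec, node: NodeSpec, grid: GridSpec
) -> tuple[LabelVolume, GroundTruth]:
    """Rasterize a fibre with a nodal gap and terminating paranodal lamellae.

    The node is centred on the centerline midpoint (by arc length).  Myelin
    is absent within the gap.  Within each paranode, lamella ``i`` (0 =
    innermost) is a shell of radius ``d/2 + (i + 0.5) * period`` (thickness
    half a period) whose node-side end sits at axial offset
    ``gap/2 + i * paranode_length / n`` -- the innermost lamella reaches
    closest to the node.
    """
    node.validate_against(fibre)
    _check_fibre_bounds(fibre, grid)
    radial, arcpos = _polyline_fields(grid, fibre.centerline)
    s_mid = fibre.length_um / 2.0
    axial = np.abs(arcpos - s_mid)  # axial distance from node center

    d2 = fibre.axon_diameter_um / 2.0
    D2 = fibre.fibre_diameter_um / 2.0
    half_gap = node.gap_length_um / 2.0
    pn_end = half_gap + node.paranode_length_um
    n = node.n_lamellae_per_side
    period = node.lamellar_period_um
    step = node.paranode_length_um / n

    labels = np.zeros(grid.shape, dtype=np.uint8)
    in_fibre = radial <= D2
    internode = in_fibre & (axial > pn_end)
    labels[internode & (radial > d2)] = fibre.myelin_label

    paranode = in_fibre & (axial > half_gap) & (axial <= pn_end)
    # shell i spans radii [d/2 + i*p, d/2 + (i+0.5)*p]: half-period-wide
    # bands separated by half-period gaps, the innermost flush with the axon
    for i in range(n):
        r_lo = d2 + i * period
        r_hi = d2 + (i + 0.5) * period
        reach = half_gap + i * step  # node-side end of lamella i
        shell = paranode & (radial > r_lo) & (radial <= r_hi) & (axial >= reach)
        labels[shell] = node.loop_label

    labels[radial <= d2] = fibre.axon_label

    vol = LabelVolume(labels, grid)
    # axial position (arc length from node center) where all n lamellae are
    # present: the far end of the paranode.
    truth = GroundTruth(
        fibres=[
            FibreTruth(
                axon_diameter_um=fibre.axon_diameter_um,
                fibre_diameter_um=fibre.fibre_diameter_um,
                g=fibre.g_true,
                axon_label=fibre.axon_label,
                myelin_label=fibre.myelin_label,
                length_um=fibre.length_um,
            )
        ],
        meta={
            "centerline_um": fibre.centerline.tolist(),
            "node": {
                "gap_length_um": node.gap_length_um,
                "n_lamellae_per_side": n,
                "lamellar_period_um": period,
                "paranode_length_um": node.paranode_length_um,
                "gap_axial_interval_um": [s_mid - half_gap, s_mid + half_gap],
                "full_lamellae_axial_offset_um": pn_end - 0.5 * step,
            },
        },
    ).with_volumes_from(vol)
    return vol, truth


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------

def add_fiducials(
    labels: LabelVolume,
    n_somata: int,
    n_nuclei: int,
    rng_seed: int,
    soma_semi_axes_um: tuple[float, float] = (1.5, 3.0),
    nucleus_semi_axes_um: tuple[float, float] = (0.6, 1.2),
    max_retries: int = 1000,
) -> tuple[LabelVolume, list[Fiducial]]:
    """Place ellipsoidal soma/nucleus blobs without overlapping existing labels.

    Semi-axes are drawn uniformly from the given (min, max) range per axis;
    placement is bounded rejection sampling, reproducible for a fixed seed.
    """
    if n_somata < 0 or n_nuclei < 0:
        raise ValueError("fiducial counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    data = labels.data.copy()
    grid = labels.grid
    fiducials: list[Fiducial] = []
    jobs = [(SOMA, soma_semi_axes_um)] * n_somata + [(NUCLEUS, nucleus_semi_axes_um)] * n_nuclei
    zc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    xc = grid.axis_centers(2)
    for material, (ax_min, ax_max) in jobs:
        placed = False
        for _ in range(max_retries):
            semi = rng.uniform(ax_min, ax_max, size=3)
            lo = np.asarray(grid.origin) + semi
            hi = np.asarray(grid.origin) + np.asarray(grid.extent_um) - semi
            if np.any(hi <= lo):
                continue
            center = rng.uniform(lo, hi)
            ez = ((zc - center[0]) / semi[0]) ** 2
            ey = ((yc - center[1]) / semi[1]) ** 2
            ex = ((xc - center[2]) / semi[2]) ** 2
            inside = (
                ez[:, None, None] + ey[None, :, None] + ex[None, None, :]
            ) <= 1.0
            if not inside.any():
                continue
            if np.any(data[inside] != BACKGROUND):
                continue
            data[inside] = material
            fiducials.append(
                Fiducial(
                    center_um=tuple(float(c) for c in center),
                    material=MATERIALS[material],
                    semi_axes_um=tuple(float(s) for s in semi),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {MATERIALS[material]} fiducial without overlap "
                f"after {max_retries} retries"
            )
    return LabelVolume(data, grid, dict(labels.materials)), fiducials


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _resample_labels_nearest(labels: LabelVolume, out_grid: GridSpec) -> np.ndarray:
    """Nearest-neighbour material lookup at the centers of ``out_grid`` voxels."""
    if out_grid == labels.grid:
        return labels.data.copy()
    idx = [
        np.round(
            (out_grid.axis_centers(ax) - labels.grid.origin[ax])
            / labels.grid.voxel_size[ax]
            - 0.5
        ).astype(int)
        for ax in range(3)
    ]
    valid = [np.clip(i, 0, labels.grid.shape[ax] - 1) for ax, i in enumerate(idx)]
    out = labels.data[np.ix_(valid[0], valid[1], valid[2])].copy()
    # outside the source volume -> background
    for ax, i in enumerate(idx):
        bad = (i < 0) | (i >= labels.grid.shape[ax])
        if bad.any():
            sl = [slice(None)] * 3
            sl[ax] = bad
            out[tuple(sl)] = BACKGROUND
    return out


def render_em(
    labels: LabelVolume,
    em_grid: GridSpec | None = None,
    contrast_map: dict[int, float] | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    out_range: tuple[float, float] = (0.0, 255.0),
) -> ImageStack:
    """Render a label volume as an EM-like stack.

    Labels are resampled to ``em_grid`` (nearest-neighbour), each material
    gets its mean intensity from ``contrast_map``, Gaussian noise of
    ``noise_sd`` is added and the result clipped to ``out_range``.  The
    contrast map must satisfy myelin < axon < background.
    """
    contrast = dict(DEFAULT_EM_CONTRAST)
    if contrast_map:
        contrast.update(contrast_map)
    if not contrast[MYELIN] < contrast[AXON] < contrast[BACKGROUND]:
        raise ValueError("EM contrast must satisfy myelin < axon < background")
    if em_grid is None:
        em_grid = labels.grid
    mat = _resample_labels_nearest(labels, em_grid)
    lut = np.zeros(max(contrast) + 1, dtype=np.float32)
    for i, v in contrast.items():
        lut[i] = v
    img = lut[mat]
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    np.clip(img, out_range[0], out_range[1], out=img)
    return ImageStack(img, em_grid, modality="em")


def render_lm(
    labels: LabelVolume,
    psf: PSFModel,
    lm_grid: GridSpec | None = None,
    rng_seed: int = 0,
    photons_per_unit: float | None = None,
    gaussian_sd: float = 0.0,
) -> ImageStack:
    """Render myelin-dye and nuclear-dye channels as an LM-like stack.

    The myelin channel sources from myelin + paranodal-loop labels, the
    nuclear channel from nucleus labels.  Each binary source is convolved
    with the separable Gaussian PSF on the label grid, trilinearly resampled
    to ``lm_grid``, then Poisson (``photons_per_unit``) and Gaussian
    (``gaussian_sd``) noise are applied.  With fwhm = 0, matched grids and no
    noise the output equals the binarized source.
    """
    if lm_grid is None:
        lm_grid = labels.grid
    rng = np.random.default_rng(rng_seed)
    sources = {
        "myelin": labels.mask(MYELIN) | labels.mask(LOOP),
        "nuclei": labels.mask(NUCLEUS),
    }
    sigmas = psf.sigmas_vox(labels.grid.voxel_size)
    channels = []
    for name, mask in sources.items():
        src = mask.astype(np.float32)
        if any(s > 0 for s in sigmas):
            src = ndimage.gaussian_filter(src, sigma=sigmas)
        if lm_grid == labels.grid:
            out = src
        else:
            coords = np.meshgrid(
                *[
                    (lm_grid.axis_centers(ax) - labels.grid.origin[ax])
                    / labels.grid.voxel_size[ax]
                    - 0.5
                    for ax in range(3)
                ],
                indexing="ij",
            )
            out = ndimage.map_coordinates(
                src, np.stack([c.ravel() for c in coords]), order=1, mode="constant", cval=0.0
            ).reshape(lm_grid.shape).astype(np.float32)
        if photons_per_unit:
            out = rng.poisson(np.maximum(out, 0.0) * photons_per_unit).astype(
                np.float32
            ) / photons_per_unit
        if gaussian_sd > 0:
            out = out + rng.normal(0.0, gaussian_sd, size=out.shape).astype(np.float32)
        channels.append(out)
    return ImageStack(
        np.stack(channels),
        lm_grid,
        modality="lm",
        channel_names=tuple(sources),
    )


def straight_fibre(
    d_um: float,
    D_um: float,
    length_um: float,
    grid: GridSpec,
    axis: int = 0,
) -> FibreSpec:
    """Convenience: a straight fibre along ``axis`` centred in ``grid``."""
    c = grid.center_um()
    a, b = c.copy(), c.copy()
    a[axis] -= length_um / 2.0
    b[axis] += length_um / 2.0
    return FibreSpec(np.stack([a, b]), axon_diameter_um=d_um, fibre_diameter_um=D_um)
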