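"""Digital re-sectioning of anisotropic stacks.

Arbitrary-plane multiplanar reslicing (trilinear, physically calibrated),
centerline-orthogonal cross-sections with a minimal-twist frame, and
physical-thickness-matched projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grids import GridSpec, ImageStack


@dataclass(frozen=True)
class PlaneSpec:
    """Oriented sampling plane in physical space.

    Vectors are ``(z, y, x)`` components in µm.  ``normal`` and ``up`` must
    be orthonormal (within 1e-9).  Output rows run along ``up``, columns
    along ``cross(normal, up)``; the plane ``origin`` maps to the image
    center.
    """

    origin: tuple[float, float, float]
    normal: tuple[float, float, float]
    up: tuple[float, float, float]
    pixel_size_um: float
    extent_um: tuple[float, float]  # (height, width)

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        u = np.asarray(self.up, dtype=float)
        if (
            abs(np.linalg.norm(n) - 1) > 1e-9
            or abs(np.linalg.norm(u) - 1) > 1e-9
            or abs(float(n @ u)) > 1e-9
        ):
            raise ValueError("normal and up must be orthonormal unit vectors")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("extent_um components must be > 0")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.asarray(self.normal, dtype=float)
        u = np.asarray(self.up, dtype=float)
        v = np.cross(n, u)
        return n, u, v

    @classmethod
    def axis_aligned(
        cls, grid: GridSpec, axis: int, index: int, pixel_size_um: float | None = None
    ) -> "PlaneSpec":
        """Plane coincident with stored slice ``index`` along ``axis``."""
        center = grid.center_um()
        center[axis] = grid.axis_centers(axis)[index]
        normal = np.zeros(3)
        normal[axis] = 1.0
        in_plane = [a for a in range(3) if a != axis]
        up = np.zeros(3)
        up[in_plane[0]] = 1.0
        px = pixel_size_um if pixel_size_um is not None else grid.voxel_size[in_plane[1]]
        extent = (
            grid.extent_um[in_plane[0]],
            grid.extent_um[in_plane[1]],
        )
        return cls(
            origin=tuple(center),
            normal=tuple(normal),
            up=tuple(up),
            pixel_size_um=px,
            extent_um=extent,
        )


@dataclass
class Reslice:
    """Resampled 2-D section with an out-of-volume validity mask."""

    image: np.ndarray
    valid: np.ndarray
    pixel_size_um: float
    plane: PlaneSpec


def _sample_volume(
    stack: ImageStack, points_um: np.ndarray, fill: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples of a 3-D stack at physical points ``(..., 3)``."""
    idx = stack.grid.physical_to_index(points_um)
    shape = np.asarray(stack.grid.shape)
    eps = 1e-9
    valid = np.all((idx >= -eps) & (idx <= shape - 1 + eps), axis=-1)
    # clip so border samples are not lost to floating-point dust; genuinely
    # out-of-volume samples are overwritten with the fill value below
    coords = np.moveaxis(np.clip(idx, 0, shape - 1), -1, 0).reshape(3, -1)
    values = ndimage.map_coordinates(
        stack.data.astype(float), coords, order=1, mode="nearest"
    ).reshape(points_um.shape[:-1])
    return np.where(valid, values, fill), valid


def multiplanar_reslice(stack: ImageStack, plane: PlaneSpec, fill: float = 0.0) -> Reslice:
    """Resample the stack on an arbitrary oriented plane.

    Trilinear interpolation at physical sample points; samples outside the
    interpolable volume are set to ``fill`` and flagged invalid.
    """
    if stack.data.ndim != 3:
        raise ValueError("multiplanar_reslice requires a single-channel stack")
    _, u, v = plane.basis()
    px = plane.pixel_size_um
    h = max(int(round(plane.extent_um[0] / px)), 1)
    w = max(int(round(plane.extent_um[1] / px)), 1)
    r = (np.arange(h) - (h - 1) / 2.0) * px
    c = (np.arange(w) - (w - 1) / 2.0) * px
    pts = (
        np.asarray(plane.origin)
        + r[:, None, None] * u[None, None, :]
        + c[None, :, None] * v[None, None, :]
    )
    values, valid = _sample_volume(stack, pts, fill)
    values = np.where(valid, values, fill)
    return Reslice(image=values, valid=valid, pixel_size_um=px, plane=plane)


@dataclass
class OrthogonalSections:
    """Stack of centerline-orthogonal cross-sections."""

    sections: np.ndarray          # (n_sections, H, W)
    valid: np.ndarray             # matching boolean masks
    positions_um: np.ndarray      # arc-length of each section
    planes: list[PlaneSpec]
    pixel_size_um: float


def _resample_polyline(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform arc-length resampling; returns (points, arc positions)."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = np.arange(0.0, total + 1e-12, spacing)
    out = np.empty((len(targets), 3))
    for ax in range(3):
        out[:, ax] = np.interp(targets, s, pts[:, ax])
    return out, targets


def orthogonal_sections(
    stack: ImageStack,
    centerline: np.ndarray,
    spacing_um: float,
    template: PlaneSpec,
    fill: float = 0.0,
) -> OrthogonalSections:
    """One reslice per arc-length step, normal to the local tangent.

    Tangents are central differences of the resampled centerline; the
    in-plane up vector is parallel-transported between consecutive sections
    to minimize twist.
    """
    centerline = np.asarray(centerline, dtype=float)
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    total = float(np.sum(np.linalg.norm(np.diff(centerline, axis=0), axis=1)))
    if total < spacing_um:
        raise ValueError(
            f"centerline length {total:.3f} µm shorter than spacing {spacing_um} µm"
        )
    pts, positions = _resample_polyline(centerline, spacing_um)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    up = np.asarray(template.up, dtype=float)
    sections, valids, planes = [], [], []
    for p, t in zip(pts, tangents):
        u = up - (up @ t) * t
        norm = np.linalg.norm(u)
        if norm < 1e-9:  # tangent (near) parallel to transported up: restart frame
            alt = np.eye(3)[np.argmin(np.abs(t))]
            u = alt - (alt @ t) * t
            norm = np.linalg.norm(u)
        u /= norm
        up = u
        plane = replace(template, origin=tuple(p), normal=tuple(t), up=tuple(u))
        rs = multiplanar_reslice(stack, plane, fill=fill)
        sections.append(rs.image)
        valids.append(rs.valid)
        planes.append(plane)
    return OrthogonalSections(
        sections=np.stack(sections),
        valid=np.stack(valids),
        positions_um=positions,
        planes=planes,
        pixel_size_um=template.pixel_size_um,
    )


@dataclass(frozen=True)
class ProjectionSpec:
    """Window of consecutive sections to reduce into one projection."""

    start: int
    count: int
    section_thickness_um: float
    reducer: str = "mean"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be > 0")
        if self.reducer not in ("mean", "max"):
            raise ValueError("reducer must be 'mean' or 'max'")

    @property
    def thickness_um(self) -> float:
        return self.count * self.section_thickness_um


def project(stack: ImageStack, spec: ProjectionSpec) -> tuple[np.ndarray, float]:
    """Reduce a window of sections; returns (2-D image, physical thickness)."""
    if stack.data.ndim != 3:
        raise ValueError("project requires a single-channel stack")
    n_planes = stack.data.shape[0]
    if spec.start < 0 or spec.start + spec.count > n_planes:
        raise ValueError(
            f"window [{spec.start}, {spec.start + spec.count}) outside stack of "
            f"{n_planes} planes"
        )
    window = stack.data[spec.start : spec.start + spec.count]
    image = window.mean(axis=0) if spec.reducer == "mean" else window.max(axis=0)
    return image, spec.thickness_um


def match_projection_thickness(t_ref_um: float, t_other_um: float) -> tuple[int, float]:
    """Largest section count whose total does not exceed a reference thickness.

    Returns ``(n_other, achieved_thickness)`` with
    ``n_other = floor(t_ref / t_other)``.  The floor dialect is deliberate:
    matching a 2.7 µm reference with 0.08 µm sections yields 33 sections
    (2.64 µm), not the nearest count of 34.
    """
    if t_ref_um <= 0 or t_other_um <= 0:
        raise ValueError("thicknesses must be > 0")
    n = int(math.floor(t_ref_um / t_other_um + 1e-12))
    if n == 0:
        raise ValueError(
            f"sections of {t_other_um} µm are thicker than the reference "
            f"{t_ref_um} µm; no projection possible"
        )
    return n, n * t_other_um
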