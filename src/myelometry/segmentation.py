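"""Contrast-gradient-bounded region growing and label measurement.

The grower emulates an interactive "blow"-style polygon-expansion gesture:
starting from a seed pixel, the region expands by repeated one-pixel
dilation, accepting a pixel iff its intensity stays within a tolerance band
around the seed value and its local gradient magnitude stays below a
threshold.  The accepted set is, by construction, the connected component of
the two-predicate set containing the seed (intersected with a radius cap),
so results are independent of visitation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, ImageStack, LabelVolume, MATERIALS, MYELIN

_STRUCTURES = {
    "face": ndimage.generate_binary_structure(2, 1),       # 4-connected
    "face+edge": ndimage.generate_binary_structure(2, 2),  # 8-connected
}


@dataclass(frozen=True)
class BlowParams:
    """Growth parameters for :func:`blow_segment`.

    ``intensity_tolerance`` is the half-width of the accepted band around the
    seed value; ``gradient_threshold`` the maximum central-difference
    gradient magnitude (intensity units per pixel); ``max_radius_um`` caps
    the physical distance from the seed.
    """

    intensity_tolerance: float
    gradient_threshold: float
    max_radius_um: float = np.inf
    connectivity: str = "face"

    def __post_init__(self) -> None:
        if self.intensity_tolerance <= 0 or self.gradient_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.max_radius_um <= 0:
            raise ValueError("max_radius_um must be > 0")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 'face' or 'face+edge'")


@dataclass
class BlowRegion:
    """Grown 2-D region: boolean mask plus a radius-cap flag."""

    mask: np.ndarray
    capped: bool

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude, per pixel."""
    gy, gx = np.gradient(image.astype(float))
    return np.hypot(gy, gx)


def blow_segment(
    image: np.ndarray,
    seed: tuple[int, int],
    params: BlowParams,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    seed_value: float | None = None,
) -> BlowRegion:
    """Grow a region from ``seed`` on a 2-D slice.

    A pixel is accepted iff ``|I - v| <= intensity_tolerance`` and its
    gradient magnitude is below ``gradient_threshold``, where ``v`` is the
    seed pixel's intensity (or ``seed_value`` when propagating a reference
    band across slices).  Growth stops at the connected component boundary
    or when it reaches ``max_radius_um`` from the seed, in which case the
    region is flagged ``capped`` rather than erroring.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("blow_segment operates on 2-D slices")
    si, sj = int(seed[0]), int(seed[1])
    if not (0 <= si < image.shape[0] and 0 <= sj < image.shape[1]):
        raise IndexError(f"seed {seed} outside slice of shape {image.shape}")
    v = float(image[si, sj]) if seed_value is None else float(seed_value)

    band = np.abs(image.astype(float) - v) <= params.intensity_tolerance
    smooth = gradient_magnitude(image) < params.gradient_threshold
    predicate = band & smooth
    if not predicate[si, sj]:
        return BlowRegion(np.zeros(image.shape, dtype=bool), capped=False)

    ii, jj = np.indices(image.shape)
    dist = np.hypot(
        (ii - si) * pixel_size_um[0], (jj - sj) * pixel_size_um[1]
    )
    within = dist <= params.max_radius_um

    structure = _STRUCTURES[params.connectivity]
    lab, _ = ndimage.label(predicate & within, structure=structure)
    mask = lab == lab[si, sj]
    # capped iff growth was halted by the radius limit rather than by the
    # intensity/gradient predicates
    frontier = ndimage.binary_dilation(mask, structure=structure) & ~mask
    capped = bool(np.any(frontier & predicate & ~within))
    return BlowRegion(mask, capped=capped)


@dataclass
class PropagationResult:
    """Outcome of slice-to-slice propagation."""

    labels: LabelVolume
    start_slice: int
    stop_slice: int | None  # first slice that yielded no usable region
    stop_reason: str | None  # 'empty' | 'capped' | None (reached stack end)
    n_segmented: int


def _next_seed(prev_mask: np.ndarray) -> tuple[int, int]:
    """Previous mask centroid, snapped to the nearest in-mask pixel."""
    ci, cj = ndimage.center_of_mass(prev_mask)
    si, sj = int(round(ci)), int(round(cj))
    si = min(max(si, 0), prev_mask.shape[0] - 1)
    sj = min(max(sj, 0), prev_mask.shape[1] - 1)
    if prev_mask[si, sj]:
        return si, sj
    ii, jj = np.nonzero(prev_mask)
    k = np.argmin((ii - ci) ** 2 + (jj - cj) ** 2)
    return int(ii[k]), int(jj[k])


def propagate_segmentation(
    stack: ImageStack,
    first_mask: np.ndarray,
    params: BlowParams,
    start_slice: int = 0,
    label_id: int = MYELIN,
) -> PropagationResult:
    """Propagate a 2-D mask through the stack, slice by slice.

    Each subsequent slice is seeded at the previous mask's centroid (nearest
    in-mask pixel when the centroid falls outside the mask, e.g. annuli) and
    grown with a band centred on the first slice's mean in-mask intensity.
    Propagation stops at the stack end or at the first slice yielding an
    empty or radius-capped region, which is reported as the stop slice.
    """
    first_mask = np.asarray(first_mask, dtype=bool)
    if not first_mask.any():
        raise ValueError("first_mask must be nonempty")
    if stack.data.ndim != 3:
        raise ValueError("propagate_segmentation requires a single-channel stack")
    if first_mask.shape != stack.data.shape[1:]:
        raise ValueError("first_mask shape must match stack slices")

    pixel = (stack.grid.voxel_size[1], stack.grid.voxel_size[2])
    reference = float(stack.data[start_slice][first_mask].mean())
    out = np.zeros(stack.data.shape, dtype=np.uint8)
    out[start_slice][first_mask] = label_id
    prev = first_mask
    stop_slice: int | None = None
    stop_reason: str | None = None
    n = 1
    for k in range(start_slice + 1, stack.data.shape[0]):
        seed = _next_seed(prev)
        region = blow_segment(
            stack.data[k], seed, params, pixel_size_um=pixel, seed_value=reference
        )
        if region.empty or region.capped:
            stop_slice = k
            stop_reason = "empty" if region.empty else "capped"
            break
        out[k][region.mask] = label_id
        prev = region.mask
        n += 1
    materials = {0: "background", label_id: MATERIALS.get(label_id, f"material_{label_id}")}
    return PropagationResult(
        labels=LabelVolume(out, stack.grid, materials),
        start_slice=start_slice,
        stop_slice=stop_slice,
        stop_reason=stop_reason,
        n_segmented=n,
    )


@dataclass
class MeasureResult:
    """Per-material voxel counts/volumes and per-slice areas."""

    totals: pd.DataFrame      # material_id, material, voxel_count, volume_um3
    slice_areas: pd.DataFrame  # plane, material_id, material, area_um2


def measure_labels(labels: LabelVolume) -> MeasureResult:
    """Voxel-count morphometry of a label volume (background excluded).

    Volume = count x voxel volume; per-slice cross-sectional area = in-plane
    count x pixel area.
    """
    grid: GridSpec = labels.grid
    vv = grid.voxel_volume_um3
    pa = grid.pixel_area_um2
    rows = []
    area_rows = []
    ids = sorted(i for i in np.unique(labels.data) if i != 0)
    for i in ids:
        mask = labels.data == i
        count = int(mask.sum())
        name = labels.materials.get(int(i), f"material_{i}")
        rows.append(
            {
                "material_id": int(i),
                "material": name,
                "voxel_count": count,
                "volume_um3": count * vv,
            }
        )
        per_slice = mask.reshape(mask.shape[0], -1).sum(axis=1)
        for k, c in enumerate(per_slice):
            area_rows.append(
                {
                    "plane": k,
                    "material_id": int(i),
                    "material": name,
                    "area_um2": float(c) * pa,
                }
            )
    totals = pd.DataFrame(
        rows, columns=["material_id", "material", "voxel_count", "volume_um3"]
    )
    slice_areas = pd.DataFrame(
        area_rows, columns=["plane", "material_id", "material", "area_um2"]
    )
    return MeasureResult(totals=totals, slice_areas=slice_areas)
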