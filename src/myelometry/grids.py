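"""Core spatial types shared across the package.

Axis conventions
----------------
3-D arrays are indexed ``(plane, row, col)`` -- i.e. ``(z, y, x)``.  Physical
3-D points are ``(z_um, y_um, x_um)`` to match.  2-D image points are
``(y_um, x_um)``.  The physical position of voxel index ``(k, i, j)`` is
``origin + ((k, i, j) + 0.5) * voxel_size`` (voxel-center convention,
0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical material table: id -> name.
MATERIALS: dict[int, str] = {
    0: "background",
    1: "axon",
    2: "myelin",
    3: "paranodal_loop",
    4: "soma",
    5: "nucleus",
}

BACKGROUND, AXON, MYELIN, LOOP, SOMA, NUCLEUS = range(6)

_AXIS_NAMES = ("plane", "row", "col")


class GridError(ValueError):
    """Invalid grid geometry."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D sampling grid with anisotropic physical voxel size.

    Parameters
    ----------
    shape:
        ``(planes, rows, cols)`` -- number of voxels per axis, each >= 1.
    voxel_size:
        Physical spacing in micrometres per axis
        ``(plane_spacing, row_spacing, col_spacing)``; all > 0.
    origin:
        Physical offset in micrometres of the volume corner (the *edge* of
        voxel ``(0, 0, 0)``, not its center).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        origin = tuple(float(v) for v in self.origin)
        if len(shape) != 3 or len(voxel) != 3 or len(origin) != 3:
            raise GridError("GridSpec requires 3 components per field")
        if any(n < 1 for n in shape):
            raise GridError(f"shape components must be >= 1, got {shape}")
        if any(v <= 0 for v in voxel):
            raise GridError(f"voxel sizes must be > 0, got {voxel}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def pixel_area_um2(self) -> float:
        """In-plane pixel area (row_spacing * col_spacing)."""
        return float(self.voxel_size[1] * self.voxel_size[2])

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge length of the volume per axis."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(..., 3)`` to physical µm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical points ``(..., 3)`` µm to fractional voxel indices."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.voxel_size) - 0.5

    def center_um(self) -> np.ndarray:
        """Physical center of the volume."""
        return np.asarray(self.origin) + 0.5 * np.asarray(self.extent_um)

    def permuted(self, order: tuple[int, int, int]) -> "GridSpec":
        """Grid for an axis-permuted volume."""
        return GridSpec(
            shape=tuple(self.shape[a] for a in order),
            voxel_size=tuple(self.voxel_size[a] for a in order),
            origin=tuple(self.origin[a] for a in order),
        )


@dataclass
class ImageStack:
    """3-D intensity volume on a :class:`GridSpec`.

    ``data`` is ``(planes, rows, cols)`` or, for multi-channel stacks,
    ``(channels, planes, rows, cols)`` with ``channel_names`` set.
    """

    data: np.ndarray
    grid: GridSpec
    modality: str = "unknown"
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            spatial = self.data.shape
        elif self.data.ndim == 4:
            if self.channel_names is None:
                self.channel_names = tuple(
                    f"ch{i}" for i in range(self.data.shape[0])
                )
            if len(self.channel_names) != self.data.shape[0]:
                raise GridError("channel_names length must match channel axis")
            spatial = self.data.shape[1:]
        else:
            raise GridError(f"ImageStack data must be 3-D or 4-D, got {self.data.ndim}-D")
        if tuple(spatial) != tuple(self.grid.shape):
            raise GridError(
                f"data spatial shape {tuple(spatial)} != grid shape {self.grid.shape}"
            )

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    def channel(self, name_or_index: str | int) -> "ImageStack":
        """Extract one channel as a plain 3-D stack."""
        if self.data.ndim == 3:
            if name_or_index in (0, self.modality):
                return self
            raise KeyError(name_or_index)
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return ImageStack(self.data[idx], self.grid, modality=self.modality)

    def plane(self, k: int) -> np.ndarray:
        """Single-channel 2-D orthoslice at plane index ``k``."""
        if self.data.ndim != 3:
            raise GridError("plane() requires a single-channel stack")
        return self.data[k]


@dataclass
class LabelVolume:
    """Integer material volume sharing a grid with an :class:`ImageStack`."""

    data: np.ndarray
    grid: GridSpec
    materials: dict[int, str] = field(default_factory=lambda: dict(MATERIALS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError("LabelVolume data must be 3-D")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GridError(
                f"label shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            raise GridError("LabelVolume data must be of integer dtype")
        if self.data.size and self.data.min() < 0:
            raise GridError("label ids must be non-negative")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.materials)
        if missing:
            raise GridError(f"label ids {sorted(missing)} missing from material table")

    def mask(self, material: int | str) -> np.ndarray:
        """Boolean mask of one material (by id or name)."""
        if isinstance(material, str):
            ids = [i for i, n in self.materials.items() if n == material]
            if not ids:
                raise KeyError(material)
            material = ids[0]
        return self.data == material

    def counts(self) -> dict[int, int]:
        """Voxel count per present non-background id."""
        ids, counts = np.unique(self.data, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
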