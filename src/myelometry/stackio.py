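"""Reading and writing stacks, labels, ground truth and measurement tables.

Image and label volumes go to multi-page TIFF.  Physical voxel sizes are
recorded both in the TIFF description (JSON) and in OME-style resolution
tags; a ``<name>.json`` sidecar is written as well so metadata survives
tools that strip descriptions.  Reading requires voxel-size metadata from
one of those sources and fails loudly otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import GridSpec, ImageStack, LabelVolume, MATERIALS
from .phantom import Fiducial, FibreTruth, GroundTruth, ModalityTransform


class MissingVoxelSizeError(ValueError):
    """TIFF carries no voxel-size metadata and no sidecar was found."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _meta_dict(stack: ImageStack) -> dict:
    return {
        "voxel_size_um": list(stack.grid.voxel_size),
        "origin_um": list(stack.grid.origin),
        "modality": stack.modality,
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
    }


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write an :class:`ImageStack` as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    meta = _meta_dict(stack)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        description=json.dumps(meta),
        resolution=(1.0 / stack.grid.voxel_size[2], 1.0 / stack.grid.voxel_size[1]),
        resolutionunit="NONE",
    )
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    2-D TIFFs are read as single-plane stacks.  Voxel sizes come from the
    embedded description or the ``.json`` sidecar; a missing voxel size is
    an explicit error demanding the sidecar.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = None
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and "voxel_size_um" in parsed:
                meta = parsed
        except json.JSONDecodeError:
            meta = None
    if meta is None and _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if meta is None or "voxel_size_um" not in meta:
        raise MissingVoxelSizeError(
            f"{path} has no voxel-size metadata; provide a '{_sidecar(path).name}' "
            "sidecar with 'voxel_size_um'"
        )
    if data.ndim == 2:
        data = data[None]
    channel_names = meta.get("channel_names")
    spatial = data.shape[1:] if data.ndim == 4 else data.shape
    grid = GridSpec(
        shape=tuple(int(n) for n in spatial),
        voxel_size=tuple(float(v) for v in meta["voxel_size_um"]),
        origin=tuple(float(v) for v in meta.get("origin_um", (0, 0, 0))),
    )
    return ImageStack(
        data,
        grid,
        modality=meta.get("modality", "unknown"),
        channel_names=tuple(channel_names) if channel_names else None,
    )


def write_labels(path: str | Path, labels: LabelVolume) -> Path:
    """Write labels as integer TIFF plus a JSON material-table sidecar."""
    path = Path(path)
    meta = {
        "voxel_size_um": list(labels.grid.voxel_size),
        "origin_um": list(labels.grid.origin),
        "materials": {str(k): v for k, v in labels.materials.items()},
    }
    tifffile.imwrite(path, labels.data, description=json.dumps(meta))
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = None
    if (meta is None or "voxel_size_um" not in meta) and _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if meta is None or "voxel_size_um" not in meta:
        raise MissingVoxelSizeError(f"{path} has no voxel-size metadata or sidecar")
    if data.ndim == 2:
        data = data[None]
    grid = GridSpec(
        shape=data.shape,
        voxel_size=tuple(float(v) for v in meta["voxel_size_um"]),
        origin=tuple(float(v) for v in meta.get("origin_um", (0, 0, 0))),
    )
    materials = {int(k): v for k, v in meta.get("materials", {}).items()} or dict(MATERIALS)
    return LabelVolume(data, grid, materials)


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "fibres": [dataclasses.asdict(f) for f in truth.fibres],
        "volumes_um3": truth.volumes_um3,
        "fiducials": [dataclasses.asdict(f) for f in truth.fiducials],
        "transform": dataclasses.asdict(truth.transform) if truth.transform else None,
        "meta": truth.meta,
    }


def ground_truth_from_dict(d: dict) -> GroundTruth:
    transform = d.get("transform")
    return GroundTruth(
        fibres=[FibreTruth(**f) for f in d.get("fibres", [])],
        volumes_um3=d.get("volumes_um3", {}),
        fiducials=[
            Fiducial(
                center_um=tuple(f["center_um"]),
                material=f["material"],
                semi_axes_um=tuple(f["semi_axes_um"]),
            )
            for f in d.get("fiducials", [])
        ],
        transform=(
            ModalityTransform(
                translation=tuple(transform["translation"]),
                scale=tuple(transform["scale"]),
                rotation_deg=transform["rotation_deg"],
            )
            if transform
            else None
        ),
        meta=d.get("meta", {}),
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ground_truth_to_dict(truth), indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return ground_truth_from_dict(json.loads(Path(path).read_text()))


def write_fiducials_csv(path: str | Path, fiducials: list[Fiducial]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "x_um": f.center_um[2],
                "y_um": f.center_um[1],
                "z_um": f.center_um[0],
                "material": f.material,
            }
            for f in fiducials
        ],
        columns=["x_um", "y_um", "z_um", "material"],
    ).to_csv(path, index=False)
    return path
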