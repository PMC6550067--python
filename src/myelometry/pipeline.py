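"""End-to-end synthetic correlation experiment, stage by stage.

Every stage is a pure function of (inputs on disk, config, seed): rerunning
a stage with identical inputs reproduces its outputs byte-identically
(timestamps are deliberately never written).  Per-stage randomness is
derived from the single config seed via named ``SeedSequence`` spawns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DOCUMENTED_DEFAULTS
from .grids import AXON, MYELIN, GridSpec, ImageStack, LabelVolume
from .morphometry import (
    MeasurementError,
    compare_gratio_groups,
    g_ratio_area,
    g_ratio_diameter,
    g_ratio_volume,
    line_scan,
    pairs_to_dataframe,
    profile_to_diameters,
)
from .phantom import (
    FibreSpec,
    ModalityTransform,
    NodeSpec,
    PSFModel,
    add_fiducials,
    build_fibre_phantom,
    build_node_phantom,
    render_em,
    render_lm,
    straight_fibre,
)
from .registration import (
    CorrespondenceSet,
    compute_shifts,
    correspondences_to_dataframe,
    shift_trend,
)
from .segmentation import BlowParams, blow_segment, measure_labels, propagate_segmentation
from .stackio import (
    read_ground_truth,
    read_labels,
    read_stack,
    write_fiducials_csv,
    write_ground_truth,
    write_labels,
    write_stack,
)

log = logging.getLogger("myelometry")


def _stage_seed(cfg: dict, stage: str) -> int:
    """Stable per-stage substream of the run seed."""
    h = int.from_bytes(stage.encode(), "big") % (2**31)
    return int(np.random.SeedSequence([int(cfg["seed"]), h]).generate_state(1)[0])


def log_documented_defaults() -> None:
    for key, note in DOCUMENTED_DEFAULTS.items():
        log.info("default %-28s %s", key, note)


def _em_grid(cfg: dict) -> GridSpec:
    em = cfg["em"]
    n_xy = int(round(em["fov_um"] / em["pixel_um"]))
    return GridSpec(
        shape=(int(em["n_planes"]), n_xy, n_xy),
        voxel_size=(em["plane_spacing_um"], em["pixel_um"], em["pixel_um"]),
    )


def _lm_grid(cfg: dict) -> GridSpec:
    lm = cfg["lm"]
    n_xy = int(round(cfg["em"]["fov_um"] / lm["pixel_um"]))
    return GridSpec(
        shape=(int(lm["n_planes"]), n_xy, n_xy),
        voxel_size=(lm["plane_spacing_um"], lm["pixel_um"], lm["pixel_um"]),
    )


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    """Phantom + EM/LM renders + ground truth on disk."""
    outdir.mkdir(parents=True, exist_ok=True)
    grid = _em_grid(cfg)
    ph = cfg["phantom"]
    fibre = straight_fibre(
        ph["fibre"]["d_um"], ph["fibre"]["D_um"], ph["fibre"]["length_um"], grid
    )
    if ph["node"]:
        node = NodeSpec(
            gap_length_um=ph["node"]["gap_length_um"],
            n_lamellae_per_side=ph["node"].get("n_lamellae_per_side", 10),
            lamellar_period_um=ph["node"].get("lamellar_period_um", 0.016),
            paranode_length_um=ph["node"].get("paranode_length_um", 0.5),
        )
        labels, truth = build_node_phantom(fibre, node, grid)
    else:
        labels, truth = build_fibre_phantom(fibre, grid)
    labels, fiducials = add_fiducials(
        labels,
        int(ph["n_somata"]),
        int(ph["n_nuclei"]),
        rng_seed=_stage_seed(cfg, "fiducials"),
        soma_semi_axes_um=tuple(ph["soma_semi_axes_um"]),
        nucleus_semi_axes_um=tuple(ph["nucleus_semi_axes_um"]),
    )
    truth.fiducials = fiducials
    truth = truth.with_volumes_from(labels)
    tr = cfg["shift"]["transform"]
    truth.transform = ModalityTransform(
        translation=tuple(tr["translation"]),
        scale=tuple(tr["scale"]),
        rotation_deg=tr["rotation_deg"],
    )

    em = render_em(
        labels,
        grid,
        noise_sd=cfg["em"]["noise_sd"],
        rng_seed=_stage_seed(cfg, "render_em"),
    )
    lm = render_lm(
        labels,
        PSFModel.preset(cfg["lm"]["psf"]),
        _lm_grid(cfg),
        rng_seed=_stage_seed(cfg, "render_lm"),
        photons_per_unit=cfg["lm"]["photons_per_unit"],
        gaussian_sd=cfg["lm"]["gaussian_sd"],
    )
    write_labels(outdir / "labels.tif", labels)
    write_stack(outdir / "em.tif", em)
    write_stack(outdir / "lm.tif", lm)
    write_ground_truth(outdir / "ground_truth.json", truth)
    write_fiducials_csv(outdir / "fiducials.csv", fiducials)
    log.info("simulate: %d fibre(s), %d fiducial(s)", len(truth.fibres), len(fiducials))
    return {"labels": "labels.tif", "em": "em.tif", "lm": "lm.tif"}


def _find_fibre_start(em: ImageStack, tol: float) -> tuple[int, tuple[int, int]]:
    """First plane containing a myelin-dark region, and its darkest pixel."""
    mins = em.data.reshape(em.data.shape[0], -1).min(axis=1)
    dark = mins <= mins.min() + tol
    k = int(np.argmax(dark))
    sl = em.data[k]
    seed = np.unravel_index(int(np.argmin(sl)), sl.shape)
    return k, (int(seed[0]), int(seed[1]))


def stage_segment(cfg: dict, outdir: Path) -> dict:
    """Blow-grow myelin and axon through the EM stack."""
    em = read_stack(outdir / "em.tif")
    seg = cfg["segmentation"]
    params = BlowParams(
        intensity_tolerance=seg["intensity_tolerance"],
        gradient_threshold=seg["gradient_threshold"],
        max_radius_um=seg["max_radius_um"],
        connectivity=seg["connectivity"],
    )
    pixel = (em.grid.voxel_size[1], em.grid.voxel_size[2])
    start, seed = _find_fibre_start(em, tol=seg["intensity_tolerance"] / 2)
    myelin0 = blow_segment(em.data[start], seed, params, pixel_size_um=pixel)
    if myelin0.empty:
        raise RuntimeError("could not find a myelin seed region")
    myelin = propagate_segmentation(em, myelin0.mask, params, start_slice=start, label_id=MYELIN)

    from scipy import ndimage as ndi

    lumen = ndi.binary_fill_holes(myelin0.mask) & ~myelin0.mask
    if not lumen.any():
        raise RuntimeError("myelin region has no lumen to seed the axon from")
    ci, cj = ndi.center_of_mass(lumen)
    axon0 = blow_segment(
        em.data[start], (int(round(ci)), int(round(cj))), params, pixel_size_um=pixel
    )
    axon = propagate_segmentation(em, axon0.mask, params, start_slice=start, label_id=AXON)

    merged = np.zeros(em.data.shape, dtype=np.uint8)
    merged[myelin.labels.data == MYELIN] = MYELIN
    merged[axon.labels.data == AXON] = AXON
    labels = LabelVolume(merged, em.grid)
    write_labels(outdir / "segmented.tif", labels)
    info = {
        "start_slice": start,
        "myelin_stop_slice": myelin.stop_slice,
        "myelin_stop_reason": myelin.stop_reason,
        "axon_stop_slice": axon.stop_slice,
        "axon_stop_reason": axon.stop_reason,
    }
    (outdir / "segmentation.json").write_text(json.dumps(info, indent=2))
    log.info("segment: myelin %d slices, axon %d slices", myelin.n_segmented, axon.n_segmented)
    return info


def stage_measure(cfg: dict, outdir: Path) -> dict:
    labels = read_labels(outdir / "segmented.tif")
    res = measure_labels(labels)
    res.totals.to_csv(outdir / "measurements.csv", index=False)
    res.slice_areas.to_csv(outdir / "slice_areas.csv", index=False)
    return {"materials": res.totals["material"].tolist()}


def stage_gratio(cfg: dict, outdir: Path) -> dict:
    """Three g-ratio estimators from the segmented EM data + line scans."""
    em = read_stack(outdir / "em.tif")
    labels = read_labels(outdir / "segmented.tif")
    totals = pd.read_csv(outdir / "measurements.csv")
    areas = pd.read_csv(outdir / "slice_areas.csv")
    n_scans = int(cfg["morphometry"]["n_scans"])
    prom = cfg["morphometry"]["prominence_fraction"]

    myelin = labels.data == MYELIN
    axon = labels.data == AXON
    planes_with_fibre = np.nonzero(myelin.any(axis=(1, 2)) & axon.any(axis=(1, 2)))[0]
    if planes_with_fibre.size == 0:
        raise RuntimeError("no segmented fibre planes; run segment first")

    pairs = []
    n_failed = 0
    scan_planes = np.unique(
        np.linspace(planes_with_fibre[0], planes_with_fibre[-1], n_scans).round().astype(int)
    )
    dy, dx = em.grid.voxel_size[1], em.grid.voxel_size[2]
    for k in scan_planes:
        fibre_mask = myelin[k] | axon[k]
        if not fibre_mask.any():
            continue
        ci, cj = np.asarray(np.nonzero(fibre_mask)).mean(axis=1)
        x_um = (cj + 0.5) * dx
        profile = line_scan(
            em.data[k],
            (0.5 * dy, x_um),
            ((em.data.shape[1] - 0.5) * dy, x_um),
            n_samples=2 * em.data.shape[1],
            pixel_size_um=(dy, dx),
        )
        try:
            pairs.append(
                profile_to_diameters(
                    profile,
                    prominence_fraction=prom,
                    orientation="orthogonal",
                    position_um=k * em.grid.voxel_size[0],
                )
            )
        except MeasurementError:
            n_failed += 1
    if not pairs:
        raise RuntimeError("all line scans failed")
    g_diam = g_ratio_diameter(pairs)

    ax_areas = areas[areas.material == "axon"].set_index("plane")["area_um2"]
    my_areas = areas[areas.material == "myelin"].set_index("plane")["area_um2"]
    common = ax_areas.index.intersection(my_areas.index)
    ca = ax_areas.loc[common].to_numpy()
    CA = ca + my_areas.loc[common].to_numpy()
    keep = (ca > 0) & (CA > ca)
    g_area = g_ratio_area(ca[keep], CA[keep])

    v_axon = float(totals.loc[totals.material == "axon", "volume_um3"].iloc[0])
    v_myelin = float(totals.loc[totals.material == "myelin", "volume_um3"].iloc[0])
    g_vol = g_ratio_volume([v_axon], [v_axon + v_myelin])

    groups = {g.method: g for g in (g_diam, g_area) if g.n >= 2}
    anova = compare_gratio_groups(groups).summary() if len(groups) >= 2 else None

    pairs_to_dataframe(pairs).to_csv(outdir / "gratio_scans.csv", index=False)
    summary = {
        "convention": "area and volume g use sqrt of the ratio (same scale as d/D)",
        "n_scans_requested": n_scans,
        "n_scans_failed": n_failed,
        "methods": {g.method: g.summary() for g in (g_diam, g_area, g_vol)},
        "anova": anova,
    }
    (outdir / "gratio_summary.json").write_text(json.dumps(summary, indent=2))
    log.info(
        "gratio: diameter %.3f, area %.3f, volume %.3f",
        g_diam.mean,
        g_area.mean,
        g_vol.mean,
    )
    return summary


def stage_shift(cfg: dict, outdir: Path) -> dict:
    """Landmark correspondences through the modality transform + shift stats."""
    truth = read_ground_truth(outdir / "ground_truth.json")
    sh = cfg["shift"]
    rng = np.random.default_rng(_stage_seed(cfg, "shift"))
    fov = cfg["em"]["fov_um"]
    n = int(sh["n_landmarks"])
    lm_pts = rng.uniform(0.0, fov, size=(n, 2))
    classes = ["myelin" if i % 2 else "nucleus" for i in range(n)]
    transform = truth.transform or ModalityTransform()
    em_pts = transform.apply(lm_pts) + rng.normal(0.0, sh["jitter_sd_um"], size=(n, 2))
    cset = CorrespondenceSet(
        lm_points_um=lm_pts,
        em_points_um=em_pts,
        origin_index=0,
        landmark_classes=classes,
    )
    result = compute_shifts(cset, ring_spacing_um=sh["ring_spacing_um"])
    trend = shift_trend(result)
    correspondences_to_dataframe(cset).to_csv(outdir / "correspondences.csv", index=False)
    result.to_dataframe().to_csv(outdir / "shifts.csv", index=False)
    summary = {
        **result.summary(),
        "trend": trend.summary(),
        "ring_spacing_um": sh["ring_spacing_um"],
    }
    (outdir / "shift_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("shift: mean %.3f ± %.3f µm", result.mean_shift_um, result.sd_shift_um)
    return summary


def stage_report(cfg: dict, outdir: Path) -> dict:
    """Aggregate stage outputs + built-in ground-truth checks."""
    truth = read_ground_truth(outdir / "ground_truth.json")
    gratio = json.loads((outdir / "gratio_summary.json").read_text())
    shift = json.loads((outdir / "shift_summary.json").read_text())
    g_true = truth.fibres[0].g if truth.fibres else None
    checks = {}
    if g_true is not None:
        for method, summ in gratio["methods"].items():
            checks[f"g_{method}_within_0.05_of_truth"] = bool(
                abs(summ["mean"] - g_true) <= 0.05
            )
    # outdir is a storage location, not an experiment parameter: leave it out
    # so reports from the same config+seed are byte-identical anywhere
    cfg_no_outdir = {k: v for k, v in cfg.items() if k != "outdir"}
    report = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg_no_outdir,
        "ground_truth_g": g_true,
        "gratio": gratio,
        "shift": shift,
        "checks": checks,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "measure": stage_measure,
    "gratio": stage_gratio,
    "shift": stage_shift,
    "report": stage_report,
}

ALL_CHAIN = ["simulate", "segment", "measure", "gratio", "shift", "report"]


def run_stages(cfg: dict, stages: list[str], outdir: str | Path | None = None) -> dict:
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for name in stages:
        log.info("--- stage %s ---", name)
        results[name] = STAGES[name](cfg, out)
    return results
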