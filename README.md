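# myelometry

Synthetic correlative light/electron-microscopy stacks of myelinated axons,
and the analysis chain used to quantify them: ground-truthed 3-D phantoms
(axon + myelin annulus fibres, nodes of Ranvier with terminating paranodal
lamellae, soma/nucleus fiducials), EM-like and LM-like renders with a
configurable inter-modality distortion, contrast-gradient-bounded region
growing, digital re-sectioning, line-scan g-ratio morphometry (diameter,
cross-sectional-area and volume estimators), lamella counting, and landmark
shift statistics for registration accuracy.

## Layout

| module | what it does |
| --- | --- |
| `myelometry.grids` | `GridSpec` / `ImageStack` / `LabelVolume` core types (voxel-center convention, anisotropic µm voxel sizes) |
| `myelometry.phantom` | fibre/node phantom rasterization, fiducials, EM/LM rendering, modality transform |
| `myelometry.segmentation` | blow-style region growing, slice-to-slice propagation, voxel-count measurement |
| `myelometry.reslice` | multiplanar reslicing, centerline-orthogonal sections, thickness-matched projections |
| `myelometry.morphometry` | line scans, half-amplitude diameters, three g-ratio estimators, lamella counts, one-way ANOVA |
| `myelometry.registration` | finder-grid label arithmetic, concentric-ring assignment, landmark shift + trend analysis |
| `myelometry.stackio` / `config` / `pipeline` / `cli` | TIFF/JSON/CSV I/O, config schema, stage orchestration, CLI |

## CLI

```sh
# full synthetic experiment: simulate -> segment -> measure -> gratio -> shift -> report
myelometry all --seed 42 --outdir out

# individual stages, with dotted-key config overrides
myelometry simulate --set em.noise_sd=5 --set phantom.fibre.d_um=1.4 --outdir out
myelometry gratio --outdir out

# thickness-matched projection of a stack on disk
myelometry reslice out/em.tif --count 33 --thickness 0.08 --out out/proj.tif
```

Configuration is one JSON document (see `myelometry.config.DEFAULT_CONFIG`);
every stage is a pure function of (inputs, config, seed), so reruns are
byte-identical.  Defaults mirror the emulated acquisition geometry: EM
13.8 nm pixels / 80 nm sections / 300 planes, LM 0.068×0.068×0.3 µm voxels /
29 planes, 100 line scans per fibre, 6.5 µm ring spacing.

## Conventions

- 3-D arrays and physical points are ordered `(plane, row, col)` = `(z, y, x)`;
  2-D registration points are `(x, y)`.
- A voxel belongs to a material iff its *center* is inside the analytic
  region, so voxel-count volumes are unbiased against closed forms.
- Area- and volume-based g-ratios take the square root of the respective
  ratio so that all three estimators target the same quantity d/D; this
  convention is recorded in every summary JSON.
- Scans whose edge detection fails raise `MeasurementError` and are skipped
  and counted, never imputed.
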