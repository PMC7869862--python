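# voxcyto

Volumetric histo-cytometry on multichannel 3D microscopy stacks: an open,
tested pipeline that segments intensity channels into labelled 3D objects
("surfaces"), computes per-object statistics (position, volume, mesh
surface area, sphericity, median intensities), measures signed shortest
distances from each cell object to the nearest anatomical target
structure, classifies cells into distance populations
(within < 0.5 µm / surrounding 0.5–20 µm / peripheral > 20 µm), applies
flow-style gating and frequency quantification, and provides
acquisition-throughput metrics. Everything is exercised on synthetic 3D
tissue phantoms with analytic ground truth, so no proprietary software or
external image data is needed.

## Modules

| module | role |
| --- | --- |
| `voxcyto.io_formats` | `VoxelGrid` / `LabelMap` types, OME-TIFF read/write, long-to-wide statistics concatenation, flow-compatible CSV export |
| `voxcyto.synthgen` | seeded phantom generator: spherical-shell "glomeruli", tubular vessels, cells planted at controlled signed distances, deposits, noise; `WT`/`KO` scenario presets |
| `voxcyto.segmentation` | smoothing → threshold → slice-wise hole fill → connected components → optional watershed split → size filter; glomeruli/vessel split by sphericity and volume |
| `voxcyto.objstats` | per-object statistics, marching-cubes surface area, sphericity, 2D roundness |
| `voxcyto.distances` | anisotropy-aware signed Euclidean distance maps, per-object shortest distance, population classification, within-fraction |
| `voxcyto.histocyto` | gates and gating trees, frequencies, positional export, Mann–Whitney U (exact + normal), Welch's t |
| `voxcyto.imagingmetrics` | duration parsing, s/sequence/nL throughput normalisation, signal/background measurement |
| `voxcyto.cli` | config-validated pipeline orchestration, run manifests, run comparison, `voxcyto` CLI |

## CLI

```sh
voxcyto simulate --scenario WT --seed 1 --out phantom/
voxcyto segment phantom/phantom.ome.tif --channel mhc2 --threshold 100 --out labels.ome.tif
voxcyto stats phantom/phantom.ome.tif labels.ome.tif --out stats.csv
voxcyto distances --objects labels_mhc2.ome.tif --targets labels_glomeruli.ome.tif
voxcyto run --scenario KO --seed 7 --outdir runs/ko7     # full pipeline
voxcyto compare runs/wt7 runs/ko7                        # MWU + fractions
voxcyto metrics acquisitions.csv                         # throughput table
```

`voxcyto run` executes simulate → segment → stats → distances → gate →
report, materialising every intermediate artifact plus a `manifest.json`
with content digests; identical config + seed reproduces identical
digests. Configs are YAML validated against a strict schema
(`voxcyto.cli.PipelineConfig`); unknown keys are rejected before any
compute.

## Notes

- Arrays are `(channel, z, y, x)`; physical coordinates are reported as
  `(x, y, z)` µm; voxel centres sit at `(index + 0.5) * voxel_size`.
- The normalisation gate is `d <= 20 µm`, so within (< 0.5) and
  surrounding (0.5–20, closed) compose it exactly; peripheral is > 20.
- Distance maps are signed: negative inside the hole-filled target.
- Deliverables are text-only; phantoms and label maps are generated at
  run/test time.
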