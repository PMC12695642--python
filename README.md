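# pxct

Desk-scale simulation and analysis toolkit for ptychographic X-ray computed
tomography (PXCT) of stained tissue, with an emphasis on radiation-dose
effects: it generates synthetic tissue phantoms that deform as dose
accumulates, simulates phase projections and ptychographic scans, retrieves
phase (difference map + maximum-likelihood refinement), reconstructs rigid
and nonrigid (3D-optical-flow-compensated) tomograms, measures resolution by
Fourier ring/shell correlation with information-bit thresholds, fits the
dose–resolution power law, and scores synapse detectability against ground
truth with census-matching and confusion-matrix procedures.

No external data is required: every fixture is generated programmatically
from explicit seeds.

## Modules

| module | contents |
| --- | --- |
| `pxct.phantom` | tissue phantoms (neurite tubes, organelles, synapse puncta on a pillar support), dose-indexed deformation models, Fermat-spiral scan geometry, annotator-score fixtures |
| `pxct.forward` | phase projection of (deforming) volumes, far-field ptychographic scan simulation with Poisson noise, absorbed-dose model (Gy) |
| `pxct.ptycho` | difference-map retrieval, preconditioned conjugate-gradient ML refinement with probe modes, phase-ramp removal |
| `pxct.tomo` | projection alignment, windowed FBP (Hann / Ram-Lak), interlaced subtomogram splitting, multiresolution 3D optical flow, warp-accumulate nonrigid reconstruction |
| `pxct.metrics` | FRC/FSC curves, 1-bit / ½-bit thresholds, split-half resolution workflow, dose–resolution power-law fit with 95% prediction bands |
| `pxct.synapse` | single-link census building, cross-modality matching, confusion hotspots, annotator QC, confidence-score confusion metrics (P/R/F1/F_β) |
| `pxct.experiments` / `pxct.cli` / `pxct.config` / `pxct.io` | config-driven dose-ladder and scoring-task experiments, CLI, TIFF/HDF5/CSV round trips |

## CLI

```sh
pxct phantom make --out ph.tiff --size 64 --seed 0
pxct acquire --phantom ph.tiff --out projs.h5 --n-projections 96 --subtomos 4
pxct tomo recon --in projs.h5 --out vol.tiff --filter hann --mode nonrigid --subtomos 4
pxct fsc --in projs.h5 --out fsc.csv --mode rigid
pxct fit-powerlaw --points-csv points.csv --out fit.json
pxct synapse census --nodes-csv nodes.csv --out census.json
pxct experiment dose-ladder --config cfg.json --out results/ --seed 0
pxct experiment captcha-sim --config cfg.json --out results/ --seed 0
pxct ptycho reconstruct --scan scan.h5 --out recon.h5 --dm-iters 300 --ml-iters 300
```

## Conventions

- Axis order `(z, y, x)`; rotation axis `z`; the beam at 0° travels along `+x`.
- Positions and resolutions in nm, angles in degrees, dose in Gy,
  displacement fields in voxels.
- Deformation is indexed by the fraction of total delivered dose in `[0, 1]`.
- FSC resolution is reported as half-pitch, `voxel_size / (2 f_cross)`; a
  curve that never crosses its threshold is flagged and reported at the band
  limit `2 × voxel_size`.
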