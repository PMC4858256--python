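# omagperf

Optic nerve head (ONH) perfusion quantification from repeated-B-scan OCT
angiography, for researchers studying microvascular changes in glaucoma
(primary open-angle and normal-tension) and for anyone who needs a fully
synthetic, ground-truthed test bed for OMAG-style processing chains.

The package implements the whole measurement chain and the cohort-level
statistics around it:

1. **Flow signal** (optical microangiography): at each transversal
   location the scanner takes R = 4 consecutive B-scans; static tissue
   gives a stable complex OCT signal while moving blood cells decorrelate
   it, so

   `I_flow(x, z) = 1/(R-1) · Σᵢ |C_{i+1}(x, z) − C_i(x, z)|`

   is a blood-flow contrast, mapped onto the 0–255 display range.
2. **Pre-laminar slab**: gradient-based segmentation of the inner
   limiting membrane and the RPE / anterior lamina cribrosa surface, with
   bit-exact manual overrides; the disc margin is an ellipse fit (RANSAC)
   to the termination points of Bruch's membrane.
3. **En-face angiogram**: maximum intensity projection of flow through
   the slab; vessels detected by a multiscale Hessian (Frangi) filter
   with σ²-normalised derivatives, thresholded into a vessel mask.
4. **Perfusion metrics** inside the disc: flux = mean(F/255) over disc
   pixels, vessel area density = vessel area / disc area, and normalized
   flux = mean(F/255) over vessel pixels only.  They obey the exact
   identity `flux = d·nf + (1−d)·b̄`.
5. **Cohort statistics**: mean ocular perfusion pressure
   (MOPP = ⅔(MAP − IOP)), two-sample sample-size/power calculation,
   three-group ANOVA, POAG-vs-NTG t-tests, univariate regressions, and
   the standard summary tables, driven by a simulator of per-eye records
   with configurable group means/SDs and correlations.

A synthetic-volume generator with full ground truth (vessel masks, layer
surfaces, disc mask, per-voxel decorrelation) makes every stage testable
without any scanner data.

## Worked example

```python
import numpy as np
import omagperf as op
from omagperf.enface import build_enface_maps
from omagperf.segmentation import segment_layers, delineate_disc_margin, prelc_mask

spec = op.make_scene(nx=128, ny=128, nz=160, target_vessel_fraction=0.7,
                     delta=1.0, seed=11)
vol, truth = op.generate_volume(spec)

structural = np.moveaxis(np.abs(vol.data).mean(axis=1), 0, 1)
layers = delineate_disc_margin(structural, segment_layers(structural))
flow = op.scale_to_dynamic_range(op.compute_flow(vol))
maps = build_enface_maps(flow, prelc_mask(layers, spec.nz),
                         disc_mask=layers.disc_mask)
pm = op.compute_perfusion_metrics(maps.mip, maps.vessel_mask, layers.disc_mask)

print(f"disc area        {layers.area_onh_px()} px ({layers.area_onh_mm2():.3f} mm^2)")
print(f"flux             {pm.flux:.3f}")
print(f"vessel density   {pm.vessel_area_density:.3f}  (truth {truth.vessel_fraction:.3f})")
print(f"normalized flux  {pm.normalized_flux:.3f}")
```

prints

```
disc area        5079 px (1.786 mm^2)
flux             0.699
vessel density   0.718  (truth 0.699)
normalized flux  0.929
```

i.e. on a healthy-like scene (70% of the disc perfused, full
decorrelation) the pipeline recovers the generated vessel fraction within
two percentage points, and the disc-averaged flux of 0.699 decomposes
into a vessel fraction of 0.718 carrying a mean in-vessel flow of 0.929
of full scale.  The statistics stage answers design questions directly:

```python
op.sample_size_two_group(0.300, 0.06, 0.15, power=0.80, alpha=0.05)  # -> 28
op.compute_mopp(120, 80, 15)                                         # -> 52.22 mmHg
```

## Command line

Each stage is a subcommand (`omagperf --help`): `simulate volume`,
`simulate cohort`, `flow`, `segment`, `enface`, `vessels`, `metrics`,
`stats`, and `run` (the whole chain with a manifest).  Volumes travel as
multi-page TIFF + JSON sidecar, tables as CSV, configuration as YAML:

```sh
omagperf simulate volume --seed 7 --out scene/
omagperf flow --in scene/ --out flow.tiff
omagperf segment --in scene/ --out layers.json
omagperf run --seed 7 --out full_run/
```

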