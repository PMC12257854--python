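# sclsettle

Quantification of the post-lens **fluid reservoir** during scleral lens wear
from wide-angle anterior-segment OCT radial scans — together with a fully
ground-truthed synthetic eye/lens/scan generator, so the entire measurement
chain can be validated by parameter recovery without any clinical data.

## The problem

A scleral lens vaults the cornea on a saline-filled reservoir. As the lens
settles into the conjunctiva over the first hours of wear, the reservoir
thins; both its thickness and its symmetry matter clinically (optics,
corneal physiology, mechanical touch). `sclsettle` implements the complete
measurement pipeline for 16-mm-wide radial B-scan series:

1. **Segmentation** — the lens back surface and the corneal epithelial front
   surface (the two reservoir boundaries) are extracted from each frame as
   sub-pixel polylines by ridge enhancement plus a minimum-cost-path dynamic
   program with a quadratic smoothness penalty, at a 512 × 512 working
   resolution and mapped back to original coordinates.
2. **Reconstruction** — boundary separation is converted to geometric
   thickness, `T = Δrow · axial_pitch / n_fluid` (optical-path correction,
   default n = 1.336), and the 32 meridional profiles (64 half-meridian
   rays at 5.625°) are assembled into a polar thickness map over the
   12-mm-diameter disc, with nasal/temporal laterality correction.
3. **Regionization** — the map is summarized over 17 regions: a central
   4-mm disc (C) plus mid-peripheral (2–5 mm) and peripheral (5–6 mm)
   annuli, each split into 8 sectors (N, SN, S, ST, T, IT, I, IN).
4. **Settling analysis** — per-eye reductions and percent reductions over
   four hours, the fraction of change completed in the first two hours,
   meridional asymmetry, and the exponential settling fit

   `T(t) = C + (T0 − C) · e^(−t/τ)`

   for which the 2-h fraction obeys the closed form `1/(1 + e^(−120/τ))`.
   Cohort inference uses a repeated-measures ANOVA (time × region within,
   group between) with Greenhouse–Geisser correction and Bonferroni post
   hocs.

The synthetic generator renders radial B-scans of parametric eyes (conicoid
corneas, keratoconic cone bumps, post-graft irregularity) under a two-zone
scleral lens with decentration/tilt, with programmed regional settling
trajectories and speckle-like noise, and records exact ground truth for
every frame, map and region.

## Worked example

```python
import numpy as np
from sclsettle import CohortConfig, SyntheticCohort, ScanProtocol, LensModel
from sclsettle.pipeline import measure_frames

cfg = CohortConfig(
    name="demo", group_label="myopia", n_eyes=1, seed=7,
    lens=LensModel(decentration=(0.0, -0.3), tilt_deg=0.5),
    protocol=ScanProtocol(noise_level=0.3),
)
cohort = SyntheticCohort(cfg)
eye = cohort.eyes[0]
frames, _ = cohort.render_eye_time(eye, 0.0)         # 32 radial B-scans
summary, pmap = measure_frames(frames)               # segment + reconstruct
reg = summary[summary.level == "region"].set_index("region")
truth = cohort.true_region_means(eye, 0.0)
print(f"coverage {pmap.coverage:.3f}")
for lab in ("C", "M-S", "M-I", "P-I"):
    print(f"{lab:4} measured {reg.loc[lab,'mean_um']:6.1f} um   "
          f"true {truth[lab]:6.1f} um")
```

prints (seed 7):

```
coverage 1.000
C    measured  300.1 um   true  300.2 um
M-S  measured  182.8 um   true  182.6 um
M-I  measured  378.4 um   true  378.6 um
P-I  measured  452.1 um   true  452.7 um
```

i.e. the full render → segment → reconstruct → regionize chain recovers the
programmed regional means to ≈ 0.5 µm at the default speckle level, and the
inferior sectors are thicker than the superior ones, as the decentred,
tilted lens geometry dictates.

A command-line pipeline wraps the same stages for on-disk datasets:

```bash
sclsettle generate --config cfg.yaml --out data/ --seed 1
sclsettle measure  data/  --out results/
sclsettle analyze  results/region_table.csv --out results/
sclsettle all      --config cfg.yaml --out run/ --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `sclsettle.geometry` | conicoid cornea, two-zone lens back surface, geometric gap |
| `sclsettle.settling` | exponential settling law and closed-form fractions |
| `sclsettle.cohort` | calibrated ground-truth fields, synthetic cohorts, dataset writer |
| `sclsettle.render` | radial B-scan renderer with speckle and exact ground truth |
| `sclsettle.segmentation` | ridge enhancement + DP boundary extraction |
| `sclsettle.reconstruction` | thickness profiles and polar map assembly |
| `sclsettle.regions` | 17-region scheme and area-weighted summaries |
| `sclsettle.kinetics` | reduction metrics, `ExponentialSettling` model/results |
| `sclsettle.anova` | repeated-measures ANOVA with GG correction |
| `sclsettle.pipeline`, `sclsettle.cli` | orchestration and the `sclsettle` CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
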