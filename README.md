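# lvquant

Quantitative analysis of small-animal cardiac MRI: late-gadolinium-enhancement
(LGE) infarct sizing, global left-ventricular (LV) function, centerline-based
regional wall mechanics with AHA 16-segment reporting, and the group/survival
statistics used in preclinical myocardial-infarction studies.  Everything is
validated against an analytic LV phantom with closed-form ground truth, so the
whole pipeline is testable without any imaging data download.

The intended users are researchers quantifying murine infarct models from
short-axis cine and LGE stacks: the package takes image volumes plus traced
epicardial/endocardial contours as input (contour tracing itself is out of
scope) and produces per-subject infarct, function and regional-wall tables.

## Methods at a glance

- **Infarct threshold.** Hyperenhanced voxels are those with intensity
  strictly above `mean + 5·SD` of a remote septal region of interest (one
  pooled threshold per subject).
- **Transmural infarct volume fraction.** `100 · V_infarct / V_wall`, from
  voxel counts inside the myocardial annulus.
- **Epicardial infarct area.** Each slice is partitioned into 100 equal-angle
  circumferential sectors; a sector is infarct when its infarct transmurality
  strictly exceeds 50%, and contributes its epicardial arc length × slice
  thickness. The fraction is relative to the total epicardial surface.
- **Global function.** Slice-summation (Simpson) cavity volumes from the
  endocardial contours; `EF = 100·(EDV − ESV)/EDV`, `CO = (EDV − ESV)·HR`.
- **Regional wall.** Per slice, a centerline equidistant from both contours
  carries 100 perpendicular chords; chord length is the wall thickness (WTS)
  and wall thickening is `WT = (WTS_ES − WTS_ED)/WTS_ES` (negative WT is a
  valid akinetic/dyskinetic reading). Chords aggregate into the AHA
  16-segment model (6 basal, 6 mid, 4 apical).
- **Statistics.** Kaplan–Meier survival with the log-rank test; one-way ANOVA
  with Dunnett's many-to-one correction; one-within-factor repeated-measures
  ANOVA.

See `docs/methods.md` for the full model description, parameter defaults and
numerical conventions.

## Worked example

Generate a synthetic study (cylindrical LV, fully transmural 90° anterolateral
wedge, the geometric truth being 25% infarct by volume and by area) and
quantify it:

```python
import numpy as np
from lvquant import PhantomSpec, generate_phantom, quantify_infarct, global_function

spec = PhantomSpec(geometry="cylinder", infarct_angle_start=np.pi / 4,
                   infarct_angle_extent=np.pi / 2, seed=7)
study = generate_phantom(spec)

infarct = quantify_infarct(study.lge, study.contours,
                           reference_angle=spec.infarct_angle_start)
gf = global_function(study.contours, heart_rate=spec.heart_rate)
```

which prints (via the obvious f-strings):

```text
threshold            : 299.9 (septal mean 200.9 + 5 x SD 19.8)
infarct volume frac  : 24.7 % (truth 25.0 %)
epicardial area frac : 25.0 %
EDV / ESV            : 113.1 / 59.4 uL
EF                   : 47.4 % (truth 47.4 %)
cardiac output       : 26.8 mL/min
```

The threshold recovers the population value `200 + 5·20 = 300` from the septal
ROI sample; both infarct measures land on the 25% geometric truth; EF matches
the closed-form half-ellipsoid/cylinder truth.

The same pipeline is scriptable from the shell:

```sh
lvquant phantom --config cfg.yaml --out study/
lvquant quantify --lge study/lge.nii --contours study/contours.json --out results/
lvquant stats --survival-csv survival.csv --measurements-csv ef.csv --control MI --out results/
```

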