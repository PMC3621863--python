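# Methods

## The phantom

The left ventricle is modeled as a thick-walled half-ellipsoid of revolution:
cavity radius `a` at the base tapering to the apex over long-axis length `L`,
with a constant-thickness wall. Slices are short-axis planes, index 0 at the
apex, ascending to the base; the endocardial radius at height `h` above the
apex is `a·sqrt(1 − ((L−h)/L)²)`. A `geometry="cylinder"` limit (equal
per-slice radii) is provided because many closed-form identities — e.g. a 90°
fully transmural wedge occupying exactly 25% of wall volume and epicardial
surface — are exact there and make the recovery tests sharp.

End-diastole and end-systole are two static geometries sharing the long axis
(no long-axis shortening, no continuous cine loop); the analysis only ever
uses the two extreme phases. Closed-form truth values never touch the voxel
grid: cavity volume is `(2/3)·π·a²·L` (or `π·a²·L_covered` for the cylinder),
EF/SV/CO follow from the ED/ES pair, and infarct truth integrates exact
annulus-wedge areas over the sliced geometry — which is precisely the
quantity a voxel-based analysis of the same stack estimates.

### Intensity and noise model

Voxel values are deterministic tissue means — blood pool, remote myocardium
(`remote_mean`), infarct wedge (`remote_mean · infarct_enhancement`) — plus
additive Gaussian noise. `remote_mean`/`remote_sd` parameterize the remote
myocardial intensity distribution that the 5-SD threshold is calibrated
against; the realized noise SD defaults to `remote_sd` so a septal ROI sample
estimates exactly that distribution, and can be set independently (including
to zero, which makes every myocardial voxel exactly `remote_mean` — the basis
of several exactness tests). Noise is additive Gaussian, not Rician:
magnitude-MRI realism is explicitly not a goal of the phantom.

The infarct wedge spans a half-open angular interval and extends from the
endocardium to a fraction `infarct_transmurality` of the wall depth.  The
septal ROI is a 30° mid-wall annular wedge placed diametrically opposite the
wedge centre on every slice; generation fails if the two overlap (the remote
ROI must stay remote), if any stated length is non-positive, or if the wall
is thinner than two pixels (the grid cannot resolve it).

The LV axis is deliberately offset from the image-grid centre by an
irrational sub-pixel amount. A lattice-aligned axis puts voxel centres
exactly on wedge/sector boundary rays, where membership becomes a 1-ulp
coin-flip between the generator and the analysis; real acquisitions are
never lattice-aligned with the anatomy, and the offset removes the
degeneracy without affecting any measured quantity.

### Default parameters

| parameter | default | why |
|---|---|---|
| `endo_radius_ed` / `endo_radius_es` | 2.0 / 1.45 mm | murine-scale cavity; EF ≈ 47% |
| `wall_thickness_ed` / `_es` | 0.8 / 1.1 mm | diastolic/systolic mouse wall |
| `lv_length`, `n_slices`, `slice_thickness` | 9 mm, 9, 1 mm | contiguous 1-mm short-axis coverage |
| `pixel_spacing` | 0.15 mm | ≈ 30 mm field of view over a 192 matrix |
| `infarct_angle_extent`, transmurality | 90°, 1.0 | transmural anterolateral wedge; ~25% infarct |
| `remote_mean`, `remote_sd`, enhancement | 200, 20, 3× | clear LGE contrast at ~10:1 wedge CNR |
| `heart_rate` | 500 /min | anesthetized mouse |

What the phantom does **not** emulate: papillary muscles and trabeculation,
partial-volume and rim artifacts, contour-tracing error (contours are the
analytic circles), through-plane motion, microvascular obstruction, and
Rician noise statistics. Passing recovery tests therefore demonstrates
correctness of the geometry, thresholding, sector/chord machinery and
statistics — not robustness to segmentation error or acquisition artifacts
in real data.

## Quantification conventions

- **Thresholding.** ROI intensities are pooled across slices (one global
  threshold per subject); SD is the sample SD (ddof = 1). Both decision
  rules are strict inequalities: intensity `> mean + 5·SD`, sector
  transmurality `> 0.5`. A voxel exactly at the threshold, or a sector at
  exactly 50%, is not infarct.
- **Voxel membership.** A voxel belongs to a region iff its centre (pixel
  index `i` ↦ `(i+0.5)·spacing` mm) lies inside the polygon, even-odd rule.
- **Denominator of the volume fraction.** Infarct volume is reported
  relative to myocardial *wall* volume (not wall + cavity): infarct voxels
  are a subset of the wall and the ratio then compares like with like.
- **Sectors.** 100 equal-angle sectors about the epicardial centroid,
  half-open bins starting at the configurable reference angle (shared with
  the AHA layout so sector and segment reports align). Per sector,
  transmurality is the infarct/myocardial voxel-count ratio rather than a
  ray-cast depth fraction — at working resolution the two agree, and the
  count ratio is robust to contour noise. Epicardial arc length per sector
  is computed by cutting each polygon edge exactly where it crosses a
  boundary ray (the crossing parameter solves a linear equation), so sector
  arcs sum to the polygon perimeter to floating precision. A sector with no
  myocardial voxels raises an error suggesting a finer grid or fewer
  sectors (the 100-sector study convention needs roughly ≤ 0.1 mm pixels on
  apical mouse slices).
- **Cavity volumes.** Polygon (shoelace) area × slice thickness, summed
  over contoured slices with no inter-slice interpolation and no
  basal-slice exclusion rule. Zero-area contours contribute nothing and log
  a warning; `ESV > EDV` warns (pathological phase labeling) but computes.

## Centerline and chords

The centerline is found on equal-angle rays from the epicardial centroid:
the initial point is the midpoint between the ray's endocardial and
epicardial crossings, refined by bisection in radius until equidistant from
both boundaries. The guaranteed imbalance is < 10⁻³ mm; the iteration is
run to ~10⁻⁹ mm so chord geometry is never limited by centerline placement.
At each of the 100 centerline points the local normal (perpendicular to the
central-difference tangent, oriented outward) is intersected with both
contours; the chord runs from the nearest inward endocardial crossing to the
nearest outward epicardial crossing and its length is the wall thickness.
The "three-dimensional" aspect is realized as per-slice 2D centerlines on a
common long axis with no inter-slice smoothing — nothing beyond slice
stacking is reconstructible for this geometry.

ED and ES chords are paired by angular index (both phases use the same
equal-angle construction), which makes per-chord WT well defined. WT with
`WTS_ES = 0` is undefined and propagates as NaN, excluded from segment
means; negative WT is never clipped.

**AHA layout.** Basal and mid levels use six 60° bins, apical four 90° bins,
all half-open and starting at `reference_angle` (the anterior boundary),
proceeding counterclockwise anterior → anteroseptal → inferoseptal →
inferior → inferolateral → anterolateral (apical: anterior → septal →
inferior → lateral). Segment ids are 1–6 basal, 7–12 mid, 13–16 apical; the
apical cap (17) is excluded. Slices are split into apical/mid/basal thirds
by index, remainders assigned basal-first, overridable per slice. Because
100 chords do not divide evenly by 6, per-segment counts at a level are
48–51 per three slices rather than exactly 50; segment WT is the mean of
per-chord WT values (not the WT of mean thicknesses), and an empty segment
reports NaN, never zero.

## Statistics

Kaplan–Meier and the log-rank test are delegated to `lifelines` (standard
hypergeometric-variance tie handling); Dunnett's many-to-one comparisons
use the multivariate-t integration in `scipy.stats.dunnett`, alongside the
one-way ANOVA F-test; the one-within-factor repeated-measures ANOVA
(sphericity assumed) is `statsmodels`' AnovaRM with a guard returning F = 0
when there is no between-time variation (otherwise 0/0). Subjects completing
the 7-week protocol are administratively censored at day 49; when only
endpoint counts are known, `endpoint_survival_table` reconstructs a table
whose day-49 estimate depends only on the counts (all deaths precede the
censoring time). Significance is α = 0.05 throughout.

## Problem sizes and determinism

The default phantom stack is 9 slices of ~51×51 pixels (0.15 mm), and tests
use 100–720-vertex contour polygons, a 12-geometry EF grid, an exhaustive
20-labeling log-rank permutation oracle, and a 2000-replicate Dunnett null
simulation — sizes at which every analytic identity in the suite is sharp
while the full suite runs in about a minute. All randomness flows through
`numpy.random.default_rng` seeds carried in `PhantomSpec` or passed
explicitly; the same seed yields bit-identical stacks.

## Known limitations

- Contours are treated as exact; no sensitivity analysis to tracing error.
- The wall is circular/elliptical in-slice; strongly crescentic remodeled
  ventricles may defeat the star-shaped assumptions of the sector splitter
  (which requires the centroid to see the whole boundary).
- No partial-volume or microvascular-obstruction modeling in either the
  phantom or the classifier.
- The repeated-measures ANOVA assumes sphericity and a complete balanced
  design; no Greenhouse–Geisser correction.
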