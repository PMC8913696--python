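# Methods

`snarfpy` analyses registered two-channel volumes of mouse cortex acquired
with combined stimulated Raman scattering (SRS) and transient absorption
(TAM) contrast — 2850 cm⁻¹ (CH₂, lipid-dominant) and 2930 cm⁻¹ (CH₃,
lipid + protein) — at two timepoints nominally 15 min apart. This note
documents the models, defaults and numerical choices; everything stated
here is computed by the test suite or `scripts/acceptance.py`, not asserted
from memory.

## The synthetic scene generator

No public in vivo volumes accompany this method, so the package ships a
forward model (`snarfpy.scene`) that emulates the statistical structure the
analysis relies on, with complete ground truth standing in for the
fluorescent labels (Tie2-GFP endothelium, NeuroTrace-positive pericytes)
that define class identity in vivo.

**Geometry.** Axis order is (z, y, x), 0-based, z increasing with depth
below the simulated pial surface; crop intervals are half-open; default
voxels are 1 µm isotropic in a 160 µm cube. Capillaries are mildly curved
tubes (radius 1.8–3.2 µm, default 30 segments) rasterized by a nearest-
centerline distance transform and kept mutually separated so their skeleton
topology stays simple. Myelin is six thinner tubes (radius 1 µm). Nuclei
are ellipsoids placed without contact (≥ 1 voxel gap); class-conditional
morphology is config-exposed, with defaults chosen so the ten-feature set
is informative (nothing in the source data constrains these distributions —
class separability here is a free parameter of the phantom, not a
reproduction of in vivo biology):

| class       | semi-axes (µm)   | orientation                     | centroid offset from wall |
|-------------|------------------|---------------------------------|---------------------------|
| endothelial | 5.5 × 2.2 × 2.0  | long axis along vessel tangent  | +1.2 µm (bulges ~1 µm into the lumen) |
| pericyte    | 3.2 × 2.9 × 2.7  | circumferential ("bump on a log") | +2.2 µm |
| unlabeled   | 3.4 × 2.2 × 1.9  | random                          | +1.8 µm |
| non-lining  | 4.0 × 2.7 × 2.3  | random                          | placed > 2 µm from any vessel |

All lining classes satisfy the 1 µm lining rule by construction; the
"unlabeled" class (astrocyte/oligodendrocyte/microglial nuclei occupying
capillary space) is given smaller nuclei, which is what makes it separable
from the endothelial class in this phantom.

**Cortical layering.** Cell depth is drawn from a piecewise-constant
density that doubles at `l23_depth` (default 100 µm), emulating the L1 →
L2/3 transition. The depth is drawn *before* a position is searched, so
overlap retries cannot leak probability toward emptier strata; a depth is
redrawn only when a stratum is locally saturated. Near the volume floor a
whole nucleus cannot fit, so the realized deep/shallow ratio on the default
scene is ≈ 1.7–2.0 rather than exactly 2 — the generator reports the
realized profile via `density_profile`.

**Optics.** Concentration fields (lipid, protein) map to the two channels
through a 2×2 mixing matrix (default rows (1.0, 0.2) and (0.45, 1.0)).
Nuclei attenuate the lipid signal multiplicatively (×0.15) and the protein
signal partially (×0.65), producing the dark-nucleus contrast; myelin is
lipid ×3. Flowing lumens carry a TAM term (amplitude 2.5) added *equally*
to both channels — hemoglobin absorption is wavenumber-flat — modulated by
per-timepoint smooth speckle (relative s.d. 0.35) standing in for moving
red blood cells; no RBC motion model is attempted. Stalled lumens keep
0.3× the tissue SRS level, are static across frames, and (when persistent)
may contain spherical stuck-cell blobs: RBCs add flat TAM (amplitude 2),
WBCs add protein concentration 2 (spectral ratio 2930/2850 ≈ 5 vs ≈ 1 for
RBCs). Per-timepoint stall probability is 3%, half persistent; content
category probabilities (WBC-only / RBC-only / both / none) default to
0.20 / 0.35 / 0.25 / 0.20, i.e. 45% of persistent stalls contain a WBC.
Stalled segments are drawn 8% narrower than flowing ones.

**Depth response and noise.** Both channels decay as exp(−z/70 µm) over a
constant background floor (0.05), so the signal-to-background ratio crosses
2 near the bottom of the default volume; additive Gaussian noise
(s.d. 0.02) and Poisson shot noise (200 counts per intensity unit) follow.
All randomness flows from one `numpy` Generator; identical configs give
bit-identical scenes, and the class tallies are the generator's first draw
so they can be reproduced externally by `rng.multinomial` with the same
seed.

**What the phantom does not contain** — optical point-spread blur,
fluorescence photophysics, laser noise, motion artifacts, myelin
arborization statistics, or realistic in vivo morphology distributions.
Passing tests therefore demonstrate that the *pipeline* recovers what the
forward model encodes, not that it would reach the same accuracy on real
tissue.

## Signal separation

A voxel is a vessel candidate iff (a) the minimum over channels (averaged
over timepoints) exceeds both the per-slice 0.90 intensity quantile and
1.5× the per-slice median — the per-slice normalisation makes the gate
attenuation-invariant, and the median floor keeps it clear of the tissue
noise tail — and (b) the cross-channel relative difference
|I₂₈₅₀ − I₂₉₃₀| / max(mean, ε) is below 0.25 (wavenumber-flatness; this is
what excludes lipid-bright myelin). Candidates survive where the
normalized inter-frame variation exceeds 0.3 (flowing RBC texture) or
where they form a tubular component ≥ 150 µm³. A 2 µm morphological
closing (computed on a padded array to avoid border erosion) bridges the
indentations left by wall-hugging nuclei. Raising the variance threshold
never adds voxels. Persistently stalled lumens carry no perfusion signal
and are invisible to this detector by design; they enter the analysis
through the hemodynamics module instead.

Unmixing inverts the 2×2 model per voxel; the matrix is always
config-supplied (no universal calibration exists). Vessel voxels are
replaced by the per-slice tissue median before inversion — but only mask
voxels that are actually bright: dark voxels under the vessel mask are
nucleus bulges and keep their Raman values, so wall-hugging nuclei are not
cut in two. Negative solutions are clipped at zero with the clipped mass
reported as a residual map.

Myelin extraction is deliberately a simplified tubularity filter, not a
tracing algorithm: the lipid map is flat-fielded per slice (removing depth
attenuation), passed through a multiscale Sato eigenvalue-of-Hessian filter
at scales around the 1 µm myelin radius, thresholded at 0.2, cleared of
vessel voxels, and filtered to components at least 10 µm long
(bounding-box diagonal).

The SBR profile divides the mean in-tissue intensity of each z-slice by the
mean of a background region (the darkest percentile of the slice by
default — in tissue with no unstained region the darkest voxels, nucleus
interiors, are the natural dark reference; an explicit mask can be
supplied instead); the imaging depth limit is the deepest slice with
SBR > 2. A closed-form check: SBR(z) = 10·e^(−z/100) crosses 2 at
100·ln 5 ≈ 160.9 µm.

A helper `pulse_snr_gain` encodes the inverse scaling of SRS signal with
excitation pulse duration (valid for pulses ≳ 1 ps): shortening 7 ps → 1 ps
predicts a 7-fold SNR gain. The optional denoiser is classical
(Gaussian/median) and makes no claim to the depth gains of learned
denoisers.

## Segmentation

Nuclei are dark, roughly convex holes. Darkness is measured against a
12 µm Gaussian background estimate — (background − intensity)/background >
0.25 — which cancels both depth attenuation and any global intensity
rescale. Touching nuclei are split by watershed on the Euclidean distance
transform with h-maxima markers (h = 0.75 × min radius). Two numerical
traps are handled explicitly: discretized EDT ties can mark several voxels
of one peak in disconnected clusters (one dilation step merges them
without bridging distinct nuclei), and thin nuclei whose EDT never rises h
above the surroundings would get no marker at all (each markerless
component is seeded at its deepest voxel). Objects outside the 4–16 µm
equivalent-diameter gate are removed; labels are relabeled contiguously in
raster order, so all downstream statistics are permutation-invariant.
Voxels equidistant between markers resolve deterministically for a fixed
input.

Capillaries: skeletonize the vessel mask, remove skeleton voxels with more
than two 26-connected neighbours (branch points), label the remaining
branches, assign every vessel voxel to its nearest branch, and discard
segments whose mean width — 2× the distance-transform value along the
branch — exceeds 10 µm, the standard capillary diameter cutoff. Anisotropic
voxels are supported by computing all geometric quantities in µm; the
bundled scenes are isotropic.

## Morphometry — the ten features

A cell is **capillary-lining** iff any of its voxels lies within 1 µm
(Euclidean, µm units) of a capillary voxel; the nearest capillary id is
recorded. This matches a brute-force all-pairs distance check exactly on
small volumes (tested).

Seven morphological features per cell, with the defining formulas (the
source analysis used commercial software and names the features without
defining them; these are this package's definitions):

* volume V = voxel count × voxel volume;
* surface area SA from a marching-cubes mesh of the padded object at
  level 0.5 (so sphericity can slightly exceed 1 on digital spheres —
  tolerance documented in the tests);
* sphericity = π^(1/3)·(6V)^(2/3)/SA;
* ESD = (6V/π)^(1/3);
* ellipsoid axes (ELA ≥ ESLA ≥ ESA) = 2√(5λᵢ) for eigenvalues λᵢ of the
  voxel-coordinate covariance in µm² — exact for a uniform solid ellipsoid
  (a digital (8,4,2) µm semi-axis ellipsoid recovers (16,8,4) within 2%).

Three relational features:

* % overlap = 100 × |cell ∩ nearest-capillary voxels| / |cell voxels|,
  against the raw (undilated) capillary mask — "volume overlap" is read as
  literal intersection;
* distance = Euclidean distance transform of the capillary background
  sampled at the cell's center-of-mass voxel (0 inside a capillary;
  clamped at 0, sub-voxel precision not attempted);
* direction = angle between the principal covariance axes of cell and
  capillary restricted to a 5 µm cube around the cell centroid, folded to
  [0°, 90°] via |cos θ|. If no capillary voxel falls in the cube the window
  doubles (flagged); a degenerate (isotropic) in-cube covariance imputes
  90° — the least-aligned value, so missing evidence cannot mimic the
  aligned endothelial signature — and flags the row.

The feature table (CSV) fixes the column order: ids/flags, then
sphericity, esd, volume, esa, ela, surface_area, esla, pct_overlap,
distance, direction; it is the classifier's input contract.

## Cell-identity classifier

A 20-tree random forest (scikit-learn) with stratified 70/30 train/test
splits predicts endothelial / pericyte / unlabeled from the ten features.
Reported accuracy is the mean ± s.d. over 20 independent stratified splits
— the package's reading of an "x ± y %" accuracy; both overall and
macro-averaged (mean per-class recall) numbers are reported because the
source does not say which was meant. ROC curves are one-vs-rest on the
forest's vote fractions. Importances are impurity-based by default
(permutation available by config), normalized to sum to 1. The out-of-bag
error curve is evaluated on a tree-count grid; because a single forest's
OOB estimate carries ~√(err/n) noise, the curve can be averaged over
replicate forests to expose the true convergence (the 20 → 100 tree change
is well under one percentage point on the bundled study-scale scene).
Group comparisons use the classic pooled-variance two-tailed unpaired
t-test (Welch by flag); no multiple-testing correction is applied, matching
the single-pairwise-test design.

## Hemodynamics

Per-segment flow state at each timepoint: **stalled** iff the luminal
temporal variance attributable to that frame is below 0.3 *and* the
background-corrected luminal *median* intensity is below 0.7× the
background-corrected perivascular mean (a 3 µm shell excluding all
vessels). The median, not the mean, judges dimness so that static stuck
cells (bright blobs) or nucleus bulges (dark) cannot mask the state of
the lumen. Two further numerical choices matter. First, the per-slice dark floor
(1st percentile) is subtracted from both lumen and shell; otherwise depth
attenuation over the constant detection background washes out the stall
contrast at depth. Second, with only two frames the inter-frame variation
is attributed to the *brighter* frame — that is where flowing-RBC texture
lives — so the dim frame of a transient stall keeps zero flow evidence and
is correctly called stalled while its flowing partner frame is not. The
0.7 drop fraction quantifies a qualitative "noticeable decrease" and is a
config knob.

Persistence: stalled at both timepoints → persistent; at exactly one →
transient; otherwise flowing. Width = mean over skeleton voxels of 2× the
distance transform (equivalent diameter fallback, flagged, for degenerate
segments); on digital cylinders this overestimates the diameter by about
half a voxel and converges as the voxel size shrinks. Luminal contents are
evaluated only for persistent stalls fully contained in the volume: blobs
brighter than 1.5× the luminal median are typed WBC if their 2930/2850
ratio exceeds 2.0 (the midpoint between the generator's RBC and WBC
spectral signatures — on real data this threshold must be calibrated) else
RBC, and the lumen is categorized WBC-only / RBC-only / both / none. The
census reports stalled fractions both volume-based and count-based, width
arrays for the flowing-vs-stalled comparison, content counts and the
fraction of persistent stalls containing at least one WBC.

## Pipeline and reproducibility

`run_pipeline` chains simulate → separate → segment → features → classify
→ stalls → report under one run directory; every stage reads and writes
files, so each is independently re-runnable. One global seed is fanned out
to per-stage 31-bit seeds via `numpy.random.SeedSequence.spawn`. All
physical quantities are serialized in µm (voxel sizes travel in YAML
sidecars); volumes and masks are multi-page TIFF, tables CSV, reports and
manifests JSON/Markdown. With a fixed seed every data output is
byte-reproducible (the manifest's timing block is the only exception). The
manifest records the config snapshot (every threshold actually used),
stage seeds, package version and SHA-256 of each output.

## Problem sizes

The bundled analyses run at desk scale by design: the default scene is a
160 µm cube with 450 cells and 30 capillary segments; the classifier
evaluation uses a 200 µm cube with ~1300 cells, sized to yield roughly the
~900 capillary-lining cells of the study population at the 661:134:120
class split; stall-rate recovery pools six default scenes (~180 segments)
so the binomial comparison against the configured 3% has power.

## Known limitations

* The phantom's class separability is chosen, not measured; accuracy
  numbers characterize the pipeline, not mouse cortex.
* Persistent stalls are invisible to the perfusion-based vessel detector;
  scenes with many stalls lower the vessel-mask Dice against the full
  geometric truth.
* The realized L1→L2/3 density step is slightly below 2 because nuclei
  cannot straddle the volume floor.
* Sub-voxel precision is not attempted anywhere; widths carry a half-voxel
  bias and sphericity a mesh-discretization tolerance.
* The WBC/RBC spectral threshold and the unmixing matrix are phantom
  defaults, not instrument calibrations.
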