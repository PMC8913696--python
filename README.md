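# snarfpy

Analysis pipeline for label-free two-channel brain microscopy volumes
combining stimulated Raman scattering (SRS) and hemoglobin transient
absorption (TAM) contrast — the modality combination known as SNARF
(simultaneous nonlinear absorption, Raman and fluorescence) microscopy.

Mouse-cortex volumes recorded at 2850 cm⁻¹ (CH₂, lipid-dominant) and
2930 cm⁻¹ (CH₃, lipid + protein) at two timepoints contain, without any
dye or transgene: dark ellipsoidal cell nuclei, bright tubular capillaries
carrying wavenumber-flat hemoglobin signal that flickers as red blood cells
flow, and lipid-bright myelin. `snarfpy` turns such volumes into
quantitative biology, for researchers studying cortical microvasculature,
capillary-lining cell populations and stalled capillary flow:

* **Signal separation** — vessel/TAM mask from intensity, cross-channel
  flatness and frame-to-frame flow texture; 2×2 linear unmixing into lipid
  and protein maps; Hessian-tubularity myelin extraction; per-slice
  signal-to-background (SBR) profiles with the SBR > 2 imaging-depth rule.
* **Segmentation** — watershed nucleus labeling in physical units;
  skeleton-based capillary segments (≤ 10 µm) with per-segment widths.
* **Morphometry** — each cell is classed capillary-lining iff any voxel
  lies within 1 µm of a capillary, and described by ten features: seven
  morphological (sphericity, ESD, volume, ESA, ELA, SA, ESLA — ellipsoid
  axes via 2√(5λ) from the voxel covariance) and three relational
  (% overlap, centroid-to-capillary distance, major-axis angle θ ≤ 90°).
* **Cell identity** — a 20-tree random forest with stratified 70/30 splits
  predicts endothelial / pericyte / unlabeled identity; accuracy is
  reported as mean ± s.d. over repeated splits with one-vs-rest ROC/AUC,
  normalized feature importances and the out-of-bag error vs tree count.
* **Hemodynamics** — per-timepoint flow states (stalled = static lumen with
  a marked SRS decrease), transient/persistent stall classification over
  the two acquisitions, widths for the flowing-vs-stalled comparison
  (two-tailed unpaired t-test), and WBC/RBC typing of stalled-lumen
  contents by the 2930/2850 spectral ratio.
* **Synthetic scenes** — a fully seeded forward model with complete ground
  truth (cell classes, vessel states, stall contents, myelin) that stands
  in for in vivo data; see `docs/methods.md` for what it does and does not
  emulate.

## Worked example

```bash
cat > demo.yaml <<'YAML'
scene:
  volume_shape_voxels: [96, 128, 128]
  n_cells: 140
  vessel_density: 14
classifier:
  n_repeats: 10
YAML
snarf run-all --config demo.yaml --seed 7 --outdir demo
```

This simulates a 96×128×128 µm volume at two timepoints, separates the
contrasts, segments 137 of the 140 generated nuclei and 17 capillary
segments, extracts the ten-feature table, trains and evaluates the forest,
and writes `demo/report.md`. Key lines from the run above:

```
## Cell populations
- cells: 137; capillary-lining: 90 (65.7%)
- lining class counts (ground truth): {'endothelial': 71, 'pericyte': 13, 'unlabeled': 6}

## Prediction accuracy
- overall: 95.4 ± 2.4% over 10 splits
- macro (mean per-class recall): 84.0 ± 9.2%
- out-of-bag error at trees [5, 10, 15, 20, 30, 50, 75, 100]: 8.9%, 3.3%, 3.3%, 3.3%, 3.3%, 2.2%, 2.2%, 2.2%

## ROC / AUC (one-vs-rest)
- endothelial: AUC = 1.000
- pericyte: AUC = 0.997
- unlabeled: AUC = 0.986
```

Reading: 65.7% of detected cells touch a capillary within 1 µm; the forest
identifies the three capillary-lining classes from morphology and vessel
relation alone at 95.4% overall accuracy on held-out splits (macro recall
is lower because this small demo has only 6 unlabeled cells), and the
out-of-bag error has already plateaued near 20 trees. The stall census in
the same report shows 0/17 stalled segments — at the realistic 3% stall
rate a volume this small usually contains none; the flowing-segment mean
width is 4.77 µm. Every stage can also be run separately (`snarf simulate`,
`separate`, `segment`, `features`, `train`, `predict`, `stalls`,
`report`) on the same run directory, and `manifest.json` records every
threshold, seed and output hash.

## Layout

```
src/snarfpy/      volume, scene, separation, segmentation, morphometry,
                  classifier, hemodynamics, pipeline, cli
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   models, defaults, numerical choices, limitations
scripts/          acceptance script
```
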