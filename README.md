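# orgaswell

Label-free quantification of organoid swelling from bright-field
microscopy.

Patient-derived intestinal organoids (PDIOs) are used to measure CFTR
channel function in cystic fibrosis: functional CFTR drives fluid
secretion into the organoid lumen, so organoids swell when the channel
works. Assays built on this principle — drug-induced swelling (DIS),
forskolin-induced swelling (FIS) and steady-state lumen area (SLA) —
need every organoid in a well to be found, measured and followed over
time. `orgaswell` implements that analysis chain for instance label
masks from **any** segmentation source (a trained network, manual
annotation, or the built-in classical segmenter), together with a
synthetic bright-field scene generator that provides exact ground truth
for testing every stage.

## What it computes

* **Instance-mask evaluation.** Predictions are matched one-to-one to
  ground-truth instances at an IoU threshold θ ∈ [0.5, 1.0]; matched
  pairs are true positives (TP), unmatched predictions false positives
  (FP), unmatched ground truth false negatives (FN); per image,

  AP(θ) = TP / (TP + FP + FN),

  averaged across images with SD. Matching maximizes the number of
  matches via optimal assignment.
* **Tracking.** Organoids are linked across timepoints by mask overlap
  (cost 1 − IoU) with a gated centroid-distance fallback, then chained
  into trajectories.
* **DIS.** Per organoid, swelling = area(t = 24 h) / area(t = 0 h);
  outliers are excluded by an explicit rule (minimum t0 area, Tukey
  fence at quartiles ± 1.5·IQR per condition per plate) and means ± SD
  are reported per (plate, condition). A bin-size stabilization
  analysis (random bins of 2–256 organoids, 10 repeats) shows how many
  structures the readout needs.
* **FIS.** Total organoid area per frame, normalized to t = 0 as a
  percentage; the readout is the baseline-subtracted trapezoidal AUC in
  %·min over the time-lapse.
* **SLA.** 100 · luminal area / total organoid area, per organoid.
* **Synthetic scenes.** Radial-harmonic organoid shapes (disks through
  "oddly-shaped" CF-like contours), dark rims, optional bright lumens,
  touching clusters, noise and illumination tilt — with exact label
  masks and, for evolved t0/t24 pairs, the exact per-organoid area
  ratio that was applied.

## Worked example

Simulate a small two-condition plate, analyse it end-to-end, and read
the per-condition summary:

```bash
cat > sim.yaml <<'YAML'
scene: {image_size: [512, 512], n_organoids: 24, mean_radius: 16,
        irregularity: 0.2, noise_sd: 2.4}
conditions:
  control: {swelling_mean: 1.0, swelling_sd: 0.05, centroid_jitter_sd: 2.0}
  treated: {swelling_mean: 1.8, swelling_sd: 0.2, centroid_jitter_sd: 2.0}
wells: {A1: control, A2: control, B1: treated, B2: treated}
YAML
cat > layout.yaml <<'YAML'
plate_id: P1
wells:
  A1: {condition: control, compounds: DMSO}
  A2: {condition: control, compounds: DMSO}
  B1: {condition: treated, compounds: VX-445/VX-661/VX-770}
  B2: {condition: treated, compounds: VX-445/VX-661/VX-770}
YAML
orgaswell simulate --config sim.yaml --out plate --seed 5
orgaswell run --input-dir plate --layout layout.yaml --out-dir analysis --segment-images
cat analysis/summary.csv
```

which prints (this exact output, seed 5):

```
plate_id,condition,mean_swelling,sd_swelling,n_included,n_excluded
P1,control,0.993813,0.0538989,48,0
P1,treated,1.6953,0.177145,47,1
```

Reading: from bright-field images alone the pipeline segmented the
organoids, tracked all 96 of them from t0 to t24, excluded one record
by the Tukey fence, and recovered the simulated condition means (1.0
and 1.8) to within 6% — swollen organoids that drift into contact cost
the classical segmenter a little boundary area; rerunning with truth
masks (`dis` instead of `run`) recovers both means to within 3% on
this small plate, and to well under 1% at the 64-organoids-per-well
scale the acceptance script uses.
`analysis/records.csv` holds the per-organoid areas, ratios and
exclusion reasons; `manifest.json` records the configuration and
per-stage counts needed to reproduce the run.

The same stages are available piecemeal (`segment`, `evaluate`,
`track`, `dis`, `fis`, `sla`, `stability`) and as library functions
(`orgaswell.ap_curve`, `orgaswell.fis_auc`, ...).

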