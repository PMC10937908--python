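# Methods

This note documents the models, conventions and numerical choices
behind `orgaswell`, and what its synthetic benchmarks do and do not
demonstrate about real microscopy data.

## Data model and conventions

Instance label masks are 2-D integer images: 0 is background, each
positive value identifies one organoid; labels need not be contiguous.
Masks are stored as single-channel 16-bit TIFF (a label above 65535 is
rejected at write time), which every mainstream reader handles;
float-valued files are rejected on read because interpolated labels are
meaningless. Coordinates are 0-based `(row, col)` and bounding boxes
half-open, so containment and area arithmetic never needs ±1
corrections. Colour images collapse to the unweighted channel mean:
bright-field channels are nearly identical, and the unweighted mean
avoids committing to any luma-coefficient dialect. JPEG input is
accepted — assay workflows commonly export it — but a warning is logged
since lossy compression perturbs gradients near organoid rims. An
organoid's size is its exact pixel count; no subpixel area model is
used anywhere, which is why several tolerances below are phrased in
terms of rasterization error.

## Evaluation: IoU matching and Average Precision

Pairwise IoU between predicted and ground-truth instances is computed
on pixel sets via a joint label histogram (one pass over the image).
Matching at threshold θ is the one-to-one assignment over pairs with
IoU ≥ θ that maximizes the number of matches first and total IoU
second; this is solved by `scipy.optimize.linear_sum_assignment` on
weights `1 + IoU/(n+1)` for eligible pairs — the IoU term is scaled
below `1/(n+1)` so it can never trade away a match. Among equally
optimal assignments the solver's deterministic choice is kept. The
per-image score is the unranked form `AP = TP/(TP+FP+FN)` (the matcher
has no confidence ranking to integrate over). Conventions that the
formula alone does not fix:

* threshold comparison is inclusive, so θ = 1.0 is attainable by
  pixel-identical instances;
* an empty prediction of an empty image scores AP = 1 (the 0/0 case is
  perfect agreement);
* the default threshold grid is 0.50 to 1.00 in steps of 0.05,
  configurable;
* the across-image SD uses the n−1 denominator and is 0 for a single
  image.

A greedy highest-IoU-first matcher is included for cross-checking; the
optimal matcher is the contract. For scenes of ≤ 6 instances the test
suite verifies the optimal matcher against exhaustive enumeration of
all one-to-one assignments.

## Classical segmentation backend

The pipeline is deliberately non-learned: flatten illumination by
subtracting a coarse Gaussian background (σ = image size / 8), smooth
(σ = 1 px), threshold the Sobel gradient magnitude at the 0.96
quantile, close gaps (disk radius 2) and fill holes, peel the
closing/edge-smear halo back off with an erosion of the same radius,
split touching blobs by a distance-transform watershed seeded at
interior maxima ≥ 12 px apart, drop components under 120 px², and apply
the border policy. Labels are renumbered 1..n in decreasing area order
(ties by prior label) so identical inputs give identical masks. The
defaults were calibrated on the generator's stylized scenes — the
gradient quantile in particular assumes edges occupy a few percent of
the image — and real bright-field data will generally need retuning or
an imported mask from a trained model; the import path
(`read_label_mask` + `validate_mask_pair`) is a first-class citizen for
exactly that reason.

The default border policy is `flag`: a frame-clipped organoid has a
censored area, so it stays in the mask (and in total-area series) but
is excluded from per-organoid swelling statistics. `keep` and `drop`
are available.

## Tracking

Adherent organoids barely translate between acquisitions, so mask
overlap is the primary cue: candidate cost is 1 − IoU when masks
overlap; otherwise centroid distance divided by the gate
`max_displacement` (default 50 px at the generator's scale) when within
the gate; otherwise forbidden. Optimal assignment maximizes link count
first (forbidden pairs carry a cost that dwarfs any admissible total),
then minimizes cost. Time-lapse trajectories chain pairwise links;
gaps are not closed — an organoid that disappears ends its trajectory,
and reappearances start new, incomplete-flagged ones. Division and
merging are out of scope.

## Assays

**DIS.** Swelling per organoid is `area(t24)/area(t0)` from a complete
trajectory. The exclusion rule is explicit because reproducibility
demands one: (a) records with t0 area below `min_area_t0` (default
300 px² at the generator's default organoid scale, ≈ a 10 px-radius
disk) are dropped as too small to measure reliably; (b) among the
survivors, swelling outside the Tukey fence `[Q1 − 1.5·IQR,
Q3 + 1.5·IQR]`, computed per condition per plate, is excluded. Tukey
fences are scale-free, need no distributional assumption, and with
fewer than 4 records per group only the area filter applies. Exclusion
reasons are recorded per record and original values retained. Summaries
pool organoids per (plate, condition); mean and n−1 SD are reported
with included/excluded counts, and a condition whose records are all
excluded is still reported with an explicit missing mean.

**FIS.** The total-area series is normalized to the first frame as a
percentage; the AUC integrates `relative_area − 100` by the trapezoid
rule in %·min. Subtracting the 100% baseline makes a non-swelling well
score exactly 0 and shrinkage negative; the trapezoid rule is exact for
piecewise-linear growth, so frame-rate changes do not move the readout
for linear signals.

**SLA.** `100 · luminal/total` per organoid. Luminal areas are inputs
(truth masks, annotation tables, or thresholding bright interior
pixels); no automatic lumen detector is validated here.

**Bin stability.** Mean swelling of bins of 2, 4, …, 256 records drawn
without replacement, 10 repeats per bin size, reporting the SD of
repeat-means per bin size. The number of structures needed for a stable
readout is dataset-dependent (it scales with the swelling dispersion as
σ/√bin), so the analysis is reported, not thresholded.

## Synthetic scene generator

Scenes are stylized, not optical: mid-gray background (default level
120 of 8 bits) with optional linear illumination tilt, organoids drawn
as radial-harmonic blobs `r(θ) = R(1 + Σ a_k cos(kθ + φ_k))` with
`Σ|a_k|` equal to the irregularity parameter (0 gives a disk; < 1
guarantees positive radius), a dark rim band of 2–3 px, brighter
interior, optional concentric lumen at linear fraction f (luminal area
fraction f², the basis of the SLA oracle), and Gaussian noise. Default
organoid radius is 16 px, typical of 4× bright-field imaging of
intestinal organoids at the few-hundred-µm scale.

Placement is rejection sampling with overlap always forbidden — truth
is a partition, every pixel has one label. With probability
`clustering` an organoid instead walks inward along a random direction
toward an existing one until contact, producing touching but
label-distinct clusters, the configuration that makes instance
segmentation hard. Non-clustered placements keep ≥ 1 background pixel
of separation. Placement is bounded: a scene that cannot fit its quota
reports how many organoids were placed.

Swelling multiplies an organoid's linear scale by √s so area scales by
the drawn ratio s; ratios are Normal(mean, sd) clipped positive, or
with probability `outlier_rate` uniform in `outlier_ratio_range`
(default 0.2–0.6), emulating the small/nonviable structures that shrink
rather than swell and that the exclusion stage must catch. Centroids
are jittered (Normal, default 2 px in the benchmark models); a
collision or out-of-frame placement is resolved by a deterministic
spiral search for the nearest free position, so swelling organoids
nudge neighbours by a few pixels rather than teleporting — this keeps
the scene trackable, as real adherent organoids are. Larger organoids
are placed first to keep nudges small; an organoid with no free
position within 48 px is dropped and reported with zero t1 area.
Rasterized area ratios track the drawn ratios to within 5% at the
default radius (boundary-pixel error ≈ half the perimeter in px over
the area); the truth table records both the drawn ratio and both pixel
areas. Plates seed each well deterministically from `(seed,
crc32(well_id))`, so any well can be regenerated independently and
byte-identically.

A time-lapse helper linearly interpolates per-organoid areas between
endpoints at fixed centres for FIS tests; it truncates at collisions
and is not a motion model.

What passing these benchmarks does **not** show: robustness to real
optics (defocus, halos, debris, meniscus shading), to multi-organoid
occlusion in dense Matrigel domes, or to morphologies outside the
radial-harmonic family (budding or annular structures). The generator
exists to verify the measurement chain, not the segmenter's generality.

## Benchmark study conditions

The end-to-end recovery benchmark uses a two-condition plate — 3 wells
per condition, 64 organoids per well (768×768 px), control swelling
Normal(1.0, 0.05), treated Normal(1.8, 0.2), 5% injected outliers,
2 px centroid jitter — chosen to mimic a realistic DIS contrast between
vehicle and a highly effective modulator combination at plate scale
while keeping a desk-scale runtime. Recovery tolerance is 3% of the
condition mean from truth masks (sampling error plus rasterization
bias) and 10% via the classical segmenter (touching swollen organoids
cost boundary pixels). Segmenter floors (mean AP@0.5 ≥ 0.8 easy,
≥ 0.5 moderate) and tracking floors (100% separated, ≥ 95% clustered)
are this package's acceptance settings for its own backend on its own
scenes, not claims about any external model or data.

## Determinism

Every stochastic component takes an explicit seed or
`numpy.random.Generator`; CLI reruns with identical configuration and
seeds produce byte-identical images, masks and CSVs (floats are
formatted to 6 significant digits). The run manifest echoes the
configuration, seed, package version and per-stage counts.
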