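# Methods

`ricefusion` implements a two-instrument calibration pipeline for the free
fatty acid content of stored rice (mg KOH-equivalent per 100 g, the
titration-based storage-quality indicator): a colorimetric sensor array
("olfactory visualization" — 15 dye spots imaged before and after headspace
exposure) and 512-point near-infrared (NIR) spectroscopy over 900–1700 nm.
Each modality is reduced by principal component analysis, calibrated with a
small backpropagation neural network (BPNN), and the optimal PC-score
blocks of the two modalities are concatenated for a fused calibration.
Because no public dataset of this kind exists, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure of such a study; all tests and the reproduction script run
against it.

## Synthetic cohort

The generator emulates an 8-month storage study: 20 samples per month
(5 bags × 4 subsamples), 160 samples total. The reference fatty acid value
follows

    fa = intercept + slope · month + ε,   ε ~ N(0, σ_sample²),

truncated to positive values. Defaults: intercept 8.5 mg/100 g, slope
1.6 mg/100 g/month, σ_sample = 1.0 mg/100 g — chosen once so the cohort
spans roughly 8–22 mg/100 g, the range typical of such storage studies.
A master seed spawns three independent sub-streams per sample (reference
noise, image rendering, spectrum synthesis), so any artefact can be
regenerated bit-for-bit in isolation.

### Sensor forward model

The 5 × 3 dye-spot array is rendered at 600 × 360 px with 30-px spots
(scanner resolution is a free choice; this leaves the 15-px extraction
disk well inside each spot). The *after* image shifts each spot's colour by

    Δ[s, c] = K[s, c] · (fa + η_sensor) + ε_spot,

where `K` is the 15 × 3 sensitivity matrix (counts per mg/100 g, fixed
default drawn once from U(−2.2, 2.2)), ε_spot ~ N(0, 1.0 counts) is
per-spot-channel measurement noise, and η_sensor ~ N(0, 0.8 mg/100 g) is a
per-sample nuisance: the array responds to headspace volatiles that track,
but are not identical to, the titrated value. Images are quantized to
8-bit, which bounds round-trip feature recovery at ±0.5 counts.

### NIR forward model

    I(λ) = m · [B(λ) + S(λ) · (fa + η_nir)] + a + ε(λ),

with analyte bands S(λ) at 1165, 1215 and 1395 nm (C–H second-overtone and
combination regions of lipids), multiplicative/additive scatter
m ~ 1 + N(0, 0.05), a ~ N(0, 0.02 AU), detector noise ε ~ N(0, 0.002 AU)
per point, and η_nir ~ N(0, 0.8 mg/100 g) an independent per-sample matrix
nuisance. The baseline B(λ) is not constant: it carries fixed water
(1450 nm) and starch (990 nm) bands. This is deliberate — with a constant
baseline every clean spectrum is an affine function of one shape, and the
SNV step would map all of them onto a single analyte-independent curve.
Fixed analyte-independent structure is what lets the preprocessed spectrum
retain analyte information, as real rice spectra do.

The two nuisances η_sensor and η_nir are independent; they are what makes
the modalities complementary and give fusion something to average away.
With both at their 0.8 mg/100 g default, single-modality prediction errors
land near 1.0–1.6 mg/100 g and fused errors near 0.6–1.0 mg/100 g,
magnitudes comparable to published storage-quality calibrations.

## Image feature extraction

Median filter (3 × 3, reflect padding, per channel) on both images;
threshold segmentation of the *after* image — Otsu's threshold on the mean
absolute deviation from the per-channel median background, connected
components, area filter at 20% of the median region area, exactly 15
regions required (a user-supplied spot grid is accepted as fallback);
mean R/G/B over the inclusive 15-px-radius disk at each centroid in both
images; ΔR/ΔG/ΔB per spot = after − before, flattened row-major into the
45-component feature vector.

Two declared conventions: "15-pixel radii" is read as a radius (not a
diameter), and disk membership uses pixel-centre coordinates with an
inclusive boundary. Per-channel min–max normalization of the deltas to
[0, 1] is implemented for the grayscale difference-image visualization,
but the calibration pipeline consumes the **raw** deltas: for a response
that is affine in the analyte, per-sample min–max normalization cancels
the analyte term exactly ((k_s·fa − min_s k_s·fa) / (max−min) is free of
fa), so normalized features would carry no signal at all in the noise-free
limit. The magnitude of the colour shift is the signal.

## Spectral preprocessing

Savitzky–Golay smoothing (window 11, polynomial order 2 — defaults, both
exposed) via least-squares local polynomials with polynomial edge
handling, then SNV: per-spectrum standardization with the sample (n−1)
standard deviation. SNV output has mean 0 / sd 1 to 1e-9 and is invariant
to affine scatter distortions. A spectrum whose variation is below machine
precision (relative 1e-12) is rejected as degenerate rather than amplified
into noise.

## PCA

Mean-centred SVD (equivalent to eigendecomposition of the sample
covariance), components ordered by decreasing variance, each loading's
sign fixed so its largest-magnitude entry is positive. Explained-variance
ratios are reported against the total training variance; the pipeline also
emits the full EVR/cumulative-EVR table per modality.

## BPNN

Topology: input → sigmoid hidden layer(s) → linear output. Inputs and
target are min–max scaled to [0, 1] from training data (a zero-range
feature maps to 0.5). Weights and thresholds initialize U(−0.5, 0.5) from
the run seed. Training is classic per-pattern (incremental)
backpropagation: each pattern is propagated forward and the weights of
every layer are adjusted along the backward pass with learning rate 0.1,
patterns visited in data order; an epoch is one pass, capped at 100
epochs or a scaled training RMSE of 4e-5.

Two numerical findings shaped the defaults:

* Full-batch gradient descent on the mean squared error cannot converge
  within a 100-epoch budget at learning rate 0.1 (the summed variant
  diverges outright); per-pattern updates — the textbook formulation of
  backpropagation — converge comfortably. The trainer is therefore
  per-pattern.
* A stack of three hidden layers of 5 sigmoid units attenuates the
  gradient enough that 100 epochs leave the output range collapsed
  (roughly 300 epochs are needed); a single hidden layer of 5 converges
  within the budget. The default is one hidden layer of 5 nodes;
  `hidden_layers=(5, 5, 5)` remains selectable.

Repeated runs: model metrics are reported as mean, sample variance and
standard deviation over 50 trainings under distinct derived seeds,
removing initialization luck. The trainer is vectorized across networks
(and across cross-validation folds via a per-pattern sample mask, where a
masked pattern contributes a zero update); this is bit-equivalent to
looping the single-network trainer and is covered by an equivalence test.

## Cross-validation and PC-count choice

RMSECV/R_C come from 5-fold cross-validation with random fold assignment,
metrics on the pooled out-of-fold predictions. PCA and all scalers are
refit inside each training fold. The PC count per modality scans k = 1…10;
for each k the mean RMSECV over the repeated runs is computed with the
fold assignment held fixed and only the network seeds varying (the
repeated runs exist to average initialization randomness); the chosen k
minimizes the mean RMSECV, ties broken toward the smaller k.

## Split, fusion, reporting

Each month's samples are split 3:1 (train fraction 0.75, rounded, train
never smaller than test), stratified and seeded: 120 training / 40
prediction samples at the default design. Fusion concatenates the two
optimal PC-score blocks and z-scores each column with training-set
statistics (the blocks live on different numeric scales). The report holds
one row per technique — sensor, NIR, fusion — with PC counts and
R_C/RMSEC/R_P/RMSEP as repeated-run statistics; the three rows share the
split and the same 50-seed sequence, so comparisons are paired. Point
estimates in the report table are means over runs; the best run (lowest
RMSEP) is retrievable from the per-run values. All fitting uses training
rows only; prediction rows are transformed, never refit.

## Problem sizes and numerical choices

The shipped tests and the reproduction script use the full default design
(160 samples, k = 1…10, 5 folds, 50 runs; the replicate-level
fusion-benefit check uses 10 runs per model across 20 replicate
experiments — the package's chosen balance between statistical resolution
and turnaround). Degenerate inputs fail loudly: constant spectra, constant
targets, zero-variance data matrices, non-odd filter windows, wrong-sized
grids and out-of-bounds disks all raise typed errors. Segmentation
failures report the region count found.

## What passing tests do and do not show

The generator reproduces the *structure* of a storage study — monotone
analyte trend, affine sensor response, scatter-corrupted spectra with
analyte-dependent bands, independent modality nuisances — not the
chemistry of any real rice cohort. Passing recovery and fusion-benefit
tests therefore demonstrates that the pipeline is correct and that fusion
helps under the stated noise model; they do not certify accuracy figures
on real instruments, real dye chemistry (cross-sensitivities, drift,
humidity), or real spectra (temperature shifts, nonlinear baselines).
Known limitations: no geometric rectification of rotated or warped arrays,
no colour calibration, no alternative preprocessing families (MSC,
derivatives), no decision-level fusion, and plain gradient descent without
momentum or adaptive steps.
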