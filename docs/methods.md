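# Methods

This note documents the models, numerical choices and limitations behind
`lritex`. It is the package's own account of its science; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## The measurement being emulated

A lensless radioluminescence imager couples a scintillator, a fiber bundle
and an EMCCD into a camera whose frame is a 300 x 407 px map of beta-decay
activity over a 4.80 x 6.51 mm field (16 um pixels). Tissue slices
incubated with a beta-emitting tracer are imaged for tens of seconds;
tumor tissue accumulates more tracer (mean counts roughly 1.6x benign
tissue) and shows visibly more heterogeneous uptake, while benign tissue
is dimmer and more uniform. The analysis task is to classify fixed
20 x 20 px ROIs as tumor or benign from image texture alone, without
supervision.

## Synthetic scene generator

Real clinical frames are not redistributable, so the generator is a
first-class, tested component whose defaults define the benchmark
conditions.

**Forward model.** Expected photons per pixel =
`acquisition_time x mean_rate x texture_field`, region by region;
background pixels are exactly zero. Detector counts =
`clip(round(gain * Poisson(expected) + N(0, read_noise) + offset), 0, 65535)`.
EM gain is a plain multiplicative factor rather than a Gamma cascade: the
downstream analysis consumes only first and second moments, which the
plain factor reproduces (variance scales as gain², verified against a
Poisson-moments oracle).

**Texture models.**

* *Smooth* (benign): `field = 1 + cv * G`, with `G` Gaussian-filtered white
  noise normalized to unit pointwise variance. Default correlation length
  4 px, coefficient of variation 0.10 — matching the few-percent ROI-mean
  spread of a uniform slice.
* *Heterogeneous* (tumor): multiplicative lognormal `exp(log_sd * G)`
  (default `log_sd = 0.5`, correlation length 3 px, pointwise mean
  `exp(log_sd²/2)`) plus sparse bright Gaussian blobs (density 3e-4 per
  pixel, sigma 3 px). This reproduces the qualitative
  high-contrast/high-run-emphasis signature of tumor tissue without
  claiming biophysical fidelity.

The noise field is normalized by the exact L2 norm of the Gaussian filter
kernel, not the sample SD: on patches of a few hundred correlation areas
the sample SD is biased low and seed-to-seed variable, which propagated a
several-percent bias into region means through the lognormal
exponentiation.

**Two-tissue scene.** Two 260 x 120 px rectangles side by side on the
detector (benign left, tumor right). The tumor rate is divided by the
analytic mean of its texture field so the realized mean-count ratio equals
the requested `cancer_ratio` (default 490/300 ≈ 1.63, the printed mean
uptakes of the tissue pair). Defaults: 5 photons/px/s benign rate, 60 s
acquisition, gain 1, read noise 10 counts, dark offset 100 counts —
placing benign tissue near 300 expected counts and tumor near 490, the
regime of the real frames.

**Edge rim.** An optional band (default width 6 px, rate x3) along the
inside of each tissue boundary emulates tracer accumulated at drying
tissue edges. Border ROIs of the benign slice then acquire tumor-like
brightness and variance, which is exactly the false-positive mechanism the
classification exhibits: enabling the rim raises the median false-positive
rate by ~44 percentage points at fixed seed while leaving false negatives
untouched.

**Determinism.** All randomness derives from the spec seed through
distinct named substreams (one per region texture, one for the detector),
so identical specs give bit-identical frames.

**What the phantom does not model** — and hence what passing tests do not
show about real data: beta-particle transport and scintillator light
spread (no PSF blur between tissue and detector), the fiber-bundle
honeycomb pattern, spatial gain nonuniformity, 3D tissue structure, and
real tissue microarchitecture. The texture parameters are calibration
knobs chosen once to sit in a plausible regime; no quantitative texture
statistics of real tissue were available to fit them to.

## ROI geometry

ROIs are half-open windows, row-major, 0-based, origin top-left — frozen
so feature tables are reproducible. The canonical grid is 78
non-overlapping 20 x 20 px ROIs per tissue sample. A 6 x 13 grid (the
`ROIGrid` default) is 120 x 260 px; two such grids cannot sit side by side
on a 407 px-wide frame, so the two-tissue pipeline instead places one
13 x 6 grid (260 x 120 px) on each slice — the same 78 ROIs per sample,
oriented to fit the detector halves. Overlapping grids (stride <
roi_shape) are supported but excluded from confusion-rate reporting to
avoid double counting.

## Feature extraction

**Resampling.** `P(x) = floor(2^s (I − min) / (max − min + 1)) + 1`,
levels 1..32 at the default `s = 5`. The `+1` in the denominator keeps the
top intensity inside the alphabet; 1-based levels keep the low/high
gray-level-emphasis features finite. A constant ROI maps to level 1.
Because min/max are taken per ROI, all matrix features are invariant to
adding a constant to the ROI — verified as a property test.

**GLCM.** Four distance-1 offsets (0°, 45°, 90°, 135°); each directed
count matrix is accumulated with its transpose before normalization
(standard Haralick symmetrization — it makes the four-direction average
well defined), then the four normalized matrices are averaged. Features
use gray-level values 1..32 as the index coordinates. Correlation is
defined as 0 when a marginal SD vanishes, so constant (background) ROIs
yield finite feature rows.

**GLRLM.** Maximal runs along the same four directions; 45° runs follow
up-right anti-diagonals. The conservation identity
`Σ_ij j·r(i,j) = n_pixels` holds per direction and is asserted on random
ROIs. The 11 features are computed per direction and averaged across
directions, mirroring the GLCM treatment; run percentage uses the total
ROI pixel count as denominator.

**NGTDM.** Neighborhood half-width `d = 1` (3 x 3 neighborhood, the
Amadasun–King default; it also maximizes valid pixels in a 20 x 20 ROI).
Border pixels within `d` of the ROI edge are excluded from both the
difference sums and the tone probabilities, with
`n = (width − 2d)(height − 2d)`. Contrast's second factor is `(1/n) Σ s(i)`
— consistent with `n` being a pixel count — and contrast is 0 when fewer
than two tones are present. An optional coarseness feature
(`1/(ε + Σ p_i s(i))`, ε = 1e-12) can be enabled as a 22nd column but is
off by default; the default vector has exactly 21 entries.

**Global statistics** use population (n) moments on raw counts; kurtosis
is non-excess (Gaussian → 3); skewness and kurtosis are 0 for constant
ROIs.

Every matrix and every matrix-derived feature is checked against literal
loop-based oracles (and, for the GLCM, against an independent library
implementation) on 100 random small ROIs at 1e-12 relative tolerance, plus
hand-computed micro-examples (SRE 13/72 on `[1,1,2,2,2]`; NGTDM contrast
33/512 on a 4 x 4 single-bright-pixel ROI).

## Classification

Features are Z-scored across all ROIs in the analysis with population SD
(so `x = z·sd + mean` round-trips exactly); constant features become
all-zero columns and are reported. ROIs are clustered agglomeratively on
Euclidean distance and the tree is cut at two clusters; cluster 1 is the
cluster containing the lowest ROI index (deterministic tie-break).

**Linkage.** Ward linkage is the default. Average linkage — the
textbook default for clustergram-style analyses — was evaluated first and
fails structurally on this problem: the tumor cloud has several-fold
larger within-class spread than the benign cloud, and the average-linkage
2-cut then splits off a handful of extreme tumor ROIs instead of the two
tissues (median accuracy ~53% across every texture regime tried). Ward's
variance criterion recovers the two tissue groups (median accuracy 100%,
minimum 98.7% over 20 seeds). Any scipy linkage can be selected in the
clustering config.

**Orientation.** The default rule labels the higher-mean-intensity cluster
as cancer (tumor uptake exceeds benign uptake); exactly equal means raise
an error rather than guessing. A placement rule (`cancer_sample=...`) is
available when the sample arrangement is known a priori. Confusion counts
treat cancer as the positive class; rates are reported both at full
precision and as display-rounded percentages.

## SNR and TNR metrics

**SNR.** Background level = mean of a signal-free window; `σ_BG` = its
population SD. The background-subtracted signal window is fitted with an
isotropic 2D Gaussian plus constant offset (Levenberg–Marquardt),
initialized at the window maximum with a 2 px width — robust for compact
spots. `SNR = A / sqrt(σ_BG² + A)`; a failed fit or non-positive amplitude
reports SNR from `A` clipped at 0 rather than raising. On noiseless
synthetic spots the fit recovers the amplitude to <1%; on simulated point
sources the median SNR grows by 2.0x when acquisition time quadruples,
the shot-noise `sqrt(t)` scaling.

**TNR.** The intensity TNR is the plain ratio of mean counts (optional
dark-offset subtraction, off by default — with the subtraction the ratio
increases monotonically in the offset, which may explain figures of merit
quoted above the raw mean ratio). The multi-feature TNR first screens for
a mutually independent feature subset by greedy forward selection in the
frozen feature order, keeping a feature iff its absolute Pearson
correlation with every kept feature is < 0.95; then each feature's
cancer/normal mean ratio is computed (min-shifted positive where needed),
oriented as `max(r, 1/r)` so features where benign tissue scores higher
still discriminate, and combined. The default combiner is the sum over
independent features — the only simple combiner whose magnitude grows with
the feature count the way a multi-feature figure of merit should — with
mean, geometric mean and quadrature reported alongside. Under the sum the
combined TNR is non-decreasing as discriminative features accrue (each
oriented ratio is ≥ 1), a property asserted in the tests.

## Problem sizes and reproducibility

Stochastic checks use 20 simulated scenes (156 ROIs each) or 20 point
source frames per condition; structural and oracle checks are exact.
`scripts/acceptance.py --seed N` derives all of its seeds from `N` via a
seed sequence and completes in well under a minute on one CPU.

## Known limitations

* The phantom is a statistical emulator, not a physical simulation;
  absolute feature values on real frames will differ.
* Z-score clustering implicitly assumes roughly Gaussian feature
  distributions; several texture features are non-negative and skewed, and
  a folded-Gaussian or rank-based treatment could reduce edge-ROI false
  positives.
* The independence screen and the combiner are pragmatic defaults, both
  config-exposed; other choices change the combined TNR's scale (the
  per-combiner report makes this visible).
* Grid placement on real images is user-specified, as in practice the
  grids are positioned over each tissue slice by the operator.
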