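# Methods

This note records the models, conventions and numerical choices behind
`drsmargin`, and what its synthetic-data experiments do and do not show.

## Spectral model and calibration

A raw acquisition is a sequence of intensity frames (counts vs wavelength)
on the spectrometer grid, 420–1000 nm at 0.5 nm (1161 samples). The
acquisition protocol records 20 frames per probed tissue site at 80
frames/s; `average_frames` takes the arithmetic mean of the first 20 frames
in timestamp order (later frames are ignored so site means stay
comparable). Calibration converts counts to unitless reflectance with a
white reflectance standard `W` and a dark-field reading `D`:

    R(λ) = (S(λ) − D(λ)) / (W(λ) − D(λ))

Wavelengths where `W − D < 1e-3 · max(W − D)` carry no usable sensitivity;
they are masked (set to 0 with a validity mask) rather than divided
through, and masked wavelengths are excluded from features. Reflectance is
clipped to [0, 2]: specular glints can legitimately exceed 1, but unbounded
ratios destabilise downstream features. Analysis is restricted to the
inclusive 468–720 nm band (505 samples); band edges must land exactly on
grid points (tolerance 1e-6 nm) — there is deliberately no interpolation.
Cropping is applied after calibration. An optional moving-average smoother
(window 5, off by default) is available; no stronger noise-reduction method
is imposed because frame averaging already suppresses most frame noise.

## Quality control

Two deterministic filters run on calibrated, cropped datasets.

*Contact artifacts.* A site where the probe lost tissue contact collects
almost no diffuse light. A site is removed when more than 80% of its
wavelengths lie below reflectance 0.02. Both thresholds live in `QCConfig`.

*Outliers.* Within each (patient, tissue-class) group — grouping per
patient respects inter-patient variability — each site's Euclidean
distance to the group's pointwise median spectrum is compared against
`median(d) + 3.5 · 1.4826 · MAD(d)`. The rule is iterated to a fixed point
(statistics recomputed on the survivors until no further site is flagged),
which makes the whole QC pipeline exactly idempotent: rerunning it at the
same configuration removes nothing. Removal per group is capped at 10% of
the group (worst offenders first, with a warning); when the cap binds,
idempotence is intentionally sacrificed to the cap — the leftover extreme
sites remain flagged on a rerun. Groups smaller than 5 are skipped.
Filters only exclude sites; intensities are never modified, and decisions
are independent of input ordering.

## Peak features

Each spectrum is summarised by its two most prominent peaks, ranked by
topographic prominence (peak height above the higher of its two flanking
minima; ties break toward the lower wavelength). Peaks must have
prominence at least 5% of the spectrum's value range. Per peak the feature
vector carries the peak wavelength and the mean reflectance over a ±10 nm
window (~41 grid points, truncated at band edges), plus the overall band
mean — five features at the default configuration. The window mean is the
*continuous* (trapezoidal) mean over the window, i.e. the band-average
intensity, which is what an analytic window integral predicts; the
arithmetic sample mean differs from it at the 1e-2 level because n samples
span n−1 step widths. If a spectrum has fewer qualifying peaks than
requested (a constant spectrum has none), the empty slots are filled with
the overall mean and the site can be flagged via an optional fill-flag
column (`include_fill_flag`), keeping the table rectangular without
changing the default five-column layout. Raw per-wavelength intensities
are available as an alternative feature source (`raw_intensity_table`).

## Feature selection

*Permutation importance* is computed on a held-out split for an
already-fitted model: baseline accuracy minus the mean accuracy over 30
seeded shuffles of one column at a time. Note the known masking effect:
when two features are strongly correlated, shuffling one leaves much of
the signal reachable through the other, so per-copy importances
underestimate the pair's joint value.

*Recursive feature elimination* (via scikit-learn's RFE, step 1) drops the
feature with the smallest importance — coefficient magnitude for linear
models, gain for tree ensembles — until `n_keep` remain; the elimination
order is the ranking.

*Boruta* is implemented from its definition: per iteration, every live
feature gets a shadow copy with independently shuffled rows; the estimator
is fitted on a bootstrap sample of the augmented matrix; a feature scores
a hit when its importance exceeds the best shadow importance. Two-sided
binomial tests of the cumulative hit count (p = 0.5) with Bonferroni
correction at α = 0.05 confirm or reject; rejected features leave the
model; survivors at 100 iterations are tentative. The per-iteration row
bootstrap is essential: without it, a noise feature whose fixed spurious
association with the labels happens to sit in the upper tail beats freshly
drawn shadows consistently and would be falsely confirmed — the bootstrap
plays the decorrelating role that bagging plays inside the random forests
the procedure was designed around. The default estimator is LightGBM, the
same family as the main benchmark.

## Classification benchmark

Sites from all patients are pooled per organ and split with repeated
stratified k-fold CV (5 folds × 5 repeats, seeded, via scikit-learn's
`RepeatedStratifiedKFold`). Four classifiers run with library defaults and
fixed seeds: linear-kernel SVM, MLP (`max_iter=500`), LightGBM, XGBoost.
The SVM and MLP sit behind a `StandardScaler` — standard practice for both,
and necessary for the SVM: on raw feature scales (wavelengths in nm next
to unit reflectances) libsvm's solver can take effectively unbounded time
on some training subsets.
Tumor is the positive class: sensitivity is the tumor-detection rate,
specificity the normal-recognition rate. AUC is the trapezoidal area under
the threshold-sweep ROC, identical to the normalised Mann–Whitney
pair-count (verified in tests against a brute-force oracle). Aggregates
are mean and sample SD (ddof = 1) over the 25 split-level values. Pooling
ignores patient identity by design, matching the acquisition-protocol
description this toolkit follows; a patient-grouped splitter
(`make_group_splits`) is provided for leakage-aware evaluation and is
explicitly a deviation from the pooled default. A classifier that fails on
a split is excluded from aggregates and surfaced in the report.

## Probe tracking

Marker segmentation converts each RGB frame to HSV and thresholds hue
90°–150°, saturation ≥ 0.4, value ≥ 0.2 (wraparound hue ranges supported);
the centroid of the largest 4-connected component with area ≥ 25 px² is
the measurement. Uniform brightness changes inside the value band do not
move the centroid.

The tracker is a linear Kalman filter with state (x, y, vx, vy) in pixels
and px/frame, constant-velocity transition (Δt = 1 frame), process noise
`Q = q · G Gᵀ` from the white-acceleration discretisation
(`G = [½, ½, 1, 1]` per axis, default q = 0.3 px²/frame⁴), and
position-only measurements with `R = r·I₂` (default r = 2 px²). The update
uses the Joseph form, and covariance symmetry/PSD is asserted after every
step (eigenvalue floor −1e-9). The filter initialises at the first
detection with zero velocity and covariance diag(25, 25, 100, 100); frames
before first detection are flagged undetected. During detection gaps the
filter coasts on its prediction; the growing covariance makes the gain
snap back to measurements within a few frames of reappearance. The
4-state constant-velocity model is the smallest model that supports
occlusion coasting; with q = 0 and noiseless constant-velocity input it
reduces to recursive least squares (checked against a batch fit).

## Overlay

Each classified site is drawn as a filled circle (radius 6 px, opacity
0.7) whose colour interpolates linearly in RGB from green (0, 255, 0) at
tumor probability 0 to pink (255, 105, 180) at probability 1 — the two
endpoint colours of the clinical display convention; the gradation shows
intermediate probabilities. Markers accumulate across frames, building the
site map of everything sampled so far. The exact pink triplet, radius and
opacity are configurable choices. Rendering is deterministic.

## Synthetic data

No patient spectra are distributed, so the generator defines the study
conditions. The tissue model is parametric rather than a measured
chromophore table: reflectance is a broad scattering baseline
(Gaussian hump centred at 650 nm, width 55 nm, on a 0.28 floor) minus two
haemoglobin-like absorption dips at 540 and 575 nm (widths 12 nm). This
yields two interior reflectance peaks (~557 nm between the dips, ~650 nm)
for both tissue classes. Tumor tissue adds a Gaussian contrast band
centred in the configured 600–700 nm window (amplitude 0.12), so the
class-mean difference peaks inside that band.

Variability has three levels: per patient, a flat baseline offset
(SD 0.04) and a spectral tilt (SD 0.02); per site, a smooth
wavelength-correlated perturbation (SD 0.008, correlation length ~8 nm) —
smooth because local vascularity and chromophore density vary smoothly in
wavelength, and because a flat per-site offset would give group distances
a one-degree-of-freedom heavy tail that no reasonable robust outlier rule
handles cleanly; per frame, white noise (SD 0.02 in reflectance units,
reduced ~4.5× by 20-frame averaging). The nonlinear class boundary is the
interaction between contrast and patient offset: patients with a
below-average baseline express a sign-flipped, attenuated contrast
(−60%), readable as between-patient variation in the dominant
chromophore/vascularity signal. Tumor deviation in the band is therefore
positive for some patients and negative for others — a non-monotone
boundary. Threshold learners condition on the overall reflectance level
and recover both branches; a single linear rule catches only one, which
is why the boosted ensembles outperform the linear SVM on generator
defaults. The asymmetric factor keeps the class-mean difference from
cancelling, so the mean tumor/normal contrast still peaks inside
600–700 nm.

Raw frames are emitted in counts through a synthetic lamp spectrum and
dark floor (`S = D + R·(W − D)` plus noise), so white/dark calibration
recovers the designed reflectance exactly in the noise-free limit.
Artifacts are injected at 5% each: no-contact sites (near-dark frames)
and outlier sites (additive Gaussian spikes, amplitude 0.6, width 10 nm,
centre uniform in 500–700 nm), all recorded in the ground truth.
Default scale is 8 patients per organ × 25 sites per class — 200 sites
per class per organ, the acquisition protocol's minimum — chosen so the
full study runs in minutes on one core; the real protocol collects far
more sites per patient, so per-patient group sizes here are at the small
end of realistic.

Scenes for the tracker are 320×240 videos: a reddish textured background
(static smoothed noise plus per-frame sensor noise) and a hard-edged green
disc (hue 120°) following a static, linear or sinusoidal trajectory;
occlusion intervals simply omit the disc while the ground-truth centroid
keeps being recorded.

*What passing does not show.* The generator's two-class contrast is a
design assumption, not tissue physics: Monte-Carlo photon transport,
probe-pressure effects, specular geometry, label noise at tumor borders
and real chromophore spectra are all absent. Results on synthetic data
validate the pipeline's mechanics (calibration identities, QC recall
against known truth, CV bookkeeping, tracker accuracy), not clinical
performance.

## Reproducibility and limits

Every stochastic step takes an explicit seed; generation, QC, splitting,
selection and tracking are bit-reproducible given (config, seed). The CLI
writes a manifest per run with a config hash and artifact checksums.
Known limitations: the outlier cap trades idempotence for safety when it
binds; Boruta's runtime is dominated by estimator fits (hundreds of
LightGBM fits in the worst case); the MLP at library defaults is weak on
five-feature tables (it is kept at defaults deliberately — no tuning is
performed for any classifier).
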