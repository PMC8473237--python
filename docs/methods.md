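# Methods

`megcoh` implements a source-space MEG analysis pipeline for discriminating
mild cognitive impairment (MCI) from healthy controls (HC): coherence-based
functional connectivity over ten cortical ROIs, a hyper-/hypo-connectivity
ROI partition, wavelet-packet neuromarkers, and a dual cross-validation
evaluation. Because the original recordings are not public, a synthetic
cohort generator reproduces the study's structure (20 subjects per class, ten
ROI-averaged channels, three minutes at 200 Hz) with controllable planted
effects. This note documents the models, the defaults and why they were
chosen, and what the synthetic experiments can and cannot show.

## Connectivity indicator

The pairwise indicator is the magnitude-squared spectral coherence

    C_xy(f) = |P_xy(f)|² / (P_xx(f) · P_yy(f)) ∈ [0, 1],

with `P_xy` the cross-spectral density of the jointly stationary signals
`x, y`. Signals are cut into non-overlapping 1-s epochs (200 samples). A
single-segment estimator on one epoch is degenerate (|C_xy| ≡ 1), so the
per-epoch estimator is Welch averaging over 0.5-s Hann sub-segments with 50%
overlap — three averaged segments, a 2 Hz frequency grid. Sub-segment length
and overlap are configurable (`WelchParams`). With so few averaged segments
the estimator has a large positive bias floor for uncoupled signals (≈ 1/L
for L independent segments); this floor is class-independent and cancels in
all between-class contrasts, but absolute coherence values should be read
with it in mind.

The scalar connectivity of a pair is the arithmetic mean of `C_xy(f)` over
the broadband range 0.5–80 Hz (band edges inclusive on the 2-Hz grid; the
mean rather than the sum keeps the value interpretable in [0, 1] and does not
affect any ranking). The degree of connectivity of an ROI within one epoch
is the sum of its nine pairwise broadband coherences, in [0, 9]. Degree
statistics (mean/max/min/SD) are pooled over all subjects' epochs per class —
3600 values per (ROI, class) at full scale — rather than per-subject means,
matching the published summary convention.

**ROI partition.** Every ROI touched by a pair whose mean coherence rises in
MCI is a hyper-connectivity candidate. With the balance rule active (the
default), candidates are demoted — lowest degree-of-connectivity delta
(MCI − HC) first — or non-candidates promoted until both groups hold exactly
five ROIs, keeping the two groups comparable in data volume for the
classifier comparison. The rule can be bypassed (`balance=False`) or
overridden with an explicit ROI list (`partition_override` in the pipeline
config), since demoting a particular ROI is ultimately a judgment call.

**Hemispheric screening.** The 45 pairs split into 25 inter- and 20
intra-hemispheric pairs (labels derived from the L/R prefix). Per pair and
class, a pooled-variance two-sample t-test compares the two member ROIs'
epoch-level degree series; the reported quantity is the fraction of pairs
significant at α = 0.05. An Anderson–Darling normality check (normal family,
estimated parameters; p-values via the D'Agostino–Stephens approximation,
since SciPy exposes only critical values for this case) is available for the
coherence sets. Note that with thousands of pooled epochs the A–D test
rejects normality for even mild skew, so it should be read as descriptive
here rather than as a gatekeeper for the t-test.

## Wavelet-packet neuromarkers

Feature epochs are 10 s (18 per subject at full scale). Each epoch is
decimated to 200 Hz if needed (anti-aliased), then band-pass filtered
0.1–100 Hz with a 4th-order Butterworth applied forward–backward
(zero-phase, so no group-delay misalignment between ROIs; the effective
order doubles). The upper edge is clamped to 0.995 × Nyquist so the filter
stays realizable when the nominal edge sits at Nyquist.

Each ROI epoch is decomposed with a db4 wavelet packet transform to level 3,
symmetric boundary extension (periodization is available and is what the
energy-conservation test uses). All nodes of all three levels are kept —
2 + 4 + 8 = 14, redundant across levels by construction, each level tiling
0–100 Hz at its own resolution. Nodes are emitted in natural
(frequency-ascending) order, applying the Gray-code reordering to the
library's Paley-ordered tree, so band labels such as "L3_37.5-50Hz" map
directly onto node indices. The per-node feature is the sample SD (n−1
denominator) of the approximate derivative (first differences) of the node's
coefficients; first-differencing acts as a high-pass on the coefficient
sequence and emphasizes non-stationary fluctuation. The 14 features are
non-negative and exactly linear in input amplitude.

One observation = one (subject, 10-s epoch). The five ROIs of a group are
combined either by concatenation (70 dims) or by averaging their 14-dim
vectors. The replication configuration uses the mean: the published PCA
sweep peaks at 7 of up to 14 retained dimensions, which is only meaningful
if an observation has 14 dimensions, so the 14-dim reading is adopted as the
default while `concat` remains selectable. PCA (`pca_reduce`) centers and
estimates axes on training rows only and then projects both sets, so test
rows can never influence the axes.

## Evaluation protocols

* **MCR** — Monte-Carlo repetition: per repeat, a stratified random 5% of
  each class's observations (18 of 360 at full scale) is held out; 20
  repeats; 3-NN is the protocol default classifier. Splits are at the
  observation level, so epochs of one subject can appear on both sides —
  the protocol is deliberately optimistic when features carry
  subject-specific structure.
* **LOO** — subject-wise leave-one-out: fold f holds out the f-th subject of
  each class (20 paired folds); no epoch of a held-out subject is seen in
  training, which the implementation asserts on every fold. RBF-kernel SVM
  (C = 1) is the protocol default, reading "Euclidean proximity mapping" as
  the RBF kernel on Euclidean distance; poly2 and linear kernels and an
  unpaired 40-fold variant are selectable. Accuracy is epoch-level (matching
  the published observation counts); a subject-level majority vote is
  reported alongside.

Features are z-scored with train-fit statistics before distance-based
classifiers. Metrics: sensitivity TP/(TP+FN) with MCI positive, specificity
TN/(TN+FP), balanced accuracy = their arithmetic mean (an exact identity on
every result object), and the rank-based AUC (Mann–Whitney normalization,
midranks for ties). Folds with an undefined rate (zero denominator) are
excluded from the means with a warning.

## Statistical screening

Per feature dimension, a pooled-variance two-sample t-test ("standard"
two-sample form; Welch is selectable) and a Kruskal–Wallis rank test, both
two-sided at α = 0.05. The joint-significance mask marks dimensions
significant under both tests. Holm–Bonferroni correction is applied within
each test family across the dimensions entering the reported table — the
published corrected values are numerically consistent with a family of six
(the jointly significant set), not fourteen, so that is the default family;
correcting across all dimensions is available (`correction_family="all"`).

## Synthetic cohort generator

Each subject's ten channels are mixtures of shared band-limited latent
sources: per unordered ROI pair and per canonical band (delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30, gamma 30–95 Hz), an independent filtered-noise
source enters both member channels with weight `w_ij`, plus per-channel
private band noise and white sensor noise. Pair coherence is a monotone
function of `w_ij`, so coherence structure is planted directly. Band source
amplitudes decay with frequency (1.0, 0.9, 0.8, 0.6, 0.45) as a coarse stand-in
for the decreasing power of neural broadband spectra.

Class effects (MCI): `w_ij + coupling_delta_hyper` on the hyper pairs
(default LF-LT, RT-RC, LP-LO), `w_ij − coupling_delta_hypo` elsewhere, and a
relative amplitude gain `spectral_effect_size` in 25–100 Hz applied to the
channels of hyper-pair member ROIs. The spectral effect sits in the beta and
gamma range because that is where the jointly significant feature dimensions
are expected. It is applied as a per-channel linear filter and is therefore
exactly coherence-neutral, keeping the two planted effects orthogonal.

Two design details matter for realism of the *contrasts*:

* **Variance normalization.** Each channel's per-band variance is normalized
  from its mixing weights (a per-channel scalar — coherence is untouched).
  Without this, changing couplings by class changes every channel's total
  power and hands all classifiers a trivial global amplitude cue; with it,
  class-discriminative spectral content exists only where it is planted.
* **Subject random effects.** Each subject perturbs all pair weights by
  N(0, `subject_sd`) (clamped into [0, 1] with a logged warning) and draws
  per-band amplitude gains 1 + N(0, 2 × `subject_sd`) shared across channels
  (again coherence-neutral). The band gains give epochs of one subject a
  common spectral signature, which is exactly what makes subject-wise LOO
  harder than pooled-epoch MCR; at half that gain spread the optimism gap is
  not reliably reproduced.

Defaults: `coupling_base` 0.25, `coupling_delta_hyper` 0.45,
`coupling_delta_hypo` 0.10, `subject_sd` 0.0625 (0.25 × base),
`noise_sd` 0.2, `spectral_effect_size` 0.15. The study reports no planted
effect sizes, so the coupling deltas were calibrated once so that the
planted pairs' summed-coherence deltas land in the ~0.01–0.17 range of the
published degree-of-connectivity table (the defaults put the hyper-pair
degree deltas around +0.07…+0.13 and the hypo ROIs around −0.02), and then
frozen. Generation is a pure function of (parameters, seed); per-subject
streams are spawned from a seed sequence, so cohorts are bit-reproducible.
Data are generated natively at 200 Hz; an `fs=1000` mode exists to exercise
the decimation path.

What the generator does **not** emulate: 1/f spectral slopes beyond the
five-band amplitude profile, non-Gaussian or non-stationary dynamics,
volume-conduction/field-spread leakage between parcels, age or severity
covariates, and any realistic anatomy. Consequently, passing synthetic
tests demonstrates that the pipeline recovers structure it is pointed at and
that the protocol comparisons behave as described — not that the published
accuracy values would be reproduced on real recordings.

## Problem sizes and numerical choices

Count identities (45 pairs, 25/20 hemispheric split, 3600 epochs per class
per ROI, 3.24 × 10⁵ coherence evaluations, 14 dimensions, 18 epochs per
subject, 360 observations per class) are checked on a full-scale synthetic
run (20 subjects/class × 180 s). The recovery and protocol-ordering
experiments run at 30 s/subject (30 connectivity epochs, 3 feature epochs
per subject) over 20 and 10 seeds respectively — the package's chosen
trade-off between Monte-Carlo stability and turnaround.

Numerical conventions: coherence values clipped into [0, 1] (tolerance
1e-9); zero-variance inputs yield a flagged undefined spectrum rather than
NaNs; sample SDs use the n−1 denominator; Holm adjustment is monotone,
capped at 1, and returned in input order; k-NN uses odd k so binary ties
cannot occur; SVM regularization C = 1 is echoed in each result's config.
Known limitations: Welch parameters for 200-sample epochs are a convention
(absolute coherence levels depend on them); the balance rule's demotion is
delta-ranked and can be arbitrary under near-ties; epoch-level accuracy
treats epochs of one subject as exchangeable test items, which is exactly
the optimism the LOO protocol is there to expose.
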