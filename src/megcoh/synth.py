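"""Synthetic MEG-like cohort generator.

Generates ROI-averaged source-space time series for two classes (healthy
controls, HC, and mild cognitive impairment, MCI) with controllable pairwise
coherence structure and class-specific spectral content, so that every
downstream stage of the connectivity / neuromarker pipeline can be exercised
without access to real recordings.

Generative model
----------------
Ten ROI channels (five per hemisphere) are built from shared band-limited
latent sources.  For each unordered ROI pair ``(i, j)`` and each canonical
frequency band (delta, theta, alpha, beta, gamma) an independent band-limited
noise source is generated and mixed into channels ``i`` and ``j`` with a
common weight ``w_ij``; because magnitude-squared coherence between two
channels is driven by their shared variance, ``w_ij`` directly controls the
planted coherence of the pair.  Each channel additionally receives private
band-limited noise and white sensor noise.  Each channel's per-band variance
is normalized from the mixing weights (a per-channel scalar, which leaves
coherence untouched) so that the coupling manipulation does not leak a
global amplitude cue into the spectral features.

Class effects:

* MCI subjects get ``coupling_delta_hyper`` added to ``w_ij`` for the
  configured hyper-connectivity pairs (default LF-LT, RT-RC, LP-LO) and
  ``coupling_delta_hypo`` subtracted elsewhere.
* MCI subjects get a relative amplitude gain ``spectral_effect_size`` in
  ``spectral_effect_band`` (default 25-100 Hz) applied to the channels that
  are members of hyper pairs.  Per-channel linear filtering leaves
  magnitude-squared coherence invariant, so this spectral effect is
  orthogonal to the planted coherence effect.

Subject random effects: each subject perturbs every pair weight by
``N(0, subject_sd)`` and draws per-band amplitude gains ``1 + N(0, subject_sd)``
shared across channels (which again does not change coherence), so that
epochs from one subject cluster together and subject-wise cross-validation
is genuinely harder than pooled-epoch splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

CLASS_LABELS = ("HC", "MCI")

#: Canonical ROI order: frontal, temporal, central, parietal, occipital x L/R.
DEFAULT_ROI_LABELS = ("LF", "RF", "LT", "RT", "LC", "RC", "LP", "RP", "LO", "RO")

DEFAULT_HYPER_PAIRS = (("LF", "LT"), ("RT", "RC"), ("LP", "LO"))

#: Canonical band edges (Hz) and relative source amplitudes.  The amplitude
#: profile decays with frequency to mimic the decreasing broadband power of
#: neural recordings; it is shared by all channels so it does not affect
#: pairwise coherence.
CANONICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 95.0),
}
BAND_AMPLITUDES = {
    "delta": 1.0,
    "theta": 0.9,
    "alpha": 0.8,
    "beta": 0.6,
    "gamma": 0.45,
}

#: Amplitude of per-channel private band-limited noise relative to the band
#: source amplitude (variance share ~0.3 per band).
PRIVATE_AMPLITUDE = 0.55

#: Subject band-gain spread relative to ``subject_sd``.  Band gains carry the
#: between-subject spectral heterogeneity that makes subject-wise LOO harder
#: than pooled-epoch splitting, so they get a larger scale than the coupling
#: jitter.
SUBJECT_GAIN_FACTOR = 2.0


def canonical_pairs(roi_labels=DEFAULT_ROI_LABELS):
    """All 45 unordered ROI pairs, in row-major upper-triangle order."""
    n = len(roi_labels)
    return [
        (roi_labels[i], roi_labels[j]) for i in range(n) for j in range(i + 1, n)
    ]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 20 subjects per class, 10 ROIs,
    three minutes of recording at 200 Hz, hyper-connectivity planted in the
    LF-LT, RT-RC and LP-LO pairs, and a class spectral effect in 25-100 Hz.
    """

    n_subjects_per_class: int = 20
    fs: float = 200.0
    duration: float = 180.0
    roi_labels: tuple = DEFAULT_ROI_LABELS
    hyper_pairs: tuple = DEFAULT_HYPER_PAIRS
    coupling_base: float = 0.25
    coupling_delta_hyper: float = 0.45
    coupling_delta_hypo: float = 0.10
    spectral_effect_band: tuple = (25.0, 100.0)
    spectral_effect_size: float = 0.15
    subject_sd: float = 0.0625  # 0.25 x coupling_base
    noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("duration x fs must be a positive integer sample count")
        if len(self.roi_labels) != 10:
            raise ValueError("exactly 10 ROI labels required")
        left = [r for r in self.roi_labels if r.startswith("L")]
        right = [r for r in self.roi_labels if r.startswith("R")]
        if len(left) != 5 or len(right) != 5:
            raise ValueError("ROI labels must be 5 per hemisphere (prefix L/R)")
        if len(set(self.roi_labels)) != 10:
            raise ValueError("ROI labels must be unique")
        for a, b in self.hyper_pairs:
            if a not in self.roi_labels or b not in self.roi_labels:
                raise ValueError(f"hyper pair ({a},{b}) uses unknown ROI label")
        if not 0.0 <= self.coupling_base <= 1.0:
            raise ValueError("coupling_base must be in [0,1]")
        if not 0.0 <= self.coupling_base + self.coupling_delta_hyper <= 1.0:
            raise ValueError("coupling_base + coupling_delta_hyper must stay in [0,1]")
        if not 0.0 <= self.coupling_base - self.coupling_delta_hypo <= 1.0:
            raise ValueError("coupling_base - coupling_delta_hypo must stay in [0,1]")
        lo, hi = self.spectral_effect_band
        if not 0.0 <= lo < hi:
            raise ValueError("spectral_effect_band must satisfy 0 <= lo < hi")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("scales must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def replace(self, **kwargs) -> "SynthParams":
        return replace(self, **kwargs)


@dataclass
class SubjectRecording:
    """One subject: 10 ROI-averaged time series plus metadata."""

    subject_id: str
    class_label: str
    fs: float
    data: np.ndarray  # (10, n_samples), rows in canonical ROI order
    roi_labels: tuple = DEFAULT_ROI_LABELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.roi_labels):
            raise ValueError("data must be (n_rois, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CohortDataset:
    """A cohort of subject recordings sharing sampling rate and duration."""

    subjects: list
    params: SynthParams | None = None
    roi_labels: tuple = DEFAULT_ROI_LABELS

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        fs = {s.fs for s in self.subjects}
        ns = {s.n_samples for s in self.subjects}
        if len(fs) != 1 or len(ns) != 1:
            raise ValueError("all subjects must share fs and duration")
        labels = {s.class_label for s in self.subjects}
        if set(CLASS_LABELS) - labels:
            raise ValueError("both classes must be present in a cohort")

    @property
    def fs(self) -> float:
        return self.subjects[0].fs

    def by_class(self, class_label: str) -> list:
        return [s for s in self.subjects if s.class_label == class_label]


def _band_sos(lo: float, hi: float, fs: float):
    nyq = fs / 2.0
    hi = min(hi, 0.995 * nyq)
    return signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def _band_noise(rng: np.random.Generator, sos, shape) -> np.ndarray:
    """Band-limited unit-variance noise rows."""
    x = signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def pair_weights(class_label: str, params: SynthParams) -> np.ndarray:
    """Class-level mixing weights for the 45 ROI pairs (before subject jitter)."""
    pairs = canonical_pairs(params.roi_labels)
    hyper = {frozenset(p) for p in params.hyper_pairs}
    w = np.empty(len(pairs))
    for k, p in enumerate(pairs):
        if class_label == "MCI":
            if frozenset(p) in hyper:
                w[k] = params.coupling_base + params.coupling_delta_hyper
            else:
                w[k] = params.coupling_base - params.coupling_delta_hypo
        else:
            w[k] = params.coupling_base
    return w


def generate_subject(
    class_label: str,
    params: SynthParams,
    rng: np.random.Generator,
    subject_id: str | None = None,
) -> SubjectRecording:
    """Generate one subject via the latent-source mixing model.

    ``rng`` is consumed; generation is a pure function of its state.
    """
    params.validate()
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    n = params.n_samples
    n_roi = len(params.roi_labels)
    pairs = canonical_pairs(params.roi_labels)
    idx = {r: i for i, r in enumerate(params.roi_labels)}

    # subject-perturbed pair weights, clamped into [0, 1]
    w = pair_weights(class_label, params)
    w = w + rng.normal(0.0, params.subject_sd, size=w.shape)
    if np.any(w < 0.0) or np.any(w > 1.0):
        logger.warning(
            "subject %s: %d pair coupling(s) clamped into [0,1]",
            subject_id,
            int(np.sum((w < 0) | (w > 1))),
        )
        w = np.clip(w, 0.0, 1.0)

    # subject band gains, shared across channels (coherence-neutral)
    gains = {
        name: max(0.05, 1.0 + rng.normal(0.0, SUBJECT_GAIN_FACTOR * params.subject_sd))
        for name in CANONICAL_BANDS
    }

    # per-channel unit-variance normalization per band (a per-channel scalar,
    # hence coherence-neutral): without it the class-dependent couplings would
    # leak a global amplitude cue into every channel's spectral features
    sumw2 = np.zeros(n_roi)
    for k, (a, b) in enumerate(pairs):
        sumw2[idx[a]] += w[k] ** 2
        sumw2[idx[b]] += w[k] ** 2
    scale = 1.0 / np.sqrt(sumw2 + PRIVATE_AMPLITUDE**2)

    data = np.zeros((n_roi, n))
    for name, (lo, hi) in CANONICAL_BANDS.items():
        amp = BAND_AMPLITUDES[name] * gains[name]
        sos = _band_sos(lo, hi, params.fs)
        shared = amp * _band_noise(rng, sos, (len(pairs), n))
        for k, (a, b) in enumerate(pairs):
            data[idx[a]] += scale[idx[a]] * w[k] * shared[k]
            data[idx[b]] += scale[idx[b]] * w[k] * shared[k]
        data += (
            scale[:, None]
            * amp
            * PRIVATE_AMPLITUDE
            * _band_noise(rng, sos, (n_roi, n))
        )

    if params.noise_sd > 0:
        data += params.noise_sd * rng.standard_normal(data.shape)

    # class spectral effect on hyper-pair member channels (per-channel linear
    # filter: leaves MS-COH unchanged, shifts band power)
    if class_label == "MCI" and params.spectral_effect_size != 0.0:
        lo, hi = params.spectral_effect_band
        sos = _band_sos(max(lo, 0.1), hi, params.fs)
        members = sorted({r for p in params.hyper_pairs for r in p}, key=idx.get)
        rows = [idx[r] for r in members]
        data[rows] += params.spectral_effect_size * signal.sosfilt(
            sos, data[rows], axis=-1
        )

    return SubjectRecording(
        subject_id=subject_id or f"{class_label}_subj",
        class_label=class_label,
        fs=params.fs,
        data=data,
        roi_labels=tuple(params.roi_labels),
    )


def generate_cohort(params: SynthParams) -> CohortDataset:
    """Generate a full two-class cohort, bit-reproducible given ``params.seed``."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(2 * params.n_subjects_per_class)
    subjects = []
    k = 0
    for class_label in CLASS_LABELS:
        for i in range(params.n_subjects_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            subjects.append(
                generate_subject(
                    class_label, params, rng, subject_id=f"{class_label}{i:02d}"
                )
            )
    return CohortDataset(subjects=subjects, params=params, roi_labels=tuple(params.roi_labels))
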