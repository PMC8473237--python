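"""Magnitude-squared coherence connectivity indicators.

The connectivity indicator is the magnitude-squared spectral coherence

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))

with P_xy the cross-spectral density (the transform of the cross-correlation
sequence of the jointly stationary processes x, y), estimated per 1-second
epoch by Welch averaging.  A single-segment estimator on a 200-sample epoch
is degenerate (|C_xy| == 1 identically), so the default estimator splits each
epoch into 0.5-second Hann sub-segments with 50% overlap (three averaged
segments, 2 Hz resolution).

A broadband summary (mean of C_xy over 0.5-80 Hz) is the scalar functional
connectivity of a pair; the degree of connectivity of an ROI within one epoch
is the sum of its nine pairwise broadband values (range [0, 9]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synth import CLASS_LABELS, CohortDataset, SubjectRecording, canonical_pairs

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 80.0)


@dataclass(frozen=True)
class WelchParams:
    """Spectral-estimation parameters for the per-epoch coherence estimator."""

    seg_seconds: float = 0.5
    overlap: float = 0.5  # fraction of a sub-segment
    window: str = "hann"
    detrend: str | bool = "constant"

    def nperseg(self, fs: float) -> int:
        n = int(round(fs * self.seg_seconds))
        if n < 2:
            raise ValueError("sub-segment shorter than 2 samples")
        return n

    def noverlap(self, fs: float) -> int:
        return int(round(self.nperseg(fs) * self.overlap))


@dataclass
class CoherenceSpectrum:
    """Frequency-resolved magnitude-squared coherence of one signal pair."""

    freqs: np.ndarray
    values: np.ndarray
    defined: bool = True

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.defined and (
            np.any(self.values < -1e-9) or np.any(self.values > 1.0 + 1e-9)
        ):
            raise ValueError("coherence values outside [0,1]")


@dataclass
class CoherenceMatrix:
    """Broadband MS-COH matrix of one epoch (symmetric, unit diagonal)."""

    epoch_index: int
    matrix: np.ndarray  # (10, 10)
    roi_labels: tuple

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.roi_labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match roi_labels")


def epoch_signal(recording: SubjectRecording, epoch_len: float = 1.0) -> list:
    """Split a recording into non-overlapping epochs of ``epoch_len`` seconds.

    A trailing partial epoch is discarded.
    """
    n_per = int(round(recording.fs * epoch_len))
    if abs(recording.fs * epoch_len - n_per) > 1e-9:
        raise ValueError("fs * epoch_len must be integral")
    if n_per > recording.n_samples:
        raise ValueError("epoch longer than recording")
    n_epochs = recording.n_samples // n_per
    return [
        recording.data[:, k * n_per : (k + 1) * n_per] for k in range(n_epochs)
    ]


def ms_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, est: WelchParams | None = None
) -> CoherenceSpectrum:
    """Welch-averaged magnitude-squared coherence of two equal-length signals."""
    est = est or WelchParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    nperseg = est.nperseg(fs)
    if x.size < 2 * nperseg - est.noverlap(fs):
        raise ValueError("signal too short: need at least two averaged segments")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
        return CoherenceSpectrum(
            freqs=freqs, values=np.full(freqs.shape, np.nan), defined=False
        )
    freqs, cxy = signal.coherence(
        x,
        y,
        fs=fs,
        window=est.window,
        nperseg=nperseg,
        noverlap=est.noverlap(fs),
        detrend=est.detrend,
    )
    return CoherenceSpectrum(freqs=freqs, values=np.clip(cxy, 0.0, 1.0))


def broadband_coherence(spec: CoherenceSpectrum, band=DEFAULT_BAND) -> float:
    """Mean coherence over frequency bins with band_lo <= f <= band_hi."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("band must satisfy lo < hi")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(mask):
        raise ValueError("band contains no frequency bins")
    if not spec.defined:
        return float("nan")
    return float(np.mean(spec.values[mask]))


def _epoch_pair_coherence(
    epoch: np.ndarray, fs: float, est: WelchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence spectra of the 45 unique pairs of a (10, n) epoch.

    Each pair is evaluated once (upper triangle) via broadcast Welch
    cross-spectra; returns (freqs, cxy[(n_pairs, n_freqs)]).
    """
    n_roi = epoch.shape[0]
    iu, ju = np.triu_indices(n_roi, k=1)
    nperseg = est.nperseg(fs)
    noverlap = est.noverlap(fs)
    kw = dict(
        fs=fs,
        window=est.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=est.detrend,
    )
    freqs, pxy = signal.csd(epoch[iu], epoch[ju], **kw)
    _, pxx = signal.welch(epoch, **kw)
    cxy = np.abs(pxy) ** 2 / (pxx[iu] * pxx[ju])
    return freqs, np.clip(cxy.real, 0.0, 1.0)


def pairwise_matrix(
    epoch: np.ndarray,
    fs: float,
    band=DEFAULT_BAND,
    est: WelchParams | None = None,
    roi_labels=None,
    epoch_index: int = 0,
) -> CoherenceMatrix:
    """Broadband MS-COH matrix of one multichannel epoch.

    All 45 unique unordered pairs are computed once and mirrored; the
    diagonal is set to 1.
    """
    est = est or WelchParams()
    epoch = np.asarray(epoch, dtype=float)
    n_roi = epoch.shape[0]
    roi_labels = tuple(roi_labels) if roi_labels is not None else tuple(
        f"ch{i}" for i in range(n_roi)
    )
    freqs, cxy = _epoch_pair_coherence(epoch, fs, est)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError("band contains no frequency bins")
    vals = cxy[:, mask].mean(axis=1)
    mat = np.eye(n_roi)
    iu, ju = np.triu_indices(n_roi, k=1)
    mat[iu, ju] = vals
    mat[ju, iu] = vals
    return CoherenceMatrix(epoch_index=epoch_index, matrix=mat, roi_labels=roi_labels)


def degree_of_connectivity(mat: CoherenceMatrix, roi: str) -> float:
    """Sum of the 9 off-diagonal coherences of one ROI's row (range [0, 9])."""
    if roi not in mat.roi_labels:
        raise KeyError(f"unknown ROI {roi!r}")
    i = mat.roi_labels.index(roi)
    return float(mat.matrix[i].sum() - mat.matrix[i, i])


@dataclass
class CohortCoherence:
    """Per-epoch broadband coherence matrices of a whole cohort.

    ``matrices[class_label]`` has shape (n_subjects, n_epochs, n_roi, n_roi).
    ``n_pair_evaluations`` counts unique-pair coherence computations performed.
    """

    roi_labels: tuple
    matrices: dict
    subject_ids: dict
    band: tuple
    n_pair_evaluations: int

    @property
    def n_epochs_per_subject(self) -> int:
        return next(iter(self.matrices.values())).shape[1]

    def degree_series(self, roi: str, class_label: str) -> np.ndarray:
        """Per-epoch degrees of connectivity pooled over a class's subjects."""
        i = self.roi_labels.index(roi)
        m = self.matrices[class_label]
        deg = m[:, :, i, :].sum(axis=-1) - m[:, :, i, i]
        return deg.reshape(-1)

    def pair_mean(self, class_label: str) -> np.ndarray:
        """Mean broadband coherence matrix over all of a class's epochs."""
        return self.matrices[class_label].mean(axis=(0, 1))


def cohort_coherence(
    cohort: CohortDataset,
    band=DEFAULT_BAND,
    epoch_len: float = 1.0,
    est: WelchParams | None = None,
) -> CohortCoherence:
    """Compute every epoch's broadband pairwise coherence matrix for a cohort."""
    est = est or WelchParams()
    n_roi = len(cohort.roi_labels)
    iu, ju = np.triu_indices(n_roi, k=1)
    matrices: dict = {}
    subject_ids: dict = {}
    n_eval = 0
    for class_label in CLASS_LABELS:
        per_subj = []
        ids = []
        for rec in cohort.by_class(class_label):
            epochs = epoch_signal(rec, epoch_len)
            stack = np.empty((len(epochs), n_roi, n_roi))
            for k, ep in enumerate(epochs):
                freqs, cxy = _epoch_pair_coherence(ep, cohort.fs, est)
                mask = (freqs >= band[0]) & (freqs <= band[1])
                vals = cxy[:, mask].mean(axis=1)
                m = np.eye(n_roi)
                m[iu, ju] = vals
                m[ju, iu] = vals
                stack[k] = m
                n_eval += len(iu)
            per_subj.append(stack)
            ids.append(rec.subject_id)
        matrices[class_label] = np.stack(per_subj)
        subject_ids[class_label] = ids
    logger.info(
        "cohort coherence: %d unique-pair MS-COH evaluations "
        "(%d epochs/subject x %d subjects x %d pairs)",
        n_eval,
        matrices["HC"].shape[1],
        sum(m.shape[0] for m in matrices.values()),
        len(iu),
    )
    return CohortCoherence(
        roi_labels=tuple(cohort.roi_labels),
        matrices=matrices,
        subject_ids=subject_ids,
        band=tuple(band),
        n_pair_evaluations=n_eval,
    )


def connectivity_stats(coh: CohortCoherence) -> pd.DataFrame:
    """Per-(ROI, class) mean/max/min/SD of the degree-of-connectivity series.

    Degrees are pooled over all subjects' epochs (n_subjects x n_epochs values
    per cell), matching the published summary-table convention.
    """
    rows = []
    for roi in coh.roi_labels:
        for class_label in CLASS_LABELS:
            d = coh.degree_series(roi, class_label)
            rows.append(
                {
                    "roi": roi,
                    "class": class_label,
                    "mean": d.mean(),
                    "max": d.max(),
                    "min": d.min(),
                    "sd": d.std(ddof=1) if d.size > 1 else 0.0,
                    "n_epochs": d.size,
                }
            )
    return pd.DataFrame(rows).set_index(["roi", "class"])


def pair_deltas(coh: CohortCoherence) -> pd.DataFrame:
    """Mean broadband coherence per pair and class, and the MCI-HC delta."""
    hc = coh.pair_mean("HC")
    mci = coh.pair_mean("MCI")
    rows = []
    for a, b in canonical_pairs(coh.roi_labels):
        i, j = coh.roi_labels.index(a), coh.roi_labels.index(b)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "roi_a": a,
                "roi_b": b,
                "hc_mean": hc[i, j],
                "mci_mean": mci[i, j],
                "delta": mci[i, j] - hc[i, j],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RoiPartition:
    """Assignment of every ROI to the hyper- or hypo-connectivity group."""

    hyper: frozenset
    hypo: frozenset
    evidence: pd.DataFrame = field(repr=False, default=None)

    def group_labels(self, roi_labels) -> dict:
        return {r: ("hyper" if r in self.hyper else "hypo") for r in roi_labels}

    def rois(self, group: str, roi_labels) -> list:
        if group == "all":
            return list(roi_labels)
        chosen = self.hyper if group == "hyper" else self.hypo
        return [r for r in roi_labels if r in chosen]


def partition_rois(
    hc_stats: pd.DataFrame,
    mci_stats: pd.DataFrame,
    deltas: pd.DataFrame,
    balance: bool = True,
) -> RoiPartition:
    """Partition ROIs into hyper-/hypo-connectivity groups.

    Every ROI participating in at least one pair whose mean coherence
    increases in MCI is a hyper candidate.  With ``balance`` set, candidates
    are demoted (lowest degree-of-connectivity delta first) or non-candidates
    promoted (highest delta first) until exactly five ROIs remain in each
    group; this mirrors the convention of keeping the two groups the same
    size for a fair classifier comparison.

    ``hc_stats`` / ``mci_stats`` are single-class views with a 'mean' column
    indexed by ROI; ``deltas`` is the 45-row pair-delta table.
    """
    rois = list(hc_stats.index)
    if set(rois) != set(mci_stats.index):
        raise ValueError("ROI sets of the two stats tables differ")
    candidates = set()
    for _, row in deltas.iterrows():
        if row["delta"] > 0:
            candidates.update([row["roi_a"], row["roi_b"]])
    degree_delta = {
        r: float(mci_stats.loc[r, "mean"] - hc_stats.loc[r, "mean"]) for r in rois
    }
    hyper = set(candidates)
    if balance:
        target = len(rois) // 2
        if len(hyper) > target:
            for r in sorted(hyper, key=degree_delta.get):
                if len(hyper) <= target:
                    break
                hyper.discard(r)
        elif len(hyper) < target:
            pool = sorted(
                (r for r in rois if r not in hyper),
                key=degree_delta.get,
                reverse=True,
            )
            for r in pool:
                if len(hyper) >= target:
                    break
                hyper.add(r)
    hypo = set(rois) - hyper
    return RoiPartition(
        hyper=frozenset(hyper), hypo=frozenset(hypo), evidence=deltas
    )


def hemisphere_of(roi: str) -> str:
    if roi.startswith("L"):
        return "L"
    if roi.startswith("R"):
        return "R"
    raise ValueError(f"ROI label {roi!r} lacks an L/R hemisphere prefix")


def hemispheric_group_tests(
    coh: CohortCoherence, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Inter-/intra-hemispheric labelling plus per-pair two-sample t-tests.

    For each of the 45 pairs and each class, a pooled-variance two-sample
    t-test compares the two member ROIs' epoch-level degree-of-connectivity
    series.  Returns the per-pair record table and the fraction of pairs with
    p < alpha per (class, hemisphere-group).
    """
    rows = []
    for a, b in canonical_pairs(coh.roi_labels):
        group = "inter" if hemisphere_of(a) != hemisphere_of(b) else "intra"
        for class_label in CLASS_LABELS:
            da = coh.degree_series(a, class_label)
            db = coh.degree_series(b, class_label)
            t, p = stats.ttest_ind(da, db, equal_var=True)
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "group": group,
                    "class": class_label,
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    table = pd.DataFrame(rows)
    fractions = {
        (cl, g): float(sub["significant"].mean())
        for (cl, g), sub in table.groupby(["class", "group"])
    }
    return table, fractions
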