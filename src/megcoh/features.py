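"""Wavelet-packet neuromarkers.

Each ROI-averaged signal is cut into 10-second epochs, band-pass filtered
(0.1-100 Hz, 4th-order Butterworth, zero-phase) at 200 Hz, and decomposed
with a db4 wavelet packet transform up to level 3.  Keeping all nodes of all
three levels (2 + 4 + 8 = 14, each level tiling the full 0-100 Hz axis at a
different resolution), the feature of a node is the sample standard deviation
of the approximate derivative (first differences) of its coefficients: a
14-dimensional vector per ROI per epoch.  Features of the five ROIs of a
connectivity group are combined per observation either by concatenation
(70-dim) or by averaging (14-dim, the default used for the replication
configuration).

Nodes are kept in natural (frequency-ascending) order so that band labels on
the 0-100 Hz axis map directly onto node indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal
from sklearn.decomposition import PCA

from .coherence import RoiPartition, epoch_signal
from .synth import CLASS_LABELS, CohortDataset, SubjectRecording

logger = logging.getLogger(__name__)

WAVELET = "db4"
MAX_LEVEL = 3
FEATURE_DIM = 14  # 2 + 4 + 8 nodes


@dataclass(frozen=True)
class PreprocessParams:
    """Band-pass/down-sampling settings applied to each feature epoch."""

    target_fs: float = 200.0
    band: tuple = (0.1, 100.0)
    filter_order: int = 4

    def validate(self):
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise ValueError("band must satisfy 0 <= lo < hi")


@dataclass
class WpdNode:
    """One wavelet-packet node with its nominal band on the 0-fs/2 axis."""

    level: int
    index: int  # frequency-ascending index within the level
    band: tuple  # (lo_hz, hi_hz)
    coefficients: np.ndarray


@dataclass
class WaveletFeatureVector:
    """14 per-node SD-of-approximate-derivative features for one ROI epoch."""

    values: np.ndarray
    roi: str
    subject_id: str
    epoch_index: int
    class_label: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FEATURE_DIM,):
            raise ValueError(f"feature vector must have length {FEATURE_DIM}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("features must be finite and non-negative")


def node_band_labels(fs: float = 200.0) -> list:
    """Labels of the 14 nodes, e.g. 'L2_25-50Hz', levels 1..3 in natural order."""
    labels = []
    for level in range(1, MAX_LEVEL + 1):
        width = (fs / 2.0) / 2**level
        for k in range(2**level):
            labels.append(f"L{level}_{_fmt(k * width)}-{_fmt((k + 1) * width)}Hz")
    return labels


def _fmt(x: float) -> str:
    return f"{x:g}"


def segment_for_features(recording: SubjectRecording, epoch_len: float = 10.0):
    """Non-overlapping 10-s epochs for feature extraction (remainder dropped)."""
    return epoch_signal(recording, epoch_len)


def preprocess(
    epoch: np.ndarray, in_fs: float, params: PreprocessParams | None = None
) -> np.ndarray:
    """Decimate to the target rate (anti-aliased) and zero-phase band-pass.

    ``epoch`` may be 1-D or (channels, samples).  The upper band edge is
    clamped to 0.995 x Nyquist so the band-pass stays realizable when the
    nominal edge sits at Nyquist.
    """
    params = params or PreprocessParams()
    params.validate()
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if in_fs < params.target_fs:
        raise ValueError("input sampling rate below target rate")
    q = in_fs / params.target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("in_fs must be an integer multiple of target_fs")
    q = int(round(q))
    if q > 1:
        epoch = signal.decimate(epoch, q, axis=-1, zero_phase=True)
    fs = params.target_fs
    if epoch.shape[-1] < 3 * params.filter_order:
        raise ValueError("epoch too short for filter warm-up")
    nyq = fs / 2.0
    lo, hi = params.band
    hi = min(hi, 0.995 * nyq)
    sos = signal.butter(
        params.filter_order, [lo / nyq, hi / nyq], btype="bandpass", output="sos"
    )
    out = signal.sosfiltfilt(sos, epoch, axis=-1)
    return out[0] if out.shape[0] == 1 else out


def wpd_decompose(
    epoch: np.ndarray,
    wavelet: str = WAVELET,
    max_level: int = MAX_LEVEL,
    fs: float = 200.0,
    mode: str = "symmetric",
) -> list:
    """Wavelet-packet decomposition returning ALL nodes of levels 1..max_level.

    Nodes are emitted in natural (frequency-ascending) order per level, each
    labelled with its nominal band tiling [0, fs/2]; 14 nodes for max_level=3.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ValueError("wpd_decompose expects a 1-D signal")
    if epoch.size < 2**max_level:
        raise ValueError("signal shorter than the deepest decomposition level")
    wp = pywt.WaveletPacket(data=epoch, wavelet=wavelet, mode=mode, maxlevel=max_level)
    nodes = []
    for level in range(1, max_level + 1):
        width = (fs / 2.0) / 2**level
        # 'freq' order applies the Gray-code reordering, i.e. natural order
        for k, nd in enumerate(wp.get_level(level, order="freq")):
            nodes.append(
                WpdNode(
                    level=level,
                    index=k,
                    band=(k * width, (k + 1) * width),
                    coefficients=np.asarray(nd.data, dtype=float),
                )
            )
    return nodes


def approx_derivative(coeffs: np.ndarray) -> np.ndarray:
    """First differences of adjacent coefficients (length n-1)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 1 or coeffs.size < 2:
        raise ValueError("need a 1-D array of length >= 2")
    return np.diff(coeffs)


def extract_features(
    epoch: np.ndarray,
    roi: str = "",
    subject_id: str = "",
    epoch_index: int = 0,
    class_label: str = "HC",
    wavelet: str = WAVELET,
    fs: float = 200.0,
) -> WaveletFeatureVector:
    """14-dim SD-of-approximate-derivative feature vector of one ROI epoch.

    Values are ordered level-1, level-2, level-3 nodes, frequency-ascending
    within each level; SD uses the sample (n-1) denominator.
    """
    nodes = wpd_decompose(epoch, wavelet=wavelet, fs=fs)
    values = np.array(
        [np.std(approx_derivative(nd.coefficients), ddof=1) for nd in nodes]
    )
    return WaveletFeatureVector(
        values=values,
        roi=roi,
        subject_id=subject_id,
        epoch_index=epoch_index,
        class_label=class_label,
    )


@dataclass
class FeatureDataset:
    """Observation matrix with subject/class indices and provenance."""

    X: np.ndarray  # (n_obs, n_dims)
    y: np.ndarray  # 0 = HC, 1 = MCI
    subject_ids: np.ndarray  # (n_obs,)
    epoch_indices: np.ndarray
    feature_labels: list
    group: str  # hyper / hypo / all
    aggregation: str  # mean / concat

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must align")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def class_matrix(self, label: str) -> np.ndarray:
        return self.X[self.y == (1 if label == "MCI" else 0)]


def roi_feature_tensor(
    cohort: CohortDataset,
    pre: PreprocessParams | None = None,
    epoch_len: float = 10.0,
) -> dict:
    """Per-ROI 14-dim features for every (subject, epoch).

    Returns {class_label: (tensor (n_subj, n_epochs, n_roi, 14), subject_ids)}.
    This is the shared expensive step behind ``build_feature_dataset`` for the
    different ROI groups.
    """
    pre = pre or PreprocessParams()
    out = {}
    for class_label in CLASS_LABELS:
        recs = cohort.by_class(class_label)
        per_subj = []
        ids = []
        for rec in recs:
            epochs = segment_for_features(rec, epoch_len)
            feats = np.empty((len(epochs), len(cohort.roi_labels), FEATURE_DIM))
            for e, ep in enumerate(epochs):
                clean = preprocess(ep, rec.fs, pre)
                for r in range(clean.shape[0]):
                    feats[e, r] = extract_features(
                        clean[r], fs=pre.target_fs
                    ).values
            per_subj.append(feats)
            ids.append(rec.subject_id)
        out[class_label] = (np.stack(per_subj), ids)
    n_sub = sum(v[0].shape[0] for v in out.values())
    logger.info(
        "feature extraction: %d subjects x %d epochs/subject x %d ROIs, "
        "%d dims/ROI (%d observations per class)",
        n_sub,
        out["HC"][0].shape[1],
        out["HC"][0].shape[2],
        FEATURE_DIM,
        out["HC"][0].shape[0] * out["HC"][0].shape[1],
    )
    return out


def build_feature_dataset(
    cohort: CohortDataset,
    partition: RoiPartition | None,
    group: str = "hyper",
    aggregation: str = "mean",
    pre: PreprocessParams | None = None,
    epoch_len: float = 10.0,
    tensor: dict | None = None,
) -> FeatureDataset:
    """One observation per (subject, 10-s epoch) from a ROI group's features.

    ``aggregation='mean'`` averages the group's per-ROI 14-dim vectors
    (14-dim observations); ``'concat'`` concatenates them (5 x 14 = 70-dim).
    ``tensor`` may carry a precomputed :func:`roi_feature_tensor` result.
    """
    if group not in ("hyper", "hypo", "all"):
        raise ValueError("group must be hyper, hypo or all")
    if group != "all" and partition is None:
        raise ValueError("partition required for hyper/hypo groups")
    rois = (
        list(cohort.roi_labels)
        if group == "all"
        else partition.rois(group, cohort.roi_labels)
    )
    if not rois:
        raise ValueError(f"group {group!r} selects no ROIs")
    roi_idx = [cohort.roi_labels.index(r) for r in rois]
    pre = pre or PreprocessParams()
    tensor = tensor or roi_feature_tensor(cohort, pre, epoch_len)
    base_labels = node_band_labels(pre.target_fs)

    X_rows, y_rows, subj_rows, epoch_rows = [], [], [], []
    for ci, class_label in enumerate(CLASS_LABELS):
        feats, ids = tensor[class_label]
        sel = feats[:, :, roi_idx, :]  # (n_subj, n_epochs, n_group, 14)
        if aggregation == "mean":
            obs = sel.mean(axis=2)
        elif aggregation == "concat":
            obs = sel.reshape(sel.shape[0], sel.shape[1], -1)
        else:
            raise ValueError("aggregation must be 'mean' or 'concat'")
        for s, sid in enumerate(ids):
            for e in range(obs.shape[1]):
                X_rows.append(obs[s, e])
                y_rows.append(ci)
                subj_rows.append(sid)
                epoch_rows.append(e)
    if aggregation == "mean":
        labels = list(base_labels)
    else:
        labels = [f"{r}_{lab}" for r in rois for lab in base_labels]
    return FeatureDataset(
        X=np.vstack(X_rows),
        y=np.array(y_rows),
        subject_ids=np.array(subj_rows),
        epoch_indices=np.array(epoch_rows),
        feature_labels=labels,
        group=group,
        aggregation=aggregation,
    )


def pca_reduce(
    train: np.ndarray, test: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """PCA with centering and axes estimated on training rows only.

    Both sets are projected onto the first ``k`` training principal axes
    (decreasing explained variance).  ``k`` beyond the training rank is
    allowed with a warning; trailing components then carry no variance.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if not 1 <= k <= train.shape[1]:
        raise ValueError("k must be in [1, n_features]")
    rank = np.linalg.matrix_rank(train - train.mean(axis=0))
    if k > rank:
        warnings.warn(
            f"k={k} exceeds training rank {rank}; trailing components are degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    train_r = pca.fit_transform(train)
    test_r = pca.transform(test)
    return train_r, test_r, pca


# The six jointly significant band labels must exist among the WPD nodes
# (levels 2 and 3 of the 0-100 Hz tree); checked once at import.
_SIGNIFICANT_BANDS = (
    "L2_25-50Hz",
    "L3_37.5-50Hz",
    "L2_50-75Hz",
    "L3_50-62.5Hz",
    "L3_62.5-75Hz",
    "L2_75-100Hz",
)
assert set(_SIGNIFICANT_BANDS) <= set(node_band_labels(200.0)), (
    "significant band labels must map onto WPD nodes"
)
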