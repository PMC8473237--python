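"""Model-style entry points.

`ConnectivityAnalysis` and `NeuromarkerClassification` wrap the functional
modules in a familiar model/results idiom: build the object from data, call
``fit()``, inspect the returned results object (``summary()`` prints a
report table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import coherence as coh_mod
from .coherence import (
    DEFAULT_BAND,
    RoiPartition,
    WelchParams,
    cohort_coherence,
    connectivity_stats,
    hemispheric_group_tests,
    pair_deltas,
    partition_rois,
)
from .evaluate import (
    LOO_DEFAULT,
    MCR_DEFAULT,
    ClassifierSpec,
    EvalResult,
    SplitScheme,
    loo_evaluate,
    mcr_evaluate,
)
from .features import PreprocessParams, build_feature_dataset, roi_feature_tensor
from .synth import CohortDataset


@dataclass
class ConnectivityResults:
    """Fitted connectivity indicators of a cohort."""

    stats_table: pd.DataFrame  # per-(roi, class) degree statistics
    pair_table: pd.DataFrame  # 45-row per-pair class means and deltas
    partition: RoiPartition
    coherence: coh_mod.CohortCoherence = field(repr=False, default=None)

    def hemispheric_tests(self, alpha: float = 0.05):
        return hemispheric_group_tests(self.coherence, alpha=alpha)

    def summary(self) -> str:
        wide = self.stats_table.unstack("class").round(3)
        lines = [
            "Connectivity analysis (broadband MS-COH degree of connectivity)",
            f"band: {self.coherence.band[0]}-{self.coherence.band[1]} Hz, "
            f"epochs/class/ROI: {self.stats_table['n_epochs'].iloc[0]}",
            "",
            wide.to_string(),
            "",
            f"hyper-connectivity group: {sorted(self.partition.hyper)}",
            f"hypo-connectivity group:  {sorted(self.partition.hypo)}",
            "",
            "pairs with increased coherence in MCI:",
            self.pair_table[self.pair_table["delta"] > 0]
            .sort_values("delta", ascending=False)
            .head(5)
            .round(4)
            .to_string(index=False),
        ]
        return "\n".join(lines)


class ConnectivityAnalysis:
    """Coherence connectivity analysis of a two-class cohort.

    Parameters
    ----------
    cohort : CohortDataset
    band : (lo, hi) broadband summary range in Hz (default 0.5-80).
    epoch_len : connectivity epoch length in seconds (default 1.0).
    est : Welch estimator settings for the per-epoch coherence.
    balance : enforce equal-size (5/5) hyper/hypo ROI groups.
    """

    def __init__(
        self,
        cohort: CohortDataset,
        band=DEFAULT_BAND,
        epoch_len: float = 1.0,
        est: WelchParams | None = None,
        balance: bool = True,
    ):
        self.cohort = cohort
        self.band = tuple(band)
        self.epoch_len = epoch_len
        self.est = est or WelchParams()
        self.balance = balance

    def fit(self) -> ConnectivityResults:
        coh = cohort_coherence(
            self.cohort, band=self.band, epoch_len=self.epoch_len, est=self.est
        )
        stats_table = connectivity_stats(coh)
        deltas = pair_deltas(coh)
        partition = partition_rois(
            stats_table.xs("HC", level="class"),
            stats_table.xs("MCI", level="class"),
            deltas,
            balance=self.balance,
        )
        return ConnectivityResults(
            stats_table=stats_table,
            pair_table=deltas,
            partition=partition,
            coherence=coh,
        )


@dataclass
class ClassificationResults:
    """Evaluation outcomes per (group, protocol)."""

    results: dict  # {(group, scheme): EvalResult}

    def get(self, group: str, scheme: str) -> EvalResult:
        return self.results[(group, scheme)]

    def summary(self) -> str:
        rows = []
        for (group, scheme), r in sorted(self.results.items()):
            rows.append(
                {
                    "group": group,
                    "scheme": scheme,
                    "mean_accuracy_%": 100 * r.mean_accuracy,
                    "sensitivity_%": 100 * r.mean_sensitivity,
                    "specificity_%": 100 * r.mean_specificity,
                    "balanced_%": 100 * r.balanced_accuracy,
                    "auc": r.auc,
                }
            )
        df = pd.DataFrame(rows).round(2)
        return "Wavelet neuromarker classification\n" + df.to_string(index=False)


class NeuromarkerClassification:
    """Wavelet-feature classification of a cohort under MCR and LOO protocols.

    Builds per-group feature datasets from a fitted ROI partition and
    evaluates the protocol-default classifiers (3-NN for MCR, RBF SVM for
    LOO) on each requested group.
    """

    def __init__(
        self,
        cohort: CohortDataset,
        partition: RoiPartition,
        groups=("hyper", "hypo"),
        schemes=("MCR", "LOO"),
        aggregation: str = "mean",
        pre: PreprocessParams | None = None,
        mcr_classifier: ClassifierSpec = MCR_DEFAULT,
        loo_classifier: ClassifierSpec = LOO_DEFAULT,
        mcr_scheme: SplitScheme | None = None,
        seed: int = 0,
    ):
        self.cohort = cohort
        self.partition = partition
        self.groups = tuple(groups)
        self.schemes = tuple(schemes)
        self.aggregation = aggregation
        self.pre = pre or PreprocessParams()
        self.mcr_classifier = mcr_classifier
        self.loo_classifier = loo_classifier
        self.mcr_scheme = mcr_scheme or SplitScheme(seed=seed)

    def fit(self) -> ClassificationResults:
        tensor = roi_feature_tensor(self.cohort, self.pre)
        results = {}
        self.feature_datasets = {}
        for group in self.groups:
            fd = build_feature_dataset(
                self.cohort,
                self.partition,
                group=group,
                aggregation=self.aggregation,
                pre=self.pre,
                tensor=tensor,
            )
            self.feature_datasets[group] = fd
            if "MCR" in self.schemes:
                results[(group, "MCR")] = mcr_evaluate(
                    fd, self.mcr_classifier, self.mcr_scheme
                )
            if "LOO" in self.schemes:
                results[(group, "LOO")] = loo_evaluate(fd, self.loo_classifier)
        return ClassificationResults(results=results)
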