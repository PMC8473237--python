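"""End-to-end orchestration: generate -> connect -> features -> classify -> stats.

`run_pipeline` executes all stages from a single JSON-serializable
`PipelineConfig`, writing a report bundle (cohort file, degree-statistics
CSV, pair-delta CSV, partition JSON, feature CSVs, evaluation JSONs,
per-dimension screening CSV, and a manifest echoing the config, its hash,
stage counts and library versions).  Each stage is also callable on its own
from the upstream artifacts.

One master seed spawns deterministic per-stage child seeds, so the whole
bundle is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import RoiPartition, WelchParams
from .evaluate import ClassifierSpec, SplitScheme, loo_evaluate, mcr_evaluate
from .features import (
    FEATURE_DIM,
    FeatureDataset,
    PreprocessParams,
    build_feature_dataset,
    node_band_labels,
    roi_feature_tensor,
)
from .io import read_cohort, write_cohort
from .model import ConnectivityAnalysis
from .stats_tests import per_dimension_screen
from .synth import CLASS_LABELS, SynthParams, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


def _from_mapping(cls, mapping, name):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in {name}: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("roi_labels", "hyper_pairs", "spectral_effect_band", "band"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[key]
            )
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    synth: SynthParams = field(default_factory=SynthParams)
    est: WelchParams = field(default_factory=WelchParams)
    band: tuple = (0.5, 80.0)
    epoch_len: float = 1.0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    feature_epoch_len: float = 10.0
    aggregation: str = "mean"
    balance: bool = True
    partition_override: dict | None = None  # {"hyper": [...], "hypo": [...]}
    groups: tuple = ("hyper", "hypo", "all")
    mcr_classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("knn", k=3))
    loo_classifier: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec("svm", kernel="rbf")
    )
    mcr: SplitScheme = field(default_factory=SplitScheme)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "megcoh_out"
    verbosity: int = 1

    _NESTED = {
        "synth": SynthParams,
        "est": WelchParams,
        "preprocess": PreprocessParams,
        "mcr_classifier": ClassifierSpec,
        "loo_classifier": ClassifierSpec,
        "mcr": SplitScheme,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in d.items():
            if key in cls._NESTED and isinstance(value, dict):
                kwargs[key] = _from_mapping(cls._NESTED[key], value, key)
            elif key in ("band", "groups") and isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages and write the report bundle; returns artifacts."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {},
    }
    counts = manifest["counts"]

    # --- stage 1: generate -------------------------------------------------
    synth = config.synth.replace(seed=child_seed(config.seed, "generate"))
    cohort = generate_cohort(synth)
    cohort_path = out / "cohort.h5"
    write_cohort(cohort, cohort_path)
    counts["n_subjects"] = len(cohort.subjects)
    counts["n_samples_per_subject"] = cohort.subjects[0].n_samples
    logger.info("generate: %d subjects, %d samples each", len(cohort.subjects),
                cohort.subjects[0].n_samples)

    # --- stage 2: connect --------------------------------------------------
    analysis = ConnectivityAnalysis(
        cohort,
        band=config.band,
        epoch_len=config.epoch_len,
        est=config.est,
        balance=config.balance,
    )
    conn = analysis.fit()
    if config.partition_override:
        conn.partition = RoiPartition(
            hyper=frozenset(config.partition_override["hyper"]),
            hypo=frozenset(config.partition_override["hypo"]),
            evidence=conn.pair_table,
        )
    conn.stats_table.reset_index().to_csv(out / "connectivity_stats.csv", index=False)
    conn.pair_table.to_csv(out / "pair_deltas.csv", index=False)
    (out / "partition.json").write_text(
        json.dumps(
            {
                "hyper": sorted(conn.partition.hyper),
                "hypo": sorted(conn.partition.hypo),
                "config_hash": config.config_hash(),
            },
            indent=1,
        )
    )
    n_pairs = len(conn.pair_table)
    epochs_per_subject = conn.coherence.n_epochs_per_subject
    n_subj_per_class = conn.coherence.matrices["HC"].shape[0]
    counts["n_roi_pairs"] = n_pairs
    counts["epochs_per_class_per_roi"] = n_subj_per_class * epochs_per_subject
    counts["total_mscoh_evaluations"] = conn.coherence.n_pair_evaluations
    counts["n_inter_hemispheric_pairs"] = int(
        sum(1 for _, r in conn.pair_table.iterrows() if r["roi_a"][0] != r["roi_b"][0])
    )
    counts["n_intra_hemispheric_pairs"] = n_pairs - counts["n_inter_hemispheric_pairs"]
    logger.info(
        "connect: %d unique pairs (%d inter / %d intra), %d epochs per class per "
        "ROI, %d MS-COH evaluations in total",
        n_pairs,
        counts["n_inter_hemispheric_pairs"],
        counts["n_intra_hemispheric_pairs"],
        counts["epochs_per_class_per_roi"],
        counts["total_mscoh_evaluations"],
    )

    # --- stage 3: features -------------------------------------------------
    tensor = roi_feature_tensor(cohort, config.preprocess, config.feature_epoch_len)
    feature_sets: dict[str, FeatureDataset] = {}
    for group in config.groups:
        fd = build_feature_dataset(
            cohort,
            conn.partition,
            group=group,
            aggregation=config.aggregation,
            pre=config.preprocess,
            epoch_len=config.feature_epoch_len,
            tensor=tensor,
        )
        feature_sets[group] = fd
        df = pd.DataFrame(fd.X, columns=fd.feature_labels)
        df.insert(0, "epoch", fd.epoch_indices)
        df.insert(0, "class", [CLASS_LABELS[c] for c in fd.y])
        df.insert(0, "subject_id", fd.subject_ids)
        df.to_csv(out / f"features_{group}.csv", index=False)
    any_fd = next(iter(feature_sets.values()))
    counts["feature_dim_per_roi"] = FEATURE_DIM
    counts["feature_epochs_per_subject"] = tensor["HC"][0].shape[1]
    counts["observations_per_class"] = int(np.sum(any_fd.y == 0))
    logger.info(
        "features: %d dims per ROI, %d feature epochs per subject, "
        "%d observations per class",
        FEATURE_DIM,
        counts["feature_epochs_per_subject"],
        counts["observations_per_class"],
    )

    # --- stage 4: classify -------------------------------------------------
    eval_results = {}
    mcr_scheme = dataclasses.replace(config.mcr, seed=child_seed(config.seed, "mcr"))
    for group, fd in feature_sets.items():
        eval_results[(group, "MCR")] = mcr_evaluate(fd, config.mcr_classifier, mcr_scheme)
        eval_results[(group, "LOO")] = loo_evaluate(fd, config.loo_classifier)
    for (group, scheme), res in eval_results.items():
        payload = res.to_dict()
        payload["config_hash"] = config.config_hash()
        (out / f"eval_{group}_{scheme.lower()}.json").write_text(
            json.dumps(payload, indent=1)
        )
        logger.info(
            "classify %s/%s: balanced accuracy %.2f%%",
            group,
            scheme,
            100 * res.balanced_accuracy,
        )

    # --- stage 5: stats ----------------------------------------------------
    hyper_fd = feature_sets.get("hyper", any_fd)
    if hyper_fd.aggregation == "mean":
        screen_labels = node_band_labels(config.preprocess.target_fs)
    else:
        screen_labels = hyper_fd.feature_labels
    table, mask = per_dimension_screen(
        hyper_fd.class_matrix("HC"),
        hyper_fd.class_matrix("MCI"),
        alpha=config.alpha,
        labels=screen_labels,
    )
    table.to_csv(out / "dimension_screen.csv", index=False)
    counts["jointly_significant_dims"] = int(mask.sum())
    logger.info("stats: %d/%d dimensions jointly significant", mask.sum(), mask.size)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "out_dir": out,
        "cohort": cohort,
        "connectivity": conn,
        "features": feature_sets,
        "evaluations": eval_results,
        "screen": table,
        "manifest": manifest,
    }


def _versions() -> dict:
    import h5py
    import pywt
    import scipy
    import sklearn

    import megcoh

    return {
        "megcoh": megcoh.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "pywavelets": pywt.__version__,
        "h5py": h5py.__version__,
    }
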