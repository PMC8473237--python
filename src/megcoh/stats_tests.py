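"""Statistical screening: location tests, normality check, Holm correction.

Per feature dimension (or per coherence set) the screen runs a pooled-variance
two-sample t-test and a Kruskal-Wallis rank test, corrects each family with
the Holm-Bonferroni step-down procedure, and flags dimensions significant
under both tests at alpha = 0.05.  An Anderson-Darling normality check
(normal family, estimated parameters) is provided for the coherence sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class PValueRecord:
    label: str
    test: str
    statistic: float
    p: float
    p_corrected: float | None = None
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0,1]")
        if self.p_corrected is not None and not (
            self.p - 1e-12 <= self.p_corrected <= 1.0 + 1e-12
        ):
            raise ValueError("p_corrected must be in [p, 1]")

    @property
    def significant(self) -> bool:
        return (self.p_corrected if self.p_corrected is not None else self.p) < self.alpha


def two_sample_t(
    sample_a, sample_b, label: str = "", equal_var: bool = True
) -> PValueRecord:
    """Two-sided pooled-variance Student t-test for equality of means.

    ``equal_var=False`` switches to the Welch form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return PValueRecord(label=label, test="t", statistic=float(t), p=float(p))


def kruskal_wallis(sample_a, sample_b, label: str = "") -> PValueRecord:
    """Kruskal-Wallis rank test (tie-corrected, chi-square approximation)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        raise ValueError("all values tied across both samples")
    h, p = stats.kruskal(a, b)
    return PValueRecord(label=label, test="kruskal_wallis", statistic=float(h), p=float(p))


def _ad_normal_pvalue(a2: float, n: int) -> float:
    """D'Agostino-Stephens p-value approximation for the A^2 statistic
    against a normal with estimated mean and variance."""
    z = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if z >= 0.6:
        p = math.exp(1.2937 - 5.709 * z + 0.0186 * z * z)
    elif z >= 0.34:
        p = math.exp(0.9177 - 4.279 * z - 1.38 * z * z)
    elif z >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * z - 59.938 * z * z)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * z - 223.73 * z * z)
    return min(max(p, 0.0), 1.0)


def anderson_darling(sample, label: str = "", alpha: float = DEFAULT_ALPHA) -> PValueRecord:
    """Anderson-Darling normality test (normal family, estimated parameters).

    Requires n >= 8; the decision is taken at the 5% level by default.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("Anderson-Darling requires n >= 8")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample")
    with warnings.catch_warnings():
        # the statistic is stable across scipy versions; the p-value comes
        # from the D'Agostino-Stephens formula below, not scipy's tables
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    a2 = float(res.statistic)
    return PValueRecord(
        label=label,
        test="anderson_darling",
        statistic=a2,
        p=_ad_normal_pvalue(a2, x.size),
        alpha=alpha,
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending
    order, then un-sorted; every adjusted value >= the raw value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a non-empty 1-D p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="holm")[1]


def per_dimension_screen(
    features_hc: np.ndarray,
    features_mci: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    labels=None,
    correction_family: str = "significant",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run both location tests per feature dimension.

    Returns a table with raw and Holm-corrected p-values per test family plus
    the joint-significance mask (raw p < alpha under BOTH tests).  With
    ``correction_family='significant'`` the Holm family is the set of jointly
    significant dimensions (the dimensions entering the reported table);
    ``'all'`` corrects across every dimension.
    """
    a = np.atleast_2d(np.asarray(features_hc, dtype=float))
    b = np.atleast_2d(np.asarray(features_mci, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch between the two feature sets")
    d = a.shape[1]
    labels = list(labels) if labels is not None else [f"dim{i}" for i in range(d)]
    if len(labels) != d:
        raise ValueError("labels must match dimensionality")
    t_p = np.empty(d)
    t_stat = np.empty(d)
    kw_p = np.empty(d)
    kw_stat = np.empty(d)
    for i in range(d):
        rt = two_sample_t(a[:, i], b[:, i])
        rk = kruskal_wallis(a[:, i], b[:, i])
        t_p[i], t_stat[i] = rt.p, rt.statistic
        kw_p[i], kw_stat[i] = rk.p, rk.statistic
    mask = (t_p < alpha) & (kw_p < alpha)
    t_corr = np.full(d, np.nan)
    kw_corr = np.full(d, np.nan)
    if correction_family == "significant":
        if mask.any():
            t_corr[mask] = holm_bonferroni(t_p[mask])
            kw_corr[mask] = holm_bonferroni(kw_p[mask])
    elif correction_family == "all":
        t_corr = holm_bonferroni(t_p)
        kw_corr = holm_bonferroni(kw_p)
    else:
        raise ValueError("correction_family must be 'significant' or 'all'")
    table = pd.DataFrame(
        {
            "band": labels,
            "t_stat": t_stat,
            "t_p": t_p,
            "t_p_corrected": t_corr,
            "kw_stat": kw_stat,
            "kw_p": kw_p,
            "kw_p_corrected": kw_corr,
            "joint_significant": mask,
        }
    )
    return table, mask
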