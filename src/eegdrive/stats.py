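"""Statistical framework: t-tests, effect sizes, FDR families, bootstrap,
Fisher combination and subregional consistency metrics.

Confirmatory tests are grouped into four families (whole-brain maps, ROI
activation, frequency modulation, connectivity); p-values are adjusted with
the Benjamini-Hochberg step-up procedure *within* family, with Bonferroni
available as an option.  One-tailed tests are used only where an explicit
predicted direction is supplied; bootstrap confidence intervals are
percentile intervals over 5,000 resamples by default, with a two-sided
bootstrap p for H0: stat = 0 defined as ``2 * min(P(stat* <= 0),
P(stat* >= 0))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TEST_FAMILIES", "StatResult", "one_sample_t", "paired_t", "bh_fdr",
    "bonferroni", "bootstrap_ci", "fisher_combine", "roi_consistency",
]

TEST_FAMILIES = ("whole-brain-maps", "roi-activation",
                 "frequency-modulation", "connectivity")


@dataclass
class StatResult:
    estimate: float
    t: float
    df: int
    p_raw: float
    cohen_d: float
    tails: str = "two"
    family: str | None = None
    p_fdr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def one_sample_t(values: np.ndarray, mu0: float = 0.0, tails: str = "two",
                 family: str | None = None) -> StatResult:
    """One-sample t-test against ``mu0``; one-tailed only for directional tests.

    ``tails`` is 'two', 'greater' or 'less'.  Zero-variance input is flagged
    degenerate (t undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values")
    sd = x.std(ddof=1)
    mean = float(x.mean())
    if sd == 0:
        logger.warning("one_sample_t: zero variance, degenerate")
        return StatResult(estimate=mean - mu0, t=np.nan, df=x.size - 1, p_raw=np.nan,
                          cohen_d=np.nan, tails=tails, family=family, degenerate=True)
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[tails]
    res = sps.ttest_1samp(x, mu0, alternative=alternative)
    d = (mean - mu0) / sd
    return StatResult(estimate=mean - mu0, t=float(res.statistic), df=x.size - 1,
                      p_raw=float(res.pvalue), cohen_d=float(d), tails=tails,
                      family=family)


def paired_t(values_a: np.ndarray, values_b: np.ndarray, tails: str = "two",
             family: str | None = None) -> StatResult:
    """Paired t-test = one-sample t on the differences."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, tails=tails, family=family)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return np.minimum(p * p.size, 1.0)


def adjust_family(results: list[StatResult], method: str = "fdr") -> list[StatResult]:
    """Attach adjusted p-values within one test family."""
    p = np.array([r.p_raw for r in results])
    finite = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if finite.any():
        adj[finite] = bh_fdr(p[finite]) if method == "fdr" else bonferroni(p[finite])
    for r, a in zip(results, adj):
        r.p_fdr = float(a) if np.isfinite(a) else None
    return results


def bootstrap_ci(values: np.ndarray, n_boot: int = 5000, stat=np.mean,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile 95% bootstrap CI and two-sided bootstrap p for H0: stat = 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.apply_along_axis(stat, 1, x[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2 * min(np.mean(boots <= 0), np.mean(boots >= 0))
    return float(lo), float(hi), float(min(p, 1.0))


def fisher_combine(p_values) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi2(2k); returns the upper-tail p.

    Zero p-values are clipped at the machine floor (and logged).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("fisher_combine: zero p-values clipped to machine floor")
        p = np.maximum(p, np.finfo(float).tiny)
    stat, p_comb = sps.combine_pvalues(p, method="fisher")
    return float(p_comb)


def roi_consistency(subregion_timecourses: np.ndarray, fs: float, tmin: float,
                    window: tuple[float, float] = (0.1, 0.8),
                    ) -> tuple[float, float, float]:
    """Consistency of a contrast across the subregions of one ROI.

    Returns ``(directional agreement %, mean pairwise r, one-way ANOVA p)``:
    agreement is the share of subregions whose window-mean contrast has the
    majority sign (> 80% read as consistent); the mean pairwise Pearson r of
    the subregion time courses (> 0.5 read as temporally coherent); and a
    one-way ANOVA across subregions over window samples (p > 0.05 read as
    homogeneity).  The ANOVA p is NaN (degenerate) for identical inputs.
    """
    x = np.asarray(subregion_timecourses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 subregion time courses")
    t = tmin + np.arange(x.shape[1]) / fs
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    win_means = x[:, mask].mean(axis=1)
    signs = np.sign(win_means)
    if np.all(signs == 0):
        agreement = 100.0
    else:
        pos = np.sum(signs > 0)
        neg = np.sum(signs < 0)
        agreement = 100.0 * max(pos, neg) / x.shape[0]
    rs = []
    for i in range(x.shape[0]):
        for j in range(i + 1, x.shape[0]):
            sd_i, sd_j = x[i].std(), x[j].std()
            rs.append(np.corrcoef(x[i], x[j])[0, 1] if sd_i > 0 and sd_j > 0 else 1.0)
    mean_r = float(np.mean(rs))
    groups = [x[i, mask] for i in range(x.shape[0])]
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        anova_p = float("nan")  # no between-group variance: degenerate
    else:
        _, anova_p = sps.f_oneway(*groups)
    return float(agreement), mean_r, float(anova_p)
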