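"""Condition-level statistics: one-way repeated-measures ANOVA with
Greenhouse-Geisser correction and Mauchly's sphericity test, approximate
(BIC-based) Bayes factors, Holm-adjusted paired post-hoc tests, and the
pooled trial-wise pupil-RT correlation.

Bayes factors here are the BIC approximation
``BF10 = exp((BIC_null - BIC_alt) / 2)`` from the corresponding
fixed-effects fits.  This is monotonically consistent with the evidence
but is *not* a Cauchy-prior Bayes factor; it is labeled approximate
throughout.  Holm correction stands in for prior-adjusted posterior
odds in the post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import ACTIVE_CONDITIONS


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way within-subject ANOVA summary.

    ``p_reported`` is the GG-corrected p when Mauchly's test rejects
    sphericity at .05, the uncorrected p otherwise.
    """

    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    p_gg: float
    log_bf10_bic: float
    mauchly_p: float
    n: int
    k: int

    @property
    def bf10_bic(self) -> float:
        return float(np.exp(min(self.log_bf10_bic, 700.0)))

    @property
    def p_reported(self) -> float:
        return self.p_gg if self.mauchly_p < 0.05 else self.p

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df1": self.df1, "df2": self.df2, "p": self.p,
            "gg_epsilon": self.gg_epsilon, "p_gg": self.p_gg,
            "p_reported": self.p_reported, "bf10_bic": self.bf10_bic,
            "log_bf10_bic": self.log_bf10_bic, "mauchly_p": self.mauchly_p,
            "n": self.n, "k": self.k,
        }


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple[str, str]
    t: float
    df: int
    p: float
    p_holm: float
    log_bf10_bic: float

    @property
    def bf10_bic(self) -> float:
        return float(np.exp(min(self.log_bf10_bic, 700.0)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    c = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(c[:, : k - 1])
    return q.T


def _anova_ss(values: np.ndarray):
    n, k = values.shape
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    return ss_cond, ss_subj, max(ss_err, 0.0)


def gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition-score covariance."""
    n, k = values.shape
    S = np.cov(values, rowvar=False, ddof=1)
    C = _orthonormal_contrasts(k)
    Sc = C @ S @ C.T
    tr = np.trace(Sc)
    denom = (k - 1) * np.trace(Sc @ Sc)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr ** 2 / denom))


def mauchly_test(values: np.ndarray) -> float:
    """Mauchly's sphericity test; returns the p-value.

    Uses the chi-square approximation on the orthonormal-contrast
    covariance.  Returns 1.0 when the test is degenerate (k = 2 or a
    singular contrast covariance).
    """
    n, k = values.shape
    if k <= 2:
        return 1.0
    C = _orthonormal_contrasts(k)
    Sc = C @ np.cov(values, rowvar=False, ddof=1) @ C.T
    d = k - 1
    eig = np.linalg.eigvalsh(Sc)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (np.mean(eig) ** d)
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, df))


def rm_anova(values: np.ndarray | pd.DataFrame) -> RmAnovaResult:
    """Classical one-way within-subject ANOVA (subject x condition).

    ``values`` is a complete subject x condition matrix (n >= 3 rows,
    k >= 2 columns).  The approximate Bayes factor compares the
    fixed-effects fits with and without the condition term.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be complete (finite)")
    ss_cond, _, ss_err = _anova_ss(values)
    if ss_err == 0 and ss_cond == 0:
        raise ValueError("constant data: F undefined")
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = np.inf if ms_err == 0 else ms_cond / ms_err
    eps = gg_epsilon(values)
    p = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    # BIC approximation: null = subject effects only, alt = + condition
    N = n * k
    rss_null = ss_cond + ss_err
    rss_alt = ss_err
    if rss_alt == 0:
        log_bf = np.inf
    else:
        log_bf = 0.5 * (N * np.log(rss_null / rss_alt) - df1 * np.log(N))
    return RmAnovaResult(
        F=float(F), df1=df1, df2=df2, p=p, gg_epsilon=eps, p_gg=p_gg,
        log_bf10_bic=float(log_bf), mauchly_p=mauchly_test(values), n=n, k=k,
    )


def rm_anova_f_map(values: np.ndarray) -> np.ndarray:
    """Vectorized within-subject one-way ANOVA F over the last axis.

    ``values`` has shape (n_subjects, k_conditions, n_voxels); returns
    the F statistic per voxel.  Degenerate voxels (zero error variance)
    yield inf or nan as the arithmetic dictates.
    """
    n, k, _ = values.shape
    grand = values.mean(axis=(0, 1))
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2, axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2, axis=0)
    ss_tot = np.sum((values - grand) ** 2, axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    # no condition variability (up to float epsilon) -> no effect
    negligible = ss_cond <= 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    return np.where(negligible, 0.0, F)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _paired_t(x: np.ndarray, y: np.ndarray):
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    # BIC Bayes factor for the one-sample test on the differences
    rss0 = np.sum(d ** 2)
    rss1 = np.sum((d - mean) ** 2)
    if rss1 == 0:
        log_bf = np.inf if mean != 0 else -0.5 * np.log(n)
    elif rss0 == 0:
        log_bf = -0.5 * np.log(n)
    else:
        log_bf = 0.5 * (n * np.log(rss0 / rss1) - np.log(n))
    return float(t), p, float(log_bf)


def posthoc_paired(values: np.ndarray | pd.DataFrame,
                   labels: list[str] | None = None) -> list[PairedComparison]:
    """All pairwise paired t-tests with Holm adjustment and BIC BFs."""
    if isinstance(values, pd.DataFrame):
        labels = labels or [str(c) for c in values.columns]
        values = values.to_numpy(float)
    values = np.asarray(values, float)
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    labels = labels or [f"c{i}" for i in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = [_paired_t(values[:, i], values[:, j]) for i, j in pairs]
    p_holm = holm_adjust([r[1] for r in raw])
    return [
        PairedComparison(pair=(labels[i], labels[j]), t=t, df=n - 1,
                         p=p, p_holm=float(ph), log_bf10_bic=lb)
        for (i, j), (t, p, lb), ph in zip(pairs, raw, p_holm)
    ]


def pupil_rt_correlation(features: pd.DataFrame, outcomes: pd.DataFrame) -> dict:
    """Pooled Pearson correlation between trial-mean pupil size and RT.

    Qualifying trials are hits on target trials of the active
    conditions, pooled across all subjects (a ``subject`` column, if
    present, joins the two tables alongside block and trial indices).
    The 10-Hz trial-mean pupil value comes from the features table.
    """
    keys = ["block_index", "trial_index"]
    if "subject" in features.columns and "subject" in outcomes.columns:
        keys = ["subject"] + keys
    merged = features.merge(
        outcomes[keys + ["outcome", "rt"]], on=keys, how="inner")
    active = {c.value for c in ACTIVE_CONDITIONS}
    sel = (merged["outcome"] == "hit") & merged["is_target"] & merged["condition"].isin(active)
    sub = merged.loc[sel].dropna(subset=["trial_mean_pupil", "rt"])
    if len(sub) < 3:
        raise ValueError("fewer than 3 qualifying trials for the pupil-RT correlation")
    r, p = sps.pearsonr(sub["trial_mean_pupil"], sub["rt"])
    return {"r": float(r), "p": float(p), "n_trials": int(len(sub))}
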