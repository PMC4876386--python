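"""Differential-expression and diversity statistics.

The core test mirrors the paired fold-change analysis: counts are
normalized with median-of-ratios size factors, per-subject log2 ratios
(after vs before, with a pseudocount) are computed per feature, and the
mean of the log ratios is tested against zero; p-values are BH-adjusted.
A two-independent-group variant of the same log-scale t test serves the
mock-community experiments.  Friedman's rank test, permutation-based
Spearman correlation, and a PCA summary of log-transformed abundance
matrices complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial, log2
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .seqio import AbundanceMatrix


@dataclass(frozen=True)
class PairedDesign:
    """Matched before/after samples per subject."""

    subjects: tuple[str, ...]
    before: tuple[str, ...]
    after: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.subjects) == len(self.before) == len(self.after)):
            raise ValueError("subjects, before and after must have equal length")
        all_samples = list(self.before) + list(self.after)
        if len(set(all_samples)) != len(all_samples):
            raise ValueError("each sample may appear in exactly one pair")


def size_factors(matrix: AbundanceMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    Uses only features with a nonzero count in every sample, as in the
    standard RNA-seq median-of-ratios scheme.  With no such feature, pass a
    positive ``pseudocount`` to compute factors on count + pseudocount.
    """
    df = matrix.df.astype(float) + pseudocount
    positive = df[(df > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "consider a pseudocount before normalization"
        )
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Size-factor-normalized counts; falls back to pseudocount factors
    (with a warning) when no feature is nonzero in every sample."""
    try:
        factors = size_factors(matrix)
    except ValueError:
        import warnings

        warnings.warn(
            "no feature nonzero in all samples; size factors computed on "
            "counts + 1"
        )
        factors = size_factors(matrix, pseudocount=1.0)
    return matrix.df.astype(float) / factors


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_ratio_frame(
    matrix: AbundanceMatrix, pseudocount: float, use_size_factors: bool = True
) -> pd.DataFrame:
    df = normalize(matrix) if use_size_factors else matrix.df.astype(float)
    return np.log2(df + pseudocount)


def paired_logratio_test(
    matrix: AbundanceMatrix,
    design: PairedDesign,
    pseudocount: float = 1.0,
    test: str = "t",
) -> pd.DataFrame:
    """Mean-of-log-ratios differential expression for a paired design.

    For each feature, r_i = log2((after_i + pc) / (before_i + pc)) over
    subjects i (on size-factor-normalized counts); log2fc is the mean of
    the r_i and p comes from a two-sided one-sample test of the r_i
    against zero (t by default, ``test='wilcoxon'`` for the signed-rank
    alternative).  Features at zero in every involved sample get p = 1,
    log2fc = 0.  Returns a DataFrame with columns feature, mean_count,
    log2fc, p, q (BH over tested features).
    """
    if len(design.subjects) < 2:
        raise ValueError("need >= 2 subjects for a variance estimate")
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    norm = normalize(matrix)
    before = norm[list(design.before)].to_numpy()
    after = norm[list(design.after)].to_numpy()
    ratios = np.log2(after + pseudocount) - np.log2(before + pseudocount)
    log2fc = ratios.mean(axis=1)
    pvals = np.ones(len(log2fc))
    for i, r in enumerate(ratios):
        if np.allclose(r, 0.0):
            log2fc[i] = 0.0
            continue
        if test == "t":
            if np.allclose(r, r[0]):
                pvals[i] = 0.0  # zero variance away from 0: maximal evidence
            else:
                pvals[i] = sps.ttest_1samp(r, 0.0).pvalue
        else:
            pvals[i] = sps.wilcoxon(r).pvalue
    out = pd.DataFrame(
        {
            "feature": matrix.features,
            "mean_count": norm.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def group_logratio_test(
    matrix: AbundanceMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-independent-group variant: Welch t on log2(normalized + pc).

    The p-value comes from the t test on the log scale; the reported
    log2fc is the log2 ratio of group mean normalized counts (with the
    pseudocount added to the means), which is far less attenuated at low
    depth than a difference of log-transformed means.  Size factors are
    computed on counts + pseudocount so that features with occasional
    zeros still inform the median — excluding them biases the factors
    toward the up-regulated features at shallow depth.  Used for the
    mock-community experiments, whose groups are independent samples.
    """
    if min(len(group1), len(group2)) < 2:
        raise ValueError("each group needs >= 2 samples")
    factors = size_factors(matrix, pseudocount=max(pseudocount, 1e-8))
    norm = matrix.df.astype(float) / factors
    logc = np.log2(norm + pseudocount)
    x1 = logc[list(group1)].to_numpy()
    x2 = logc[list(group2)].to_numpy()
    mean1 = norm[list(group1)].mean(axis=1).to_numpy()
    mean2 = norm[list(group2)].mean(axis=1).to_numpy()
    log2fc = np.log2(mean2 + pseudocount) - np.log2(mean1 + pseudocount)
    pvals = np.ones(len(log2fc))
    for i in range(len(log2fc)):
        a, b = x1[i], x2[i]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            # no within-group variance: identical groups are null evidence,
            # separated constant groups are maximal evidence
            pvals[i] = 1.0 if np.isclose(a[0], b[0]) else 0.0
            continue
        pvals[i] = sps.ttest_ind(b, a, equal_var=False).pvalue
    out = pd.DataFrame(
        {
            "feature": matrix.features,
            "mean_count": matrix.df.astype(float).mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def select_de(
    results: pd.DataFrame, alpha: float = 0.01, min_abs_lfc: float = 1.0
) -> pd.DataFrame:
    """Significant features at the default cutoffs q < 0.01, |log2fc| > 1."""
    mask = (results["q"] < alpha) & (results["log2fc"].abs() > min_abs_lfc)
    return results[mask].copy()


# ---------------------------------------------------------------------------
# nonparametric tests


def friedman_test(values: np.ndarray, exact: bool = False) -> tuple[float, float]:
    """Friedman chi-square over subjects (rows) x conditions (columns).

    Within-subject midranks with tie correction; df = k - 1.  With
    ``exact=True`` the p-value is computed by enumerating all within-
    subject rank permutations (requires (k!)^n <= 1e6).  All-constant rows
    yield statistic 0, p 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    statistic = _friedman_statistic(ranks, n, k)
    if statistic == 0.0:
        return 0.0, 1.0
    if exact:
        if factorial(k) ** n > 1_000_000:
            raise ValueError("exact enumeration too large; use the asymptotic p")
        perms = list(permutations(range(1, k + 1)))
        count = 0
        total = 0
        # enumerate rank assignments per subject; ties in the observed data
        # are handled by enumerating raw rank permutations (the null of
        # exchangeability within subjects)
        from itertools import product

        for combo in product(perms, repeat=n):
            r = np.asarray(combo, dtype=float)
            stat = _friedman_statistic(r, n, k)
            total += 1
            if stat >= statistic - 1e-12:
                count += 1
        return statistic, count / total
    p = sps.chi2.sf(statistic, k - 1)
    return statistic, float(p)


def _friedman_statistic(ranks: np.ndarray, n: int, k: int) -> float:
    rank_sums = ranks.sum(axis=0)
    raw = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction from within-subject tie groups
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0
    return float(raw / correction)


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho with permutation-based two-sided significance.

    rho is the Pearson correlation of midranks.  The p-value permutes y:
    exact enumeration over all n! orderings when n! <= n_perm (p = exact
    fraction with |rho_perm| >= |rho|), otherwise ``n_perm`` random
    permutations with the add-one estimator (p is never zero).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.allclose(xa, xa[0]) or np.allclose(ya, ya[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)

    def rho_of(r2: np.ndarray) -> float:
        return float(np.corrcoef(rx, r2)[0, 1])

    rho = rho_of(ry)
    n = len(xa)
    if factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(rho_of(np.asarray(perm))) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(rho_of(rng.permutation(ry))) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# ordination


def pca_scores(
    matrix: AbundanceMatrix, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of log2(normalized + 1) counts; returns (scores, percent variance).

    Features are centered; components come from the SVD of the samples x
    features matrix.  Sign convention: the largest-magnitude feature
    loading of each component is made positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    logc = _log_ratio_frame(matrix, pseudocount)
    x = logc.to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    with np.errstate(invalid="ignore", divide="ignore"):
        total = float(np.sum(s**2))
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.samples, columns=cols), pct
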