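"""Assessment metrics: correlations against ground truth, per-branch
precision/recall/F1, and rank tests on differentiation potential."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ValidationError
from .results import PROGENITOR


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, Spearman rho, and Kendall tau.

    ``kendall`` is the tie-naive pairwise-sign statistic
    sum_{i != j} sgn(x_i - x_j) sgn(y_i - y_j) / (n (n - 1)): tied pairs
    drop out of the numerator while the denominator keeps all ordered
    pairs (a tau-a-like convention).  ``kendall_b`` is the standard
    tie-corrected tau-b for comparison.
    """

    pearson: float
    spearman: float
    kendall: float
    kendall_b: float


def kendall_tau_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    """The pairwise-sign Kendall statistic over ordered pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    return float((sx * sy).sum() / (n * (n - 1)))


def correlations(estimate, truth) -> CorrelationResult:
    """Correlation triple between an estimated and a reference ordering."""
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValidationError("estimate and truth must be equal-length vectors")
    if est.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.isnan(est).any() or np.isnan(tru).any():
        raise ValidationError("NaN values are not allowed")
    if np.ptp(est) == 0 or np.ptp(tru) == 0:
        warnings.warn("constant vector: correlations are undefined (NaN)")
        return CorrelationResult(float("nan"), float("nan"), float("nan"), float("nan"))
    r = stats.pearsonr(est, tru).statistic
    rho = stats.spearmanr(est, tru).statistic
    tau_b = stats.kendalltau(est, tru).statistic
    return CorrelationResult(float(r), float(rho), kendall_tau_pairwise(est, tru), float(tau_b))


@dataclass(frozen=True)
class BranchConfusion:
    """One-vs-rest confusion counts for a terminal branch.

    Progenitor predictions count as "not this branch" everywhere, so an
    unassigned cell whose true fate is the target branch is a false
    negative.  Empty denominators yield 0 by convention.
    """

    branch: object
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def branch_f1(predicted, truth, branch) -> BranchConfusion:
    """Binary one-vs-rest confusion for ``branch``."""
    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    if pred.shape != tru.shape:
        raise ValidationError("predicted and truth must have equal length")
    in_pred = pred == branch
    in_true = tru == branch
    tp = int(np.sum(in_pred & in_true))
    fp = int(np.sum(in_pred & ~in_true))
    fn = int(np.sum(~in_pred & in_true))
    return BranchConfusion(branch, tp, fp, fn)


def all_branch_f1(predicted, truth, branches=None) -> dict:
    tru = np.asarray(truth)
    if branches is None:
        branches = [b for b in np.unique(tru) if b != PROGENITOR]
    return {b: branch_f1(predicted, truth, b) for b in branches}


def dp_group_tests(dp, labels, ordered_pairs):
    """Kruskal-Wallis across groups plus one-tailed Mann-Whitney per pair.

    Each (earlier, later) pair tests whether the earlier state has HIGHER
    differentiation potential (alternative='greater').  Exact Mann-Whitney
    null for small tie-free groups, normal approximation with tie
    correction otherwise.
    """
    dp = np.asarray(dp, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for lab in np.unique(labels):
        vals = dp[labels == lab]
        if vals.size < 2:
            raise ValidationError(f"group {lab!r} has fewer than 2 members")
        groups[lab] = vals
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    kw = stats.kruskal(*groups.values())
    mwu = {}
    for earlier, later in ordered_pairs:
        if earlier not in groups or later not in groups:
            raise ValidationError(f"unknown group in pair ({earlier!r}, {later!r})")
        a, b = groups[earlier], groups[later]
        small = a.size <= 20 and b.size <= 20
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
        mwu[(earlier, later)] = float(res.pvalue)
    return float(kw.statistic), float(kw.pvalue), mwu
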