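"""ROC metrics and AUC inference.

Implements the Mann-Whitney AUC estimator (ties half-weighted), operating
point metrics, stratified-bootstrap percentile confidence intervals, an
unpaired bootstrap AUC comparison for independent cohorts, and DeLong's
paired test for correlated AUCs.  All resampling is stratified: positives
and negatives are resampled independently so every replicate keeps both
classes, matching the behaviour of pROC's ``ci.auc``/``roc.test`` with
``boot.stratified = TRUE``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "RocResult",
    "ComparisonResult",
    "auc",
    "operating_metrics",
    "bootstrap_ci",
    "roc_result",
    "compare_unpaired",
    "delong_test",
]


@dataclass(frozen=True)
class RocResult:
    """Point estimates plus a percentile-bootstrap CI for one score set."""

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-AUC comparison."""

    method: str  # "delong" | "bootstrap_unpaired"
    statistic: float
    p_value: float
    delta_auc: float
    two_tailed: bool = True
    alpha: float = 0.05
    n_boot: int | None = None


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise InputError("scores must be finite")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney U-statistic AUC; tied pairs count one half.

    Equivalent to the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _validate(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties: lowest)."""
    pos, neg = _validate(scores, labels)
    scores = np.asarray(scores, dtype=float)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        j = np.mean(pos >= t) + np.mean(neg < t) - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def operating_metrics(scores, labels, threshold: float = 0.5):
    """Sensitivity, specificity and accuracy for ``score >= threshold``."""
    pos, neg = _validate(scores, labels)
    tp = int(np.sum(pos >= threshold))
    tn = int(np.sum(neg < threshold))
    sens = tp / len(pos)
    spec = tn / len(neg)
    acc = (tp + tn) / (len(pos) + len(neg))
    return sens, spec, acc


def _boot_auc_replicates(pos, neg, n_boot, rng):
    """Vectorized stratified-bootstrap AUC replicates.

    Memory is O(n_boot * n_pos * n_neg); chunked to stay below ~64 MB.
    """
    n_pos, n_neg = len(pos), len(neg)
    out = np.empty(n_boot)
    chunk = max(1, int(8e6 / max(1, n_pos * n_neg)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        ps = pos[rng.integers(0, n_pos, size=(b, n_pos))]
        ns = neg[rng.integers(0, n_neg, size=(b, n_neg))]
        gt = (ps[:, :, None] > ns[:, None, :]).sum(axis=(1, 2))
        eq = (ps[:, :, None] == ns[:, None, :]).sum(axis=(1, 2))
        out[start : start + b] = (gt + 0.5 * eq) / (n_pos * n_neg)
    return out


def bootstrap_ci(scores, labels, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05):
    """Percentile CI of AUC from a stratified bootstrap (default 2000 reps)."""
    pos, neg = _validate(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise InputError("bootstrap_ci needs at least 2 cases per class")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is too small for stable percentiles", RuntimeWarning)
    rng = np.random.default_rng(seed)
    reps = _boot_auc_replicates(pos, neg, n_boot, rng)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def roc_result(scores, labels, threshold: float = 0.5, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Full evaluation bundle at one operating threshold."""
    pos, neg = _validate(scores, labels)
    a = auc(scores, labels)
    sens, spec, acc = operating_metrics(scores, labels, threshold)
    lo, hi = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    # percentile CI always brackets the point estimate up to resampling noise;
    # enforce the documented invariant rather than report a crossed interval
    lo, hi = min(lo, a), max(hi, a)
    return RocResult(a, sens, spec, acc, threshold, lo, hi, len(pos), len(neg))


def compare_unpaired(scores_a, labels_a, scores_b, labels_b, n_boot: int = 2000, seed: int = 0) -> ComparisonResult:
    """Unpaired bootstrap z-test for AUCs of two independent cohorts.

    Both cohorts are resampled stratified; the difference of replicate AUCs
    estimates SD(AUC_a - AUC_b) and z = (AUC_a - AUC_b) / SD with a
    two-tailed normal p-value.
    """
    pos_a, neg_a = _validate(scores_a, labels_a)
    pos_b, neg_b = _validate(scores_b, labels_b)
    rng = np.random.default_rng(seed)
    reps_a = _boot_auc_replicates(pos_a, neg_a, n_boot, rng)
    reps_b = _boot_auc_replicates(pos_b, neg_b, n_boot, rng)
    delta = auc(scores_a, labels_a) - auc(scores_b, labels_b)
    sd = float(np.std(reps_a - reps_b, ddof=1))
    if sd == 0.0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / sd
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult("bootstrap_unpaired", float(z), p, float(delta), n_boot=n_boot)


def _delong_placements(pos, neg):
    """Mid-rank structural components V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_test(scores_1, scores_2, labels) -> ComparisonResult:
    """DeLong's paired test for two correlated AUCs on identical cases.

    Uses the structural-component covariance estimator; z = dAUC / sqrt(var)
    with a two-tailed normal p-value.
    """
    scores_1 = np.asarray(scores_1, dtype=float).ravel()
    scores_2 = np.asarray(scores_2, dtype=float).ravel()
    if scores_1.shape != scores_2.shape:
        raise InputError("paired score vectors must have equal length")
    labels = np.asarray(labels).ravel().astype(int)
    pos1, neg1 = _validate(scores_1, labels)
    pos2, neg2 = _validate(scores_2, labels)
    m, n = len(pos1), len(neg1)
    v10 = np.stack([_delong_placements(pos1, neg1)[0], _delong_placements(pos2, neg2)[0]])
    v01 = np.stack([_delong_placements(pos1, neg1)[1], _delong_placements(pos2, neg2)[1]])
    aucs = v10.mean(axis=1)  # equals v01.mean(axis=1)
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = float(aucs[0] - aucs[1])
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        z = 0.0 if abs(delta) < 1e-12 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult("delong", float(z), p, delta)


def delong_variance(scores, labels) -> float:
    """Variance of a single AUC from DeLong structural components."""
    pos, neg = _validate(scores, labels)
    v10, v01 = _delong_placements(pos, neg)
    m, n = len(pos), len(neg)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
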