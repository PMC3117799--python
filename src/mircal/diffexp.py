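"""Two-class unpaired SAM-style permutation differential expression.

The modified t score for feature i is

    d_i = (mean_F,i - mean_M,i) / (s_i + s0)

with s_i the pooled standard error and s0 an exchangeability constant
chosen to make the spread of d approximately independent of s (Tusher's
percentile-sweep rule).  Expected scores are per-rank means of sorted
permuted scores; significance comes from a delta sweep: a feature is
called at delta when its score departs from the expected score by more
than delta and lies beyond the resulting cut, the estimated FDR at delta
is the median permuted exceedance count over the observed call count, and
a feature's q-value is the minimum estimated FDR over deltas at which it
is called (exactly 0 when no permuted score ever exceeds the cuts).

Sample clustering of the significant features uses complete-linkage
agglomeration on Euclidean distances of log2 intensities.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .types import (
    DetectionTable,
    MircalError,
    ProbesetMatrix,
    SamResult,
    SampleSheet,
)

log = logging.getLogger("mircal")

MALE, FEMALE = "M", "F"


def _group_masks(groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = set(groups.unique())
    if labels != {MALE, FEMALE}:
        raise MircalError(f"groups must be two-level M/F, got {sorted(labels)}")
    male = (groups == MALE).to_numpy()
    female = (groups == FEMALE).to_numpy()
    if male.sum() < 2 or female.sum() < 2:
        raise MircalError("each group needs at least 2 samples")
    return male, female


def _d_stats(x: np.ndarray, female_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean difference (female - male) and pooled scale s_i."""
    n2 = int(female_mask.sum())
    n1 = x.shape[1] - n2
    sum2 = x[:, female_mask].sum(axis=1)
    sum_all = x.sum(axis=1)
    mean2 = sum2 / n2
    mean1 = (sum_all - sum2) / n1
    sq2 = (x[:, female_mask] ** 2).sum(axis=1)
    sq_all = (x**2).sum(axis=1)
    ss2 = np.maximum(sq2 - n2 * mean2**2, 0.0)
    ss1 = np.maximum((sq_all - sq2) - n1 * mean1**2, 0.0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return mean2 - mean1, s


def _safe_d(diff: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Elementwise diff/denom with the 0/0 convention d = 0.

    A zero denominator with zero mean difference is a constant feature
    (no evidence); a zero denominator with nonzero difference is a
    perfectly separated degenerate feature and keeps its sign as +/-inf.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            denom > 0,
            diff / np.where(denom > 0, denom, 1.0),
            np.where(diff == 0, 0.0, np.sign(diff) * np.inf),
        )
    return d


def sam_scores(
    expr: ProbesetMatrix, groups: pd.Series, s0: float = 0.0
) -> pd.Series:
    """Modified t scores; positive d means up-regulated in females.

    With ``s0=0`` this is the classical equal-variance two-sample t
    statistic.
    """
    groups = groups.reindex(expr.sample_ids)
    male, female = _group_masks(groups)
    diff, s = _d_stats(expr.values.to_numpy(), female)
    return pd.Series(_safe_d(diff, s + s0), index=expr.values.index, name="d")


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)) / 0.64)


def choose_s0(diff: np.ndarray, s: np.ndarray, n_windows: int | None = None) -> float:
    """Percentile-sweep selection of the exchangeability constant.

    Candidates are the 0th, 5th, ..., 100th percentiles of s_i.  For each
    candidate the features are split into windows of s quantiles and the
    candidate minimizing the coefficient of variation of the per-window
    median absolute deviation of d is chosen (ties -> smallest
    candidate).  With all s_i equal, the common value's 5th percentile is
    returned (degenerate fallback).
    """
    diff = np.asarray(diff, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(s)
    if n < 10:
        raise MircalError("s0 selection needs at least 10 features")
    if np.ptp(s) == 0:
        log.warning("all s_i equal; s0 falls back to their 5th percentile")
        return float(np.percentile(s, 5))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    if n_windows is None:
        n_windows = min(100, max(2, n // 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best_s0, best_cv = None, np.inf
    for s0 in candidates:
        d = _safe_d(diff, s + s0)
        if not np.isfinite(d).all():
            continue  # candidate leaves degenerate features unpenalized
        mads = np.array([_mad(d[idx]) for idx in windows])
        mu = mads.mean()
        cv = mads.std(ddof=1) / mu if mu > 0 else np.inf
        if best_s0 is None or cv < best_cv - 1e-12:
            best_s0, best_cv = float(s0), cv
    if best_s0 is None:
        log.warning("no finite s0 candidate; falling back to 5th percentile")
        return float(np.percentile(s, 5))
    return best_s0


def _distinct_assignments(
    n: int, n_female: int, n_perm: int, seed: int
) -> np.ndarray:
    """Boolean (n_perm', n) female-assignment masks, distinct rows.

    Enumerates all C(n, n_female) assignments when there are no more than
    ``n_perm`` of them (count logged); otherwise samples distinct
    assignments uniformly without replacement.
    """
    total = math.comb(n, n_female)
    if total <= n_perm:
        log.info("enumerating all %d distinct label assignments", total)
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), n_female)):
            masks[i, list(combo)] = True
        return masks
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    rows = []
    while len(rows) < n_perm:
        combo = tuple(sorted(rng.choice(n, size=n_female, replace=False).tolist()))
        if combo in seen:
            continue
        seen.add(combo)
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        rows.append(mask)
    return np.array(rows)


def permutation_null(
    expr: ProbesetMatrix,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 17,
    s0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null scores for the two-class design.

    Returns ``(d_expected, perm_sorted)``: the per-rank (ascending) mean
    of sorted permuted scores, and the full sorted permuted score matrix
    of shape (n_features, n_permutations used).
    """
    if n_perm < 1:
        raise MircalError("n_perm must be positive")
    groups = groups.reindex(expr.sample_ids)
    male, female = _group_masks(groups)
    n = len(groups)
    n_female = int(female.sum())
    masks = _distinct_assignments(n, n_female, n_perm, seed)
    x = expr.values.to_numpy()
    m = masks.T.astype(float)  # n_samples x P
    n2 = n_female
    n1 = n - n2
    sum2 = x @ m
    sum_all = x.sum(axis=1, keepdims=True)
    mean2 = sum2 / n2
    mean1 = (sum_all - sum2) / n1
    x2 = x**2
    sq2 = x2 @ m
    sq_all = x2.sum(axis=1, keepdims=True)
    ss = np.maximum(sq2 - n2 * mean2**2, 0.0) + np.maximum(
        (sq_all - sq2) - n1 * mean1**2, 0.0
    )
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    perm_d = _safe_d(mean2 - mean1, s + s0)
    perm_sorted = np.sort(perm_d, axis=0)
    d_expected = perm_sorted.mean(axis=1)
    return d_expected, perm_sorted


def sam_threshold(
    d: pd.Series,
    d_expected: np.ndarray,
    perm_sorted: np.ndarray,
    fdr_target: float = 0.05,
) -> tuple[frozenset[str], float, float, pd.Series]:
    """Delta sweep: significant set, chosen delta, its FDR, and q-values.

    Sweeps delta over the observed |d - expected| spectrum; at each delta
    the cuts are the extreme observed scores among features departing by
    more than delta, the estimated FDR is the median permuted exceedance
    count divided by the observed call count (0 when nothing is called),
    and the smallest delta meeting ``fdr_target`` is chosen.  If that
    delta calls nothing the significant set is empty and delta is
    reported as infinity.
    """
    if not 0 < fdr_target < 1:
        raise MircalError("fdr_target must lie in (0, 1)")
    order = np.argsort(d.to_numpy(), kind="stable")
    d_sorted = d.to_numpy()[order]
    n = len(d_sorted)
    if len(d_expected) != n:
        raise MircalError("d_expected length mismatch")
    dev = d_sorted - d_expected
    deltas = np.unique(np.concatenate([[0.0], np.abs(dev)]))
    up = dev[None, :] > deltas[:, None]
    down = -dev[None, :] > deltas[:, None]
    cutups = np.where(up, d_sorted[None, :], np.inf).min(axis=1)
    cutlows = np.where(down, d_sorted[None, :], -np.inf).max(axis=1)
    # a call needs both the deviation beyond delta and the score beyond
    # the cut; for observed scores the cut clause is implied by
    # candidacy, so the call set is exactly the candidate set
    called = (up & (d_sorted[None, :] >= cutups[:, None])) | (
        down & (d_sorted[None, :] <= cutlows[:, None])
    )
    n_called = called.sum(axis=1)

    n_perm = perm_sorted.shape[1]
    counts = np.empty((n_perm, len(deltas)))
    for p in range(n_perm):
        col = perm_sorted[:, p]
        counts[p] = (n - np.searchsorted(col, cutups, side="left")) + \
            np.searchsorted(col, cutlows, side="right")
    median_counts = np.median(counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, median_counts / np.maximum(n_called, 1), 0.0)

    ok = fdr <= fdr_target
    idx = int(np.flatnonzero(ok)[0])  # deltas ascending; smallest qualifying
    if n_called[idx] == 0:
        delta, fdr_at = float("inf"), 0.0
        significant: frozenset[str] = frozenset()
    else:
        delta, fdr_at = float(deltas[idx]), float(fdr[idx])
        significant = frozenset(d.index[order[called[idx]]])

    q_sorted = np.where(called, np.minimum(fdr, 1.0)[:, None], np.inf).min(axis=0)
    q_sorted = np.where(np.isinf(q_sorted), 1.0, q_sorted)
    qvalues = pd.Series(index=d.index, dtype=float, name="qvalue")
    qvalues.iloc[order] = q_sorted
    return significant, delta, fdr_at, qvalues


def detection_filter(
    significant: frozenset[str] | set[str], d: DetectionTable
) -> frozenset[str]:
    """Drop significant features never detected in any cohort sample."""
    any_call = d.calls.sum(axis=1) > 0
    detected = set(any_call.index[any_call])
    return frozenset(f for f in significant if f not in d.feature_ids or f in detected)


def fold_change(expr: ProbesetMatrix, groups: pd.Series) -> pd.Series:
    """Female/male ratio of linear-scale group mean intensities."""
    groups = groups.reindex(expr.sample_ids)
    male, female = _group_masks(groups)
    linear = expr.linear().to_numpy()
    mean_m = linear[:, male].mean(axis=1)
    mean_f = linear[:, female].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_m > 0, mean_f / mean_m, np.nan)
    return pd.Series(fc, index=expr.values.index, name="fold_change")


def run_sam(
    expr: ProbesetMatrix,
    samples: SampleSheet,
    fdr_target: float = 0.05,
    n_perm: int = 1000,
    seed: int = 17,
    s0: float | None = None,
) -> SamResult:
    """End-to-end SAM: s0 tuning, scores, permutation null, delta sweep."""
    groups = samples.table.loc[expr.sample_ids, "sex"]
    male, female = _group_masks(groups)
    diff, s = _d_stats(expr.values.to_numpy(), female)
    if s0 is None:
        s0 = choose_s0(diff, s)
    d = pd.Series(_safe_d(diff, s + s0), index=expr.values.index, name="d")
    d_expected, perm_sorted = permutation_null(
        expr, groups, n_perm=n_perm, seed=seed, s0=s0
    )
    significant, delta, fdr_at, qvalues = sam_threshold(
        d, d_expected, perm_sorted, fdr_target
    )
    order = np.argsort(d.to_numpy(), kind="stable")
    d_exp_series = pd.Series(index=d.index, dtype=float, name="d_expected")
    d_exp_series.iloc[order] = d_expected
    return SamResult(
        d=d,
        d_expected=d_exp_series,
        s0=float(s0),
        fold_change=fold_change(expr, groups),
        qvalue=qvalues,
        significant=significant,
        delta=delta,
        fdr_at_delta=fdr_at,
        fdr_target=fdr_target,
        n_perm=perm_sorted.shape[1],
        seed=seed,
    )


def cluster_features(expr: ProbesetMatrix) -> dict:
    """Complete-linkage sample clustering on the significant features.

    Euclidean distances over log2 intensities; returns the merge tree
    (scipy linkage matrix), merge heights, and the dendrogram leaf order
    as sample ids.
    """
    if len(expr.feature_ids) < 2 or len(expr.sample_ids) < 2:
        raise MircalError("clustering needs >= 2 features and >= 2 samples")
    x = expr.values.to_numpy().T  # samples as observations
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(z)
    return {
        "linkage": z,
        "heights": z[:, 2].tolist(),
        "leaf_order": [expr.sample_ids[i] for i in leaves],
    }
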