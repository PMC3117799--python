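"""Probe-level preprocessing: background handling, detection, normalization.

The workflow mirrors standard miRNA-array practice:

1. detection calls on raw intensities — a one-sided Wilcoxon rank-sum
   test of each probe set's replicate probes against the GC-matched
   anti-genomic background pool, per sample;
2. background subtraction — per sample, per GC bin, subtract the median
   background-probe intensity from each target probe, clamping at zero;
3. a small offset (default 16) and log2 transform;
4. optional quantile normalization across samples (cohort mode only —
   fraction-level comparisons keep each fraction's own distribution);
5. median summarization of probes into probe-set features.
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .types import (
    DetectionTable,
    MircalError,
    ProbeAnnotation,
    ProbeMatrix,
    ProbesetMatrix,
)

log = logging.getLogger("mircal")

#: Combined-sample-size cutoff below which the Wilcoxon detection
#: p-value is computed by exhaustive enumeration rather than the
#: tie-corrected normal approximation.
EXACT_LIMIT = 20


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum detection
# ---------------------------------------------------------------------------

def rank_sum_pvalue(x, y, exact_limit: int = EXACT_LIMIT) -> float:
    """One-sided Wilcoxon rank-sum p-value for ``x`` greater than ``y``.

    Midranks are used for ties.  When the combined sample size is at most
    ``exact_limit``, the p-value is P(rank sum >= observed) under the
    exact permutation distribution (enumerated over all assignments of
    the pooled ranks); otherwise a tie-corrected normal approximation
    with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0:
        raise MircalError("probe set with zero probes")
    if m == 0:
        raise MircalError("empty background pool")
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[:n].sum()
    if n + m <= exact_limit:
        return _exact_rank_sum_p(ranks, n, rx)
    return _approx_rank_sum_p(ranks, n, m, rx)


def _exact_rank_sum_p(ranks: np.ndarray, n: int, rx: float) -> float:
    total = math.comb(len(ranks), n)
    hits = 0
    tol = 1e-9
    for combo in combinations(ranks, n):
        if sum(combo) >= rx - tol:
            hits += 1
    return hits / total


def _approx_rank_sum_p(ranks: np.ndarray, n: int, m: int, rx: float) -> float:
    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 0.5  # all values tied: no evidence either way
    z = (rx - mu - 0.5) / math.sqrt(var)
    return float(norm.sf(z))


def _background_by_gc(annotation: ProbeAnnotation) -> dict[int, list[str]]:
    bg = annotation.background
    if bg.empty:
        raise MircalError("annotation contains no background probes")
    return {
        int(gc): idx.tolist()
        for gc, idx in bg.groupby("gc_count").groups.items()
    }


def detection_call(
    m: ProbeMatrix, annotation: ProbeAnnotation, alpha: float = 0.06
) -> DetectionTable:
    """Per probe set x sample presence calls on the raw intensity matrix.

    For each probe set and sample the replicate target-probe intensities
    are tested against the background probes drawn from the probe set's
    own GC bins (pooled); call = p < ``alpha``.
    """
    if not 0 < alpha < 1:
        raise MircalError("alpha must lie in (0, 1)")
    if m.scale != "linear":
        raise MircalError("detection runs on the raw linear matrix")
    bg_by_gc = _background_by_gc(annotation)
    values = m.values
    sample_ids = m.sample_ids
    n_samples = len(sample_ids)
    tgt = annotation.target
    present = tgt.index.intersection(values.index)
    tgt = tgt.loc[present]
    probesets = sorted(tgt["probeset_id"].unique())

    pmat = np.empty((len(probesets), n_samples))
    arr = values.to_numpy()
    row_pos = {pid: i for i, pid in enumerate(values.index)}
    for i, ps in enumerate(probesets):
        probe_ids = tgt.index[tgt["probeset_id"] == ps]
        if len(probe_ids) == 0:
            raise MircalError(f"probe set {ps} has zero probes")
        gcs = sorted({int(g) for g in tgt.loc[probe_ids, "gc_count"]})
        pool_ids = [pid for gc in gcs for pid in bg_by_gc.get(gc, [])
                    if pid in row_pos]
        if not pool_ids:
            raise MircalError(f"probe set {ps}: empty background pool")
        t_rows = np.array([row_pos[pid] for pid in probe_ids])
        b_rows = np.array([row_pos[pid] for pid in pool_ids])
        sub = np.vstack([arr[t_rows], arr[b_rows]])
        n, mm = len(t_rows), len(b_rows)
        ranks = rankdata(sub, axis=0)
        rx = ranks[:n].sum(axis=0)
        if n + mm <= EXACT_LIMIT:
            for j in range(n_samples):
                pmat[i, j] = _exact_rank_sum_p(ranks[:, j], n, rx[j])
        else:
            for j in range(n_samples):
                pmat[i, j] = _approx_rank_sum_p(ranks[:, j], n, mm, rx[j])
    pvalues = pd.DataFrame(pmat, index=probesets, columns=sample_ids)
    calls = pvalues < alpha
    return DetectionTable(pvalues, calls, alpha)


# ---------------------------------------------------------------------------
# Background subtraction, transform, normalization, summarization
# ---------------------------------------------------------------------------

def gc_background_subtract(
    m: ProbeMatrix, annotation: ProbeAnnotation
) -> ProbeMatrix:
    """Subtract the per-sample, per-GC-bin median background intensity.

    Each target probe's intensity has the median of same-GC background
    probes (that sample) subtracted; negatives are clamped to zero.  A
    target GC bin with no background probes falls back to the nearest
    available bin (warning logged).  Background rows are dropped.
    """
    if m.scale != "linear":
        raise MircalError("background subtraction runs on the linear scale")
    bg = annotation.background
    if bg.empty:
        raise MircalError("annotation contains no background probes")
    values = m.values
    bg_ids = bg.index.intersection(values.index)
    if bg_ids.empty:
        raise MircalError("matrix contains no background probe rows")
    medians = (
        values.loc[bg_ids]
        .groupby(bg.loc[bg_ids, "gc_count"].astype(int))
        .median()
    )  # gc bins x samples
    available = np.array(sorted(medians.index))
    tgt = annotation.target
    t_ids = tgt.index.intersection(values.index)
    gc_target = tgt.loc[t_ids, "gc_count"].astype(int).to_numpy()
    missing = sorted(set(gc_target) - set(available))
    if missing:
        log.warning(
            "no background probes for GC bins %s; using nearest bins", missing
        )
    # nearest available bin per target GC (ties -> lower bin)
    pos = np.searchsorted(available, gc_target)
    pos = np.clip(pos, 0, len(available) - 1)
    lower = np.clip(pos - 1, 0, None)
    use_lower = np.abs(available[lower] - gc_target) <= np.abs(
        available[pos] - gc_target
    )
    chosen = np.where(use_lower, available[lower], available[pos])
    sub = values.loc[t_ids].to_numpy() - medians.loc[chosen].to_numpy()
    out = pd.DataFrame(
        np.clip(sub, 0.0, None), index=t_ids, columns=values.columns
    )
    return ProbeMatrix(out, scale="linear")


def offset_log2(m: ProbeMatrix, offset: float = 16.0) -> ProbeMatrix:
    """Elementwise ``log2(value + offset)``; the offset keeps logs finite."""
    if offset <= 0:
        raise MircalError("offset must be positive")
    if (m.values.to_numpy() < 0).any():
        raise MircalError("negative intensities; clamp before transforming")
    return ProbeMatrix(np.log2(m.values + offset), scale="log2")


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Classic rank-mean quantile normalization across samples.

    Each column's sorted values are replaced by the across-column mean of
    sorted values, reassigned by the original ranks; tied values receive
    the mean of their tied positions' reference values.
    """
    values = m.values
    if values.shape[1] < 2:
        warnings.warn("quantile normalization with one sample is the identity")
        return m
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = ref
        # average reference values over tie groups
        out[:, j] = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
    return ProbeMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        scale=m.scale,
    )


def median_summarize(
    m: ProbeMatrix, annotation: ProbeAnnotation
) -> ProbesetMatrix:
    """Collapse replicate target probes to their per-sample median."""
    tgt = annotation.target
    present = tgt.index.intersection(m.values.index)
    extra = m.values.index.difference(tgt.index)
    if len(extra):
        raise MircalError(
            f"matrix contains non-target rows (e.g. {list(extra[:3])})"
        )
    dropped = set(tgt["probeset_id"].unique()) - set(
        tgt.loc[present, "probeset_id"].unique()
    )
    if dropped:
        log.warning("%d probe sets absent from matrix; dropped", len(dropped))
    grouped = m.values.loc[present].groupby(tgt.loc[present, "probeset_id"])
    values = grouped.median().sort_index()
    values.index.name = "probeset_id"
    return ProbesetMatrix(values, scale=m.scale)


def preprocess_pipeline(
    raw: ProbeMatrix,
    annotation: ProbeAnnotation,
    mode: str = "normalized",
    alpha: float = 0.06,
    offset: float = 16.0,
) -> tuple[ProbesetMatrix, DetectionTable]:
    """Full preprocessing: detection on raw, then subtract -> log2 ->
    (quantile normalize iff ``mode='normalized'``) -> median summarize.

    ``mode='non_normalized'`` preserves each sample's own intensity
    distribution, as fraction-level comparisons require; ``'normalized'``
    quantile-normalizes all samples together for cohort analysis.
    """
    if mode not in ("normalized", "non_normalized"):
        raise MircalError(f"unknown mode {mode!r}")
    detection = detection_call(raw, annotation, alpha=alpha)
    corrected = gc_background_subtract(raw, annotation)
    logged = offset_log2(corrected, offset=offset)
    if mode == "normalized":
        logged = quantile_normalize(logged)
    expr = median_summarize(logged, annotation)
    common = expr.values.index.intersection(detection.pvalues.index)
    expr = ProbesetMatrix(expr.values.loc[common], scale=expr.scale)
    detection = DetectionTable(
        detection.pvalues.loc[common], detection.calls.loc[common], detection.alpha
    )
    return expr, detection
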