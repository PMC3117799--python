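"""Intensity-stratified concordance and stability analyses across fractions.

These operations quantify how well the miRNA content of plasma fractions
agrees: Spearman rank correlation of per-feature mean intensities between
fractions (and against the pooled cellular contaminant profile), paired
intensity comparisons between fractions, pairwise replicate stability
within a fraction, and coefficient-of-variation contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import MircalError, ProbesetMatrix

log = logging.getLogger("mircal")

#: Smallest p-value reported for degenerate (zero-variance) paired tests.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class StrataSpec:
    """Ordered intensity strata (top-N bins) used to slice feature sets."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if any(s <= 0 for s in sizes):
            raise MircalError("strata sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise MircalError("strata sizes must be strictly increasing")


def top_n_features(expr: ProbesetMatrix, n: int) -> list[str]:
    """The ``n`` features of highest across-sample mean intensity.

    Descending by mean; ties broken lexicographically by feature id for
    determinism.
    """
    if n <= 0:
        raise MircalError("n must be positive")
    if n > len(expr.feature_ids):
        raise MircalError(f"n={n} exceeds feature count {len(expr.feature_ids)}")
    means = expr.values.mean(axis=1)
    ordered = sorted(means.index, key=lambda f: (-means[f], f))
    return ordered[:n]


def spearman(x: Sequence[float], y: Sequence[float], method: str = "spearman") -> float:
    """Rank correlation (Pearson on midranks).  NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MircalError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined, returning NaN")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def contaminant_profile(
    expr: ProbesetMatrix, cellular_sample_ids: Iterable[str]
) -> pd.Series:
    """Per-feature mean intensity over all cellular-class samples (the
    single-vector contaminant reference, labelled LWR in the maps)."""
    ids = list(cellular_sample_ids)
    if not ids:
        raise MircalError("no cellular samples given")
    return expr.values[ids].mean(axis=1)


def fraction_correlation_map(
    expr_by_fraction: Mapping[str, ProbesetMatrix],
    reference_features: Sequence[str],
    extra_profiles: Mapping[str, pd.Series] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise Spearman map of per-feature mean intensities.

    Each fraction is collapsed to its per-feature mean over samples,
    restricted to ``reference_features``; optional named profiles (e.g.
    the contaminant LWR vector) are appended as extra rows/columns.
    Features missing from a pair are dropped pairwise (count logged).
    """
    profiles: dict[str, pd.Series] = {
        frac: m.values.mean(axis=1) for frac, m in expr_by_fraction.items()
    }
    if extra_profiles:
        profiles.update(extra_profiles)
    names = list(profiles)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    ref = list(reference_features)
    for a, b in combinations(names, 2):
        common = [
            f for f in ref if f in profiles[a].index and f in profiles[b].index
        ]
        dropped = len(ref) - len(common)
        if dropped:
            log.info("map %s~%s: %d reference features dropped", a, b, dropped)
        if len(common) < 3:
            raise MircalError(f"fewer than 3 shared features for {a}~{b}")
        r = spearman(profiles[a][common], profiles[b][common], method=method)
        out.loc[a, b] = out.loc[b, a] = r
    return out


def paired_intensity_test(
    expr: ProbesetMatrix,
    fraction_a_samples: Sequence[str],
    fraction_b_samples: Sequence[str],
    features: Sequence[str],
) -> tuple[float, float]:
    """Paired two-sided t-test of per-feature mean log2 intensities.

    Each feature contributes one pair: its mean over fraction A's samples
    vs its mean over fraction B's.  Returns (t, p); a zero-variance
    difference vector with nonzero shift yields the underflow floor.
    """
    feats = [f for f in features if f in expr.values.index]
    if len(feats) < 2:
        raise MircalError("need at least 2 paired features")
    a = expr.values.loc[feats, list(fraction_a_samples)].mean(axis=1)
    b = expr.values.loc[feats, list(fraction_b_samples)].mean(axis=1)
    diffs = (a - b).to_numpy()
    if np.allclose(diffs.std(ddof=1), 0):
        if np.allclose(diffs.mean(), 0):
            return 0.0, 1.0
        return float(np.sign(diffs.mean()) * np.inf), P_FLOOR
    t, p = stats.ttest_rel(a, b)
    return float(t), float(max(p, P_FLOOR))


def replicate_stability(
    expr: ProbesetMatrix, strata: StrataSpec, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise inter-replicate rank correlations per intensity stratum.

    Features are ranked by across-replicate mean within this fraction;
    for each stratum size the correlation of every replicate pair is
    computed over the stratum's features.  Returns one row per
    (stratum size, replicate pair).
    """
    cols = expr.sample_ids
    if len(cols) < 2:
        raise MircalError("need at least 2 replicate samples")
    rows = []
    for size in strata.sizes:
        feats = top_n_features(expr, size)
        sub = expr.values.loc[feats]
        for a, b in combinations(cols, 2):
            rows.append(
                {
                    "stratum": size,
                    "sample_a": a,
                    "sample_b": b,
                    "correlation": spearman(sub[a], sub[b], method=method),
                }
            )
    return pd.DataFrame(rows)


def stability_means(stability: pd.DataFrame) -> pd.Series:
    """Mean pairwise correlation per stratum from ``replicate_stability``."""
    return stability.groupby("stratum")["correlation"].mean()


def feature_cv(expr: ProbesetMatrix, features: Sequence[str] | None = None) -> pd.Series:
    """Per-feature coefficient of variation of linear-scale intensities.

    CV = sample sd / mean across the matrix's samples; zero-mean features
    are dropped with a warning.
    """
    linear = expr.linear()
    if features is not None:
        linear = linear.loc[[f for f in features if f in linear.index]]
    mean = linear.mean(axis=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-mean features dropped from CV")
        linear = linear.loc[~zero]
        mean = mean[~zero]
    return linear.std(axis=1, ddof=1) / mean


def fraction_cv_compare(
    expr_a: ProbesetMatrix,
    expr_b: ProbesetMatrix,
    features: Sequence[str],
) -> tuple[pd.DataFrame, float, float]:
    """Per-feature CVs in two fractions plus a paired two-sided t-test.

    Returns (table with cv_a/cv_b per common feature, t, p).  When both
    fractions have zero within-fraction variance the contrast is reported
    as no difference (t=0, p=1).
    """
    cv_a = feature_cv(expr_a, features)
    cv_b = feature_cv(expr_b, features)
    common = cv_a.index.intersection(cv_b.index)
    if len(common) < 2:
        raise MircalError("need at least 2 common features with defined CV")
    table = pd.DataFrame({"cv_a": cv_a[common], "cv_b": cv_b[common]})
    diffs = (table["cv_a"] - table["cv_b"]).to_numpy()
    if np.allclose(diffs, 0):
        return table, 0.0, 1.0
    if np.allclose(diffs.std(ddof=1), 0):
        return table, float(np.sign(diffs.mean()) * np.inf), P_FLOOR
    t, p = stats.ttest_rel(table["cv_a"], table["cv_b"])
    return table, float(t), float(p)
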