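"""Cohort-level feature classes and variability calibration.

Circulation-detected features (a 50% detection threshold across the
cohort by default) are partitioned by contaminant-catalogue membership
into +S/+L (also detected in the cellular classes) and +S/-L (detected in
circulation only).  Intensity and coefficient-of-variation distributions
of the two classes are then compared; removing the contaminant-overlapping
class reduces both the level and the inter-individual variability of the
circulating signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import feature_cv
from .contaminant import detected_set
from .types import (
    ClassPartition,
    ContaminantCatalog,
    DetectionTable,
    MircalError,
    ProbesetMatrix,
)


def partition_classes(
    d: DetectionTable, catalog: ContaminantCatalog, rate: float = 0.5
) -> ClassPartition:
    """Split circulation-detected features by contaminant membership.

    A feature is "in circulation" when detected in at least
    ``ceil(rate * n_samples)`` cohort samples (rate 0.5 over 18 samples
    requires 9 calls).
    """
    if not d.sample_ids:
        raise MircalError("empty cohort detection table")
    circulating = detected_set(d, d.sample_ids, rate=rate)
    s_plus_l = circulating & catalog.members
    s_only = circulating - catalog.members
    return ClassPartition(s_plus_l=frozenset(s_plus_l), s_only=frozenset(s_only))


def class_intensity_compare(
    expr: ProbesetMatrix, part: ClassPartition
) -> tuple[pd.DataFrame, float, float]:
    """Compare pooled per-feature-per-sample log2 intensities by class.

    All cells of each class's features are pooled into one distribution;
    a two-sided t-test contrasts +S/+L against +S/-L.  Returns a summary
    table, t and p.
    """
    groups = {}
    for name, members in (("s_plus_l", part.s_plus_l), ("s_only", part.s_only)):
        feats = [f for f in members if f in expr.values.index]
        if len(feats) < 2:
            raise MircalError(f"class {name} has fewer than 2 features")
        groups[name] = expr.values.loc[feats].to_numpy().ravel()
    t, p = stats.ttest_ind(groups["s_plus_l"], groups["s_only"])
    summary = pd.DataFrame(
        {
            name: {
                "n_features": len(members),
                "n_values": len(groups[name]),
                "mean": float(np.mean(groups[name])),
                "median": float(np.median(groups[name])),
            }
            for name, members in (
                ("s_plus_l", part.s_plus_l),
                ("s_only", part.s_only),
            )
        }
    )
    return summary, float(t), float(p)


def class_cv_compare(
    expr: ProbesetMatrix, part: ClassPartition, statistic: str = "cv"
) -> tuple[pd.DataFrame, float, float]:
    """Compare per-feature variability between +S/+L and +S/-L.

    ``statistic='cv'`` uses the coefficient of variation of linear-scale
    intensities across all cohort samples; ``'sd'`` uses the linear-scale
    standard deviation instead.  Returns (per-feature table, t, p) from a
    two-sided t-test between the class distributions.
    """
    if len(expr.sample_ids) < 2:
        raise MircalError("need at least 2 cohort samples")
    if statistic not in ("cv", "sd"):
        raise MircalError("statistic must be 'cv' or 'sd'")
    if statistic == "cv":
        values = feature_cv(expr)
    else:
        values = expr.linear().std(axis=1, ddof=1)
    rows = []
    for name, members in (("s_plus_l", part.s_plus_l), ("s_only", part.s_only)):
        for f in sorted(members):
            if f in values.index:
                rows.append({"feature": f, "class": name, "value": values[f]})
    table = pd.DataFrame(rows)
    a = table.loc[table["class"] == "s_plus_l", "value"].to_numpy()
    b = table.loc[table["class"] == "s_only", "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise MircalError("each class needs >= 2 features with defined values")
    if np.allclose(np.concatenate([a, b]).std(), 0):
        warnings.warn("all variability values identical; reporting no difference")
        return table, 0.0, 1.0
    t, p = stats.ttest_ind(a, b)
    return table, float(t), float(p)
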