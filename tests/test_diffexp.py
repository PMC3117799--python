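"""SAM scores, s0 tuning, permutation null, thresholding, clustering."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircal import (
    MircalError,
    ProbesetMatrix,
    SampleSheet,
    choose_s0,
    cluster_features,
    detection_filter,
    fold_change,
    permutation_null,
    run_sam,
    sam_scores,
    sam_threshold,
)
from mircal.diffexp import _d_stats

from conftest import make_detection_frame


def _expr(arr, samples, index=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    idx = index or [f"f{i}" for i in range(arr.shape[0])]
    return ProbesetMatrix(pd.DataFrame(arr, index=idx, columns=samples))


def _groups(samples, sexes):
    return pd.Series(list(sexes), index=samples)


# ---------------------------------------------------------------------------
# Modified t scores
# ---------------------------------------------------------------------------


def test_sam_score_hand_example():
    # male [1,2], female [3,4], s0=0: s = sqrt((1/2+1/2)*(0.5+0.5)/2),
    # d = 2 / sqrt(0.5)
    expr = _expr([[1, 2, 3, 4]], ["m1", "m2", "f1", "f2"])
    d = sam_scores(expr, _groups(expr.sample_ids, "MMFF"), s0=0.0)
    assert d.iloc[0] == pytest.approx(2 / math.sqrt(0.5))


def test_equal_group_means_give_zero_score():
    expr = _expr([[1, 3, 1, 3]], ["m1", "m2", "f1", "f2"])
    d = sam_scores(expr, _groups(expr.sample_ids, "MMFF"), s0=0.0)
    assert d.iloc[0] == pytest.approx(0.0)


def test_positive_s0_shrinks_scores():
    expr = _expr([[1, 2, 3, 4]], ["m1", "m2", "f1", "f2"])
    g = _groups(expr.sample_ids, "MMFF")
    d0 = abs(sam_scores(expr, g, s0=0.0).iloc[0])
    d1 = abs(sam_scores(expr, g, s0=0.5).iloc[0])
    assert d1 < d0


def test_small_groups_rejected():
    expr = _expr([[1, 2, 3]], ["m1", "f1", "f2"])
    with pytest.raises(MircalError):
        sam_scores(expr, _groups(expr.sample_ids, "MFF"))


# ---------------------------------------------------------------------------
# s0 selection
# ---------------------------------------------------------------------------


def _oracle_s0(diff, s):
    """Independent re-implementation of the percentile-sweep rule."""
    diff, s = np.asarray(diff, float), np.asarray(s, float)
    n = len(s)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_windows = min(100, max(2, n // 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best, best_cv = None, np.inf
    for cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / (s + cand)
        if not np.isfinite(d).all():
            continue
        mads = []
        for w in windows:
            med = np.median(d[w])
            mads.append(np.median(np.abs(d[w] - med)) / 0.64)
        mads = np.asarray(mads)
        cv = mads.std(ddof=1) / mads.mean() if mads.mean() > 0 else np.inf
        if best is None or cv < best_cv - 1e-12:
            best, best_cv = float(cand), cv
    return best


def test_choose_s0_matches_oracle_on_synthetic_set():
    rng = np.random.default_rng(21)
    diff = rng.normal(0, 1, 50)
    s = rng.gamma(4, 0.2, 50)
    assert choose_s0(diff, s) == pytest.approx(_oracle_s0(diff, s))


def test_choose_s0_degenerate_all_equal():
    s = np.full(20, 0.7)
    diff = np.linspace(-1, 1, 20)
    assert choose_s0(diff, s) == pytest.approx(0.7)


def test_choose_s0_needs_enough_features():
    with pytest.raises(MircalError):
        choose_s0(np.ones(5), np.ones(5))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def test_identical_samples_give_zero_null():
    expr = _expr(np.ones((12, 4)), ["m1", "m2", "f1", "f2"])
    d_exp, perm = permutation_null(
        expr, _groups(expr.sample_ids, "MMFF"), n_perm=10, seed=1, s0=1.0
    )
    assert np.allclose(d_exp, 0.0) and np.allclose(perm, 0.0)


def test_null_deterministic_given_seed(small_cohort):
    matrix, samples, _ = small_cohort
    expr = ProbesetMatrix(
        np.log2(matrix.values.iloc[:40] + 16), scale="log2"
    )
    groups = samples.table["sex"]
    a = permutation_null(expr, groups, n_perm=50, seed=17, s0=0.1)
    b = permutation_null(expr, groups, n_perm=50, seed=17, s0=0.1)
    np.testing.assert_array_equal(a[1], b[1])


def test_small_design_enumerates_all_assignments():
    rng = np.random.default_rng(2)
    samples = ["m1", "m2", "f1", "f2"]
    expr = _expr(rng.normal(5, 1, size=(15, 4)), samples)
    groups = _groups(samples, "MMFF")
    d_exp, perm = permutation_null(expr, groups, n_perm=1000, seed=0, s0=0.2)
    assert perm.shape == (15, 6)  # C(4,2) distinct assignments
    # exhaustive oracle: recompute scores for every relabelling via the
    # public scalar path and compare the pooled sorted score sets
    oracle_cols = []
    for combo in combinations(range(4), 2):
        sexes = ["F" if i in combo else "M" for i in range(4)]
        d = sam_scores(expr, _groups(samples, sexes), s0=0.2)
        oracle_cols.append(np.sort(d.to_numpy()))
    oracle = np.column_stack(oracle_cols)  # already sorted per column
    np.testing.assert_allclose(
        np.sort(perm, axis=1), np.sort(oracle, axis=1), atol=1e-12
    )
    np.testing.assert_allclose(d_exp, oracle.mean(axis=1), atol=1e-12)


# ---------------------------------------------------------------------------
# Delta sweep / q-values
# ---------------------------------------------------------------------------


def _run_small_sam(effect=0.0, seed=5, n_features=80):
    rng = np.random.default_rng(seed)
    samples = [f"m{i}" for i in range(5)] + [f"f{i}" for i in range(6)]
    x = rng.normal(7, 1, size=(n_features, 11))
    x[:4, 5:] += effect
    expr = _expr(x, samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "fraction": ["S1"] * 11,
                "subject_id": samples,
                "sex": ["M"] * 5 + ["F"] * 6,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return run_sam(expr, sheet, fdr_target=0.05, n_perm=200, seed=3)


def test_null_data_yield_empty_or_tiny_significant_set():
    sam = _run_small_sam(effect=0.0)
    assert len(sam.significant) <= 2


def test_planted_effect_is_called_with_low_q():
    sam = _run_small_sam(effect=2.5)
    planted = {"f0", "f1", "f2", "f3"}
    assert len(planted & sam.significant) >= 3
    assert sam.fdr_at_delta <= 0.05
    assert all(sam.qvalue[f] <= 0.1 for f in planted & sam.significant)


def test_qvalues_monotone_in_deviation_within_sign():
    sam = _run_small_sam(effect=2.5)
    dev = (sam.d - sam.d_expected).dropna()
    up = dev[sam.d > 0].sort_values(ascending=False)
    q_up = sam.qvalue[up.index]
    assert (q_up.diff().dropna() >= -1e-12).all()


def test_threshold_rejects_bad_fdr_target():
    sam = _run_small_sam()
    with pytest.raises(MircalError):
        sam_threshold(sam.d, np.sort(sam.d_expected.to_numpy()),
                      np.zeros((len(sam.d), 5)), fdr_target=1.5)


# ---------------------------------------------------------------------------
# Detection filter, fold change
# ---------------------------------------------------------------------------


def test_detection_filter_drops_only_never_detected():
    d = make_detection_frame(
        {"seen": [True, False], "unseen": [False, False]}, ["c1", "c2"]
    )
    assert detection_filter({"seen", "unseen"}, d) == {"seen"}
    assert detection_filter({"seen"}, d) == {"seen"}
    assert detection_filter(set(), d) == frozenset()
    # features outside the table are kept
    assert detection_filter({"foreign"}, d) == {"foreign"}


def test_fold_change_cases():
    samples = ["m1", "m2", "f1", "f2"]
    groups = _groups(samples, "MMFF")
    linear = ProbesetMatrix(
        pd.DataFrame(
            [[10.0, 10.0, 18.0, 18.0], [7.0, 7.0, 7.0, 7.0]],
            index=["up", "flat"],
            columns=samples,
        ),
        scale="linear",
    )
    fc = fold_change(linear, groups)
    assert fc["up"] == pytest.approx(1.8)
    assert fc["flat"] == pytest.approx(1.0)
    # females = males shifted by +1 log2 -> fold change 2 everywhere
    rng = np.random.default_rng(0)
    base = rng.normal(6, 1, size=(5, 4))
    base[:, 2:] = base[:, :2] + 1.0
    shifted = ProbesetMatrix(
        pd.DataFrame(base, index=[f"f{i}" for i in range(5)], columns=samples)
    )
    np.testing.assert_allclose(fold_change(shifted, groups), 2.0, rtol=1e-9)


def test_fold_change_zero_male_mean_is_nan():
    samples = ["m1", "m2", "f1", "f2"]
    linear = ProbesetMatrix(
        pd.DataFrame([[0.0, 0.0, 2.0, 2.0]], index=["z"], columns=samples),
        scale="linear",
    )
    assert math.isnan(fold_change(linear, _groups(samples, "MMFF"))["z"])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def test_identical_samples_merge_at_zero():
    expr = _expr([[1, 1, 5], [2, 2, 9]], ["a", "b", "c"])
    out = cluster_features(expr)
    assert out["heights"][0] == pytest.approx(0.0)


def test_three_point_line_complete_linkage_heights():
    # samples at positions 0, 1, 10 on a line: merge {0,1} at height 1,
    # then the pair joins 10 at the farthest-member distance 10
    expr = _expr([[0, 1, 10]], ["a", "b", "c"])
    out = cluster_features(
        ProbesetMatrix(
            pd.DataFrame([[0.0, 1.0, 10.0], [0.0, 1.0, 10.0]],
                         index=["f1", "f2"], columns=["a", "b", "c"])
        )
    )
    np.testing.assert_allclose(
        out["heights"], [math.sqrt(2) * 1, math.sqrt(2) * 10]
    )


def test_relabeling_preserves_merge_heights():
    rng = np.random.default_rng(4)
    vals = rng.normal(5, 2, size=(6, 5))
    cols = ["a", "b", "c", "d", "e"]
    e1 = _expr(vals, cols)
    e2 = _expr(vals[:, ::-1], cols)  # same geometry, reversed labels
    h1 = cluster_features(e1)["heights"]
    h2 = cluster_features(e2)["heights"]
    np.testing.assert_allclose(sorted(h1), sorted(h2))


def test_merge_heights_non_decreasing(small_cohort):
    matrix, _, _ = small_cohort
    expr = ProbesetMatrix(np.log2(matrix.values.iloc[:10] + 16), scale="log2")
    heights = cluster_features(expr)["heights"]
    assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


def test_cluster_needs_two_by_two():
    with pytest.raises(MircalError):
        cluster_features(_expr([[1, 2]], ["a", "b"], index=["only"]))
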