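"""Preprocessing stages against hand-computed and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mircal import (
    MircalError,
    ProbeAnnotation,
    ProbeMatrix,
    detection_call,
    gc_background_subtract,
    median_summarize,
    offset_log2,
    preprocess_pipeline,
    quantile_normalize,
    rank_sum_pvalue,
)

# ---------------------------------------------------------------------------
# GC background subtraction
# ---------------------------------------------------------------------------


def test_subtraction_arithmetic_and_clamp(toy_annotation, toy_matrix):
    out = gc_background_subtract(toy_matrix, toy_annotation)
    # s1: GC-10 background median = median(80, 70) = 75; GC-12 = 55
    assert out.values.loc["A1", "s1"] == pytest.approx(100 - 75)
    assert out.values.loc["A2", "s1"] == pytest.approx(90 - 55)
    # B2 (GC 12) = 20 < 55 -> clamped at zero
    assert out.values.loc["B2", "s1"] == 0.0
    # background rows dropped
    assert set(out.values.index) == {"A1", "A2", "B1", "B2"}


def test_subtraction_per_sample_hand_medians():
    """3-probe toy: per-sample medians computed by hand per GC bin."""
    table = pd.DataFrame(
        {
            "probeset_id": ["s", "s", "s", "", "", ""],
            "probe_class": ["target"] * 3 + ["background"] * 3,
            "gc_count": [8, 8, 9, 8, 8, 9],
            "is_human": [True] * 3 + [False] * 3,
        },
        index=pd.Index(["t1", "t2", "t3", "b1", "b2", "b3"], name="probe_id"),
    )
    ann = ProbeAnnotation(table)
    values = pd.DataFrame(
        {"x": [10.0, 20.0, 30.0, 4.0, 6.0, 7.0],
         "y": [10.0, 20.0, 30.0, 14.0, 16.0, 27.0]},
        index=table.index,
    )
    out = gc_background_subtract(ProbeMatrix(values), ann)
    # sample x: GC8 median=5, GC9 median=7; sample y: GC8=15, GC9=27
    np.testing.assert_allclose(out.values["x"], [5.0, 15.0, 23.0])
    np.testing.assert_allclose(out.values["y"], [0.0, 5.0, 3.0])


def test_subtraction_nearest_bin_fallback():
    table = pd.DataFrame(
        {
            "probeset_id": ["s", ""],
            "probe_class": ["target", "background"],
            "gc_count": [15, 10],  # no background at GC 15 -> nearest is 10
            "is_human": [True, False],
        },
        index=pd.Index(["t1", "b1"], name="probe_id"),
    )
    ann = ProbeAnnotation(table)
    m = ProbeMatrix(pd.DataFrame({"x": [50.0, 30.0]}, index=table.index))
    out = gc_background_subtract(m, ann)
    assert out.values.loc["t1", "x"] == pytest.approx(20.0)


def test_subtraction_requires_background(toy_matrix, toy_annotation):
    targets_only = ProbeAnnotation(
        toy_annotation.table[toy_annotation.table["probe_class"] == "target"]
    )
    with pytest.raises(MircalError):
        gc_background_subtract(toy_matrix, targets_only)


def test_subtraction_never_negative(small_fractions, small_annotation):
    m, _, _ = small_fractions
    out = gc_background_subtract(m, small_annotation)
    assert (out.values.to_numpy() >= 0).all()


# ---------------------------------------------------------------------------
# Wilcoxon detection
# ---------------------------------------------------------------------------


def test_exact_p_all_targets_above_background():
    # 4 vs 4, targets strictly greater: one extreme assignment of C(8,4)=70
    p = rank_sum_pvalue([10, 11, 12, 13], [1, 2, 3, 4])
    assert p == pytest.approx(1 / 70)
    assert p < 0.06  # detected at the default threshold


def test_targets_below_background_not_detected():
    p = rank_sum_pvalue([1, 2, 3, 4], [10, 11, 12, 13])
    assert p >= 0.5


def test_all_tied_values_not_detected():
    p = rank_sum_pvalue([5.0] * 4, [5.0] * 6)
    assert p >= 0.5


def test_pvalue_monotone_in_target_intensity():
    background = [5.0, 6.0, 7.0, 8.0, 9.0]
    previous = 1.0
    for shift in (0.0, 2.0, 4.0, 6.0):
        p = rank_sum_pvalue([6.0 + shift, 7.0 + shift, 8.0 + shift], background)
        assert p <= previous + 1e-12
        previous = p


def test_detection_call_detects_signal_not_background(toy_annotation, toy_matrix):
    det = detection_call(toy_matrix, toy_annotation, alpha=0.1)
    assert det.pvalues.shape == (2, 2)
    # setA probes (100, 90) exceed all 4 pooled backgrounds: the most
    # extreme of the C(6,2)=15 rank assignments
    assert det.pvalues.loc["setA", "s1"] == pytest.approx(1 / 15)
    assert bool(det.calls.loc["setA", "s1"])
    # setB probes (30, 20) sit below all backgrounds -> not detected
    assert det.pvalues.loc["setB", "s1"] > 0.5
    assert not bool(det.calls.loc["setB", "s1"])
    assert ((det.pvalues < det.alpha) == det.calls).all().all()


# ---------------------------------------------------------------------------
# Offset + log2
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("value,expected", [(0.0, 4.0), (16.0, 5.0), (240.0, 8.0)])
def test_offset_log2_closed_forms(value, expected):
    m = ProbeMatrix(pd.DataFrame({"s": [value]}, index=["p"]))
    assert offset_log2(m).values.loc["p", "s"] == pytest.approx(expected)


def test_offset_log2_rejects_negatives():
    m = ProbeMatrix(pd.DataFrame({"s": [-1.0]}, index=["p"]), scale="log2")
    with pytest.raises(MircalError):
        offset_log2(m)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def _pm(arr):
    arr = np.asarray(arr, dtype=float)
    return ProbeMatrix(
        pd.DataFrame(
            arr,
            index=[f"p{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        scale="log2",
    )


def test_quantile_normalize_hand_example():
    out = quantile_normalize(_pm([[1, 2], [3, 4]]))
    np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])


def test_quantile_normalize_fixed_point():
    m = _pm([[1, 1], [2, 2], [5, 5]])
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


def test_quantile_normalize_tie_rule():
    # column 0 has a 2-way tie at the bottom: its tied entries share the
    # mean of the two lowest reference values
    out = quantile_normalize(_pm([[1, 10], [1, 20], [4, 30]]))
    ref = np.sort([[1, 10], [1, 20], [4, 30]], axis=0).mean(axis=1)
    expected_tied = (ref[0] + ref[1]) / 2
    assert out.values.iloc[0, 0] == pytest.approx(expected_tied)
    assert out.values.iloc[1, 0] == pytest.approx(expected_tied)
    assert out.values.iloc[2, 0] == pytest.approx(ref[2])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    arrays(
        np.float64,
        (6, 3),
        elements=st.floats(0, 100, allow_nan=False, width=32),
        unique=True,
    )
)
def test_quantile_normalize_equalizes_sorted_columns(arr):
    out = quantile_normalize(_pm(arr)).values.to_numpy()
    sorted_cols = np.sort(out, axis=0)
    for j in range(1, out.shape[1]):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)


def test_quantile_normalize_idempotent_and_rank_preserving():
    rng = np.random.default_rng(0)
    m = _pm(rng.normal(size=(30, 4)))
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())
    for j in range(4):
        orig = m.values.iloc[:, j].rank()
        new = once.values.iloc[:, j].rank()
        pd.testing.assert_series_equal(orig, new, check_names=False)


def test_quantile_normalize_single_sample_is_identity():
    m = _pm([[1], [2]])
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


# ---------------------------------------------------------------------------
# Median summarization
# ---------------------------------------------------------------------------


def test_median_summarize_even_and_odd(toy_annotation):
    values = pd.DataFrame(
        {"s": [4.0, 6.0, 1.0, 9.0]}, index=["A1", "A2", "B1", "B2"]
    )
    out = median_summarize(ProbeMatrix(values, scale="log2"), toy_annotation)
    assert out.values.loc["setA", "s"] == pytest.approx(5.0)
    assert out.values.loc["setB", "s"] == pytest.approx(5.0)
    odd = pd.DataFrame({"s": [1.0, 2.0, 9.0]}, index=["t1", "t2", "t3"])
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probeset_id": ["x", "x", "x"],
                "probe_class": ["target"] * 3,
                "gc_count": [8, 8, 8],
                "is_human": [True] * 3,
            },
            index=pd.Index(["t1", "t2", "t3"], name="probe_id"),
        )
    )
    assert median_summarize(
        ProbeMatrix(odd, scale="log2"), ann
    ).values.loc["x", "s"] == pytest.approx(2.0)


def test_median_summarize_rejects_background_rows(toy_annotation, toy_matrix):
    with pytest.raises(MircalError):
        median_summarize(toy_matrix, toy_annotation)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def test_pipeline_modes_differ_only_by_normalization(small_fractions, small_annotation):
    m, _, _ = small_fractions
    expr_raw, det_raw = preprocess_pipeline(m, small_annotation, mode="non_normalized")
    expr_qn, det_qn = preprocess_pipeline(m, small_annotation, mode="normalized")
    # detection does not depend on the normalization mode
    pd.testing.assert_frame_equal(det_raw.pvalues, det_qn.pvalues)
    # non-normalized columns keep distinct distributions; normalized
    # probe-level columns were equalized before summarization
    raw_sorted = np.sort(expr_raw.values.to_numpy(), axis=0)
    assert not np.allclose(raw_sorted[:, 0], raw_sorted[:, 1])
    assert expr_raw.values.shape == expr_qn.values.shape


def test_pipeline_zero_noise_closed_form():
    from mircal import SimulationParams, make_annotation, simulate_fractions

    p = SimulationParams(
        n_features=15, n_background=80, noise_sigma_log2=0.0,
        bio_sigma_log2=0.0, seed=6,
    )
    ann = make_annotation(p)
    m, samples, truth = simulate_fractions(p, ann)
    expr, _ = preprocess_pipeline(m, ann, mode="non_normalized")
    cs = samples.samples_in_fraction("CS")[0]
    for f in truth["circulating_features"]:
        expected = math.log2(2 ** truth["abundance_log2"][f] + 16)
        assert expr.values.loc[f, cs] == pytest.approx(expected, rel=1e-9)


def test_pipeline_rejects_unknown_mode(small_fractions, small_annotation):
    m, _, _ = small_fractions
    with pytest.raises(MircalError):
        preprocess_pipeline(m, small_annotation, mode="fancy")
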