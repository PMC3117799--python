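"""Shared fixtures: small hand-built tables and simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mircal import (
    ProbeAnnotation,
    ProbeMatrix,
    SampleSheet,
    SimulationParams,
    make_annotation,
    preprocess_pipeline,
    simulate_cohort,
    simulate_fractions,
)
from mircal.contaminant import build_catalog


@pytest.fixture()
def toy_annotation() -> ProbeAnnotation:
    """Two probe sets x two probes plus four background probes (2 GC bins)."""
    table = pd.DataFrame(
        {
            "probeset_id": ["setA", "setA", "setB", "setB", "", "", "", ""],
            "probe_class": ["target"] * 4 + ["background"] * 4,
            "gc_count": [10, 12, 10, 12, 10, 10, 12, 12],
            "is_human": [True] * 4 + [False] * 4,
        },
        index=pd.Index(
            ["A1", "A2", "B1", "B2", "bg1", "bg2", "bg3", "bg4"], name="probe_id"
        ),
    )
    return ProbeAnnotation(table)


@pytest.fixture()
def toy_matrix(toy_annotation) -> ProbeMatrix:
    values = pd.DataFrame(
        {
            "s1": [100.0, 90.0, 30.0, 20.0, 80.0, 70.0, 60.0, 50.0],
            "s2": [110.0, 95.0, 25.0, 15.0, 85.0, 75.0, 65.0, 55.0],
        },
        index=toy_annotation.table.index,
    )
    return ProbeMatrix(values)


@pytest.fixture()
def toy_samples() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "fraction": ["S1", "S1"],
                "subject_id": ["d1", "d2"],
                "sex": ["NA", "NA"],
            },
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_features=60, n_background=150, seed=11)


@pytest.fixture(scope="session")
def small_annotation(small_params):
    return make_annotation(small_params)


@pytest.fixture(scope="session")
def small_fractions(small_params, small_annotation):
    return simulate_fractions(small_params, small_annotation)


@pytest.fixture(scope="session")
def small_cohort(small_params, small_annotation):
    return simulate_cohort(small_params, small_annotation)


@pytest.fixture(scope="session")
def default_fraction_run():
    """Full-scale fractionation arm at seed 1: sim, preprocessing, catalogue."""
    params = SimulationParams(seed=1)
    annotation = make_annotation(params)
    matrix, samples, truth = simulate_fractions(params, annotation)
    expr, detection = preprocess_pipeline(matrix, annotation, mode="non_normalized")
    catalog = build_catalog(detection, samples)
    return {
        "params": params,
        "annotation": annotation,
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "expr": expr,
        "detection": detection,
        "catalog": catalog,
    }


def make_detection_frame(calls: dict[str, list[bool]], samples: list[str]):
    """Build a DetectionTable from explicit boolean calls (p = 0 or 0.5)."""
    from mircal import DetectionTable

    calls_df = pd.DataFrame(calls, index=samples).T
    calls_df.columns = samples
    pvals = calls_df.map(lambda c: 0.0 if c else 0.5)
    return DetectionTable(pvals, calls_df.astype(bool), alpha=0.06)
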