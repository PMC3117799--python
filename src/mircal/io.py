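"""Tab-separated readers and writers for the pipeline's interchange files.

File dialects:

* ``probes.tsv``  — probe_id, probeset_id, probe_class, gc_count, is_human
* ``samples.tsv`` — sample_id, fraction, subject_id, sex
* ``matrix.tsv``  — first column the feature/probe id, one column per sample

Writers emit lexicographic row order and fixed decimal precision so that
two writes of the same object are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .types import (
    DetectionTable,
    FormatError,
    MetadataError,
    MircalError,
    ProbeAnnotation,
    ProbeMatrix,
    ProbesetMatrix,
    SampleSheet,
)

log = logging.getLogger("mircal")


def read_probe_annotation(path: str | Path, probe_length: int = 25) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probeset_id": str})
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: missing probe_id column")
    df = df.set_index("probe_id")
    df["probeset_id"] = df["probeset_id"].fillna("")
    df["is_human"] = df["is_human"].astype(bool)
    return ProbeAnnotation(df, probe_length=probe_length)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.sort_index().to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample_id")


def _read_matrix_frame(path: str | Path, id_label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.columns.empty:
        raise FormatError(f"{path}: no sample columns (missing header?)")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        raise FormatError(
            f"{path}: non-numeric cells in columns {list(non_numeric)[:3]}"
        )
    df.index = df.index.astype(str)
    df.index.name = id_label
    return df.astype(float)


def read_probe_matrix(
    path: str | Path,
    annotation: ProbeAnnotation,
    samples: SampleSheet,
    scale: str = "linear",
) -> ProbeMatrix:
    """Read a probe-level intensity matrix and check it against the metadata.

    Rows must all be probes known to the annotation; columns must all be
    samples present in the sample sheet.
    """
    df = _read_matrix_frame(path, "probe_id")
    unknown_samples = set(df.columns) - set(samples.table.index)
    if unknown_samples:
        raise MetadataError(
            f"{path}: samples absent from sample sheet: {sorted(unknown_samples)[:5]}"
        )
    unknown_probes = set(df.index) - set(annotation.table.index)
    if unknown_probes:
        raise MetadataError(
            f"{path}: probes absent from annotation: {sorted(unknown_probes)[:5]}"
        )
    return ProbeMatrix(df, scale=scale)


def write_matrix(values: pd.DataFrame, path: str | Path, decimals: int = 6) -> None:
    if values.empty:
        raise MircalError(f"refusing to write empty matrix to {path}")
    values.sort_index().to_csv(path, sep="\t", float_format=f"%.{decimals}f")


def write_probe_matrix(m: ProbeMatrix, path: str | Path, decimals: int = 6) -> None:
    values = m.values.copy()
    values.index.name = "probe_id"
    write_matrix(values, path, decimals)


def write_probeset_matrix(m: ProbesetMatrix, path: str | Path, decimals: int = 6) -> None:
    values = m.values.copy()
    values.index.name = "probeset_id"
    write_matrix(values, path, decimals)


def read_probeset_matrix(path: str | Path, scale: str = "log2") -> ProbesetMatrix:
    return ProbesetMatrix(_read_matrix_frame(path, "probeset_id"), scale=scale)


def write_detection(d: DetectionTable, p_path: str | Path, calls_path: str | Path) -> None:
    pv = d.pvalues.copy()
    pv.index.name = "probeset_id"
    write_matrix(pv, p_path, decimals=8)
    calls = d.calls.astype(int).sort_index()
    calls.index.name = "probeset_id"
    calls.to_csv(calls_path, sep="\t")


def read_detection(p_path: str | Path, calls_path: str | Path, alpha: float) -> DetectionTable:
    pv = _read_matrix_frame(p_path, "probeset_id")
    calls = _read_matrix_frame(calls_path, "probeset_id").astype(bool)
    return DetectionTable(pv, calls, alpha)


def read_catalog(path: str | Path) -> frozenset[str]:
    """Read a one-id-per-line contaminant member list."""
    text = Path(path).read_text().split()
    return frozenset(text)


def write_catalog(members: frozenset[str] | set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(members)) + ("\n" if members else ""))


def read_config(path: str | Path) -> dict:
    """Read a flat key-value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a flat mapping")
    return cfg
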