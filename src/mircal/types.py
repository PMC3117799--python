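"""Core containers for probe-level miRNA microarray analysis.

The pipeline operates on four kinds of tabular objects: a probe annotation
(probe -> probe set, target/background class, GC count), a sample sheet
(sample -> blood fraction, subject, sex), intensity matrices at probe or
probe-set resolution, and detection tables (per-feature, per-sample
presence p-values and calls).  All of them wrap :class:`pandas.DataFrame`
and validate their invariants on construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Blood fractions of the differential-centrifugation design: cloudy
#: supernatant, two further supernatants, two pellets, and the three
#: cellular classes (red cells, buffy-coat white cells, Ficoll leukocytes).
FRACTIONS: tuple[str, ...] = ("CS", "S1", "S2", "P1", "P2", "RBC", "WBC", "LEU")
PLASMA_FRACTIONS: tuple[str, ...] = ("CS", "S1", "S2", "P1", "P2")
CELLULAR_FRACTIONS: tuple[str, ...] = ("RBC", "WBC", "LEU")

PROBE_CLASSES = ("target", "background")
SEXES = ("M", "F", "NA")


class MircalError(ValueError):
    """Base error for contract violations in this package."""


class FormatError(MircalError):
    """Malformed input file."""


class MetadataError(MircalError):
    """Sample or probe identifiers not covered by the available metadata."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise MircalError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe-level annotation of the array.

    ``table`` is indexed by ``probe_id`` with columns ``probeset_id``,
    ``probe_class`` (``target`` or ``background``), ``gc_count`` and
    ``is_human``.  Background (anti-genomic) probes match no genomic
    sequence and are used only to model non-specific signal stratified by
    GC content; they never enter probe-set summarization.
    """

    table: pd.DataFrame
    probe_length: int = 25

    def __post_init__(self) -> None:
        required = {"probeset_id", "probe_class", "gc_count", "is_human"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "probe_id")
        bad_class = set(self.table["probe_class"]) - set(PROBE_CLASSES)
        if bad_class:
            raise MircalError(f"unknown probe_class values: {sorted(bad_class)}")
        gc = self.table["gc_count"]
        if (gc < 0).any() or (gc > self.probe_length).any():
            raise MircalError(
                f"gc_count must lie in [0, {self.probe_length}] (probe length)"
            )
        tgt = self.table[self.table["probe_class"] == "target"]
        if tgt["probeset_id"].isna().any() or (tgt["probeset_id"] == "").any():
            raise MircalError("every target probe must map to a probeset_id")

    @property
    def target(self) -> pd.DataFrame:
        return self.table[self.table["probe_class"] == "target"]

    @property
    def background(self) -> pd.DataFrame:
        return self.table[self.table["probe_class"] == "background"]

    @property
    def probeset_ids(self) -> list[str]:
        """Sorted probe-set identifiers of the target probes."""
        return sorted(self.target["probeset_id"].unique())

    def probes_of(self, probeset_id: str) -> list[str]:
        tgt = self.target
        return tgt.index[tgt["probeset_id"] == probeset_id].tolist()


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: fraction label, subject and sex per array column."""

    table: pd.DataFrame  # index sample_id; columns fraction, subject_id, sex

    def __post_init__(self) -> None:
        required = {"fraction", "subject_id", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample_id")
        bad = set(self.table["fraction"]) - set(FRACTIONS)
        if bad:
            raise MircalError(f"unknown fraction labels: {sorted(bad)}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise MircalError(f"unknown sex labels: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def samples_in_fraction(self, fraction: str) -> list[str]:
        return self.table.index[self.table["fraction"] == fraction].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        missing = set(ids) - set(self.table.index)
        if missing:
            raise MetadataError(f"unknown sample ids: {sorted(missing)[:5]}")
        return SampleSheet(self.table.loc[ids])


def _validate_matrix(values: pd.DataFrame, scale: str) -> None:
    if scale not in ("linear", "log2"):
        raise MircalError(f"scale must be 'linear' or 'log2', got {scale!r}")
    _check_unique(values.index, "row id")
    _check_unique(values.columns, "sample id")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("matrix contains non-numeric cells")
    if np.isnan(arr).any():
        raise MircalError("matrix contains missing cells")
    if scale == "linear" and (arr < 0).any():
        raise MircalError("linear-scale intensities must be non-negative")


@dataclass(frozen=True)
class ProbeMatrix:
    """Probe-level intensity matrix (rows probes, columns samples)."""

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.scale)

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def restrict_samples(self, sample_ids: Iterable[str]) -> "ProbeMatrix":
        return dataclasses.replace(self, values=self.values[list(sample_ids)])


@dataclass(frozen=True)
class ProbesetMatrix:
    """Summarized intensity matrix (rows probe sets, columns samples)."""

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.scale)

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def restrict_samples(self, sample_ids: Iterable[str]) -> "ProbesetMatrix":
        return dataclasses.replace(self, values=self.values[list(sample_ids)])

    def restrict_features(self, feature_ids: Iterable[str]) -> "ProbesetMatrix":
        ids = [f for f in feature_ids if f in self.values.index]
        return dataclasses.replace(self, values=self.values.loc[ids])

    def linear(self) -> pd.DataFrame:
        """Per-cell linear-scale intensities regardless of stored scale."""
        if self.scale == "linear":
            return self.values
        return np.power(2.0, self.values)


@dataclass(frozen=True)
class DetectionTable:
    """Per probe set x sample detection p-values and boolean calls.

    The call in cell (i, j) is True exactly when ``pvalues[i, j] < alpha``.
    """

    pvalues: pd.DataFrame
    calls: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        if self.pvalues.shape != self.calls.shape:
            raise MircalError("pvalues and calls must share a shape")
        if not (
            self.pvalues.index.equals(self.calls.index)
            and self.pvalues.columns.equals(self.calls.columns)
        ):
            raise MircalError("pvalues and calls must share labels")
        p = self.pvalues.to_numpy()
        if (p < 0).any() or (p > 1).any():
            raise MircalError("p-values must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise MircalError("alpha must lie in (0, 1)")
        expected = p < self.alpha
        if not np.array_equal(expected, self.calls.to_numpy().astype(bool)):
            raise MircalError("calls are inconsistent with pvalues < alpha")

    @property
    def feature_ids(self) -> list[str]:
        return self.pvalues.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.pvalues.columns.tolist()


@dataclass(frozen=True)
class ContaminantCatalog:
    """Probe sets declared hematopoietic contaminants, with provenance.

    ``members`` is the union of the three cellular-class sets (red blood
    cells, white blood cells, leukocytes).
    """

    per_class: Mapping[str, frozenset[str]]
    members: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        per_class = {k: frozenset(v) for k, v in self.per_class.items()}
        object.__setattr__(self, "per_class", per_class)
        union: frozenset[str] = frozenset().union(*per_class.values()) if per_class else frozenset()
        if self.members and frozenset(self.members) != union:
            raise MircalError("members must equal the union of per-class sets")
        object.__setattr__(self, "members", union)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.members


@dataclass(frozen=True)
class ClassPartition:
    """Partition of circulation-detected features by contaminant overlap.

    ``s_plus_l``: detected in circulation and present in the contaminant
    catalogue (+S/+L).  ``s_only``: detected in circulation only (+S/-L).
    """

    s_plus_l: frozenset[str]
    s_only: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_plus_l", frozenset(self.s_plus_l))
        object.__setattr__(self, "s_only", frozenset(self.s_only))
        if self.s_plus_l & self.s_only:
            raise MircalError("+S/+L and +S/-L classes must be disjoint")

    @property
    def circulating(self) -> frozenset[str]:
        return self.s_plus_l | self.s_only


@dataclass(frozen=True)
class SamResult:
    """Output of the permutation-based modified-t differential analysis.

    ``d`` holds the per-feature modified t score (positive = up in
    females), ``d_expected`` the mean permuted order statistic at the
    feature's rank, ``fold_change`` the female/male ratio of linear-scale
    group means, and ``qvalue`` the minimum estimated FDR over thresholds
    at which the feature is called (0 is possible when no permuted score
    ever exceeds the cuts).
    """

    d: pd.Series
    d_expected: pd.Series
    s0: float
    fold_change: pd.Series
    qvalue: pd.Series
    significant: frozenset[str]
    delta: float
    fdr_at_delta: float
    fdr_target: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.d)
        for name in ("d_expected", "fold_change", "qvalue"):
            if len(getattr(self, name)) != n:
                raise MircalError(f"{name} length must match d")
        q = self.qvalue.dropna()
        if ((q < 0) | (q > 1)).any():
            raise MircalError("q-values must lie in [0, 1]")
        if not frozenset(self.significant) <= set(self.d.index):
            raise MircalError("significant set must be a subset of tested features")
        object.__setattr__(self, "significant", frozenset(self.significant))

    def table(self) -> pd.DataFrame:
        """Per-feature summary with score, expected score, fold change and q."""
        return pd.DataFrame(
            {
                "score": self.d,
                "expected_score": self.d_expected,
                "fold_change": self.fold_change,
                "qvalue": self.qvalue,
                "called": self.d.index.isin(self.significant),
            }
        )
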