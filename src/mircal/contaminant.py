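"""Cellular contaminant cataloguing and filtering.

Features consistently detected in the cellular blood fractions (red blood
cells, buffy-coat white cells, Ficoll-purified leukocytes) are treated as
hematopoietic contaminants of plasma preparations.  The catalogue is the
union of the per-class sets obtained under a 100% detection criterion
(present in every sample of the class).
"""

from __future__ import annotations

import math
from typing import Iterable, overload

from .types import (
    CELLULAR_FRACTIONS,
    ContaminantCatalog,
    DetectionTable,
    MetadataError,
    MircalError,
    ProbesetMatrix,
    SampleSheet,
)


def detected_set(
    d: DetectionTable, sample_ids: Iterable[str], rate: float = 1.0
) -> frozenset[str]:
    """Features called present in at least ``ceil(rate * n)`` of the samples.

    ``rate=1.0`` is the 100% criterion (present in all samples); a 50%
    rate over 18 samples requires at least 9 calls.
    """
    ids = list(sample_ids)
    if not ids:
        raise MircalError("sample_ids must be non-empty")
    if not 0 < rate <= 1:
        raise MircalError("rate must lie in (0, 1]")
    unknown = set(ids) - set(d.sample_ids)
    if unknown:
        raise MetadataError(f"unknown sample ids: {sorted(unknown)[:5]}")
    threshold = math.ceil(rate * len(ids))
    counts = d.calls[ids].sum(axis=1)
    return frozenset(counts.index[counts >= threshold])


def build_catalog(d: DetectionTable, samples: SampleSheet) -> ContaminantCatalog:
    """Union of per-cellular-class 100%-detected sets (RBC, WBC, LEU)."""
    per_class: dict[str, frozenset[str]] = {}
    for fraction in CELLULAR_FRACTIONS:
        ids = [s for s in samples.samples_in_fraction(fraction) if s in d.sample_ids]
        if not ids:
            raise MircalError(f"no samples for cellular class {fraction}")
        per_class[fraction] = detected_set(d, ids, rate=1.0)
    return ContaminantCatalog(per_class=per_class)


@overload
def filter_contaminants(features: ProbesetMatrix, catalog: ContaminantCatalog) -> ProbesetMatrix: ...
@overload
def filter_contaminants(features: Iterable[str], catalog: ContaminantCatalog) -> frozenset[str]: ...


def filter_contaminants(features, catalog: ContaminantCatalog):
    """Remove catalogue members from a feature set or expression matrix."""
    if isinstance(features, ProbesetMatrix):
        keep = [f for f in features.feature_ids if f not in catalog.members]
        return features.restrict_features(keep)
    return frozenset(features) - catalog.members
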