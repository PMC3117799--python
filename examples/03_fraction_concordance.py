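"""Rank concordance between plasma fractions and the contaminant profile.

Two Spearman maps: (1) every plasma fraction against the pooled cellular
profile (LWR) over the catalogue features — contaminant-rich fractions
(CS, P1) track it closely, clarified supernatants less so; (2) CS/S1/P1
against each other on the top-100 features after contaminant removal —
S1 preserves the CS content while the P1 pellet is compositionally
distinct.
"""

import pandas as pd

from mircal import (
    CELLULAR_FRACTIONS,
    PLASMA_FRACTIONS,
    ProbesetMatrix,
    SimulationParams,
    make_annotation,
    preprocess_pipeline,
    simulate_fractions,
)
from mircal.concordance import contaminant_profile, fraction_correlation_map, top_n_features
from mircal.contaminant import build_catalog, filter_contaminants

params = SimulationParams(seed=1)
annotation = make_annotation(params)
matrix, samples, _ = simulate_fractions(params, annotation)
expr, detection = preprocess_pipeline(matrix, annotation, mode="non_normalized")
catalog = build_catalog(detection, samples)

by_fraction = {
    f: expr.restrict_samples(samples.samples_in_fraction(f)) for f in PLASMA_FRACTIONS
}
cellular = [s for f in CELLULAR_FRACTIONS for s in samples.samples_in_fraction(f)]
lwr = contaminant_profile(expr.restrict_features(sorted(catalog.members)), cellular)
cmap = fraction_correlation_map(
    by_fraction, sorted(catalog.members), extra_profiles={"LWR": lwr}
)
print("Spearman vs the contaminant profile (catalogue features):")
print(cmap["LWR"].drop("LWR").round(3).to_string())

filtered = {
    f: filter_contaminants(by_fraction[f], catalog) for f in ("CS", "S1", "P1")
}
pool = ProbesetMatrix(
    pd.concat([filtered[f].values for f in ("CS", "S1", "P1")], axis=1), scale="log2"
)
ref = top_n_features(pool, 100)
fmap = fraction_correlation_map(filtered, ref)
print("\nSpearman after contaminant removal (top-100 features):")
print(fmap.round(3).to_string())
# CS~S1 stays high (circulating content preserved by the extra spin)
# while CS~P1 drops (the pellet holds different species).
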