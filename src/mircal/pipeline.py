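"""End-to-end orchestration of the two study arms.

``run_all`` executes, from a flat configuration: simulation (or loading
of user matrices), fraction-mode preprocessing (non-normalized), the
contaminant catalogue, contaminant filtering, fraction concordance,
cohort-mode preprocessing (quantile normalized), the +S/+L vs +S/-L
variability analysis, and the SAM gender differential analysis.  Every
stage's feature counts, parameters and seeds go into a manifest so a run
can be audited and reproduced from the run directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import contaminant as cont
from . import diffexp, io, preprocess, variability
from .simulate import SimulationParams, make_annotation, simulate_cohort, simulate_fractions
from .types import (
    CELLULAR_FRACTIONS,
    MircalError,
    PLASMA_FRACTIONS,
    ProbesetMatrix,
)

log = logging.getLogger("mircal")

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.06,
    "offset": 16.0,
    "catalog_rate": 1.0,
    "cohort_rate": 0.5,
    "fdr_target": 0.05,
    "n_perm": 1000,
    "strata": [20, 35, 50, 100],
}


def _sim_params(config: dict) -> SimulationParams:
    fields = set(SimulationParams.__dataclass_fields__)
    kwargs = {k: v for k, v in config.items() if k in fields}
    kwargs.setdefault("seed", config.get("seed", 0))
    return SimulationParams(**kwargs)


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the complete pipeline; returns the manifest dictionary.

    The configuration is a flat mapping; unknown keys matching simulation
    parameters are forwarded to the generator.  Outputs are written under
    ``out_dir`` in per-stage subdirectories.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: cfg[k] for k in sorted(cfg)}, "stages": {}}
    params = _sim_params(cfg)

    # --- simulate ---------------------------------------------------------
    annotation = make_annotation(params)
    frac_raw, frac_samples, frac_truth = simulate_fractions(params, annotation)
    cohort_raw, cohort_samples, cohort_truth = simulate_cohort(params, annotation)
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    io.write_probe_annotation(annotation, sim_dir / "probes.tsv")
    io.write_sample_sheet(frac_samples, sim_dir / "samples_fractions.tsv")
    io.write_sample_sheet(cohort_samples, sim_dir / "samples_cohort.tsv")
    io.write_probe_matrix(frac_raw, sim_dir / "matrix_fractions.tsv")
    io.write_probe_matrix(cohort_raw, sim_dir / "matrix_cohort.tsv")
    (sim_dir / "truth.json").write_text(
        json.dumps(
            {"fractions": frac_truth, "cohort": cohort_truth}, indent=2, default=str
        )
    )
    manifest["stages"]["simulate"] = {
        "n_features": params.n_features,
        "n_contaminant_planted": params.n_contaminant,
        "n_fraction_samples": len(frac_samples.sample_ids),
        "n_cohort_samples": len(cohort_samples.sample_ids),
    }

    # --- preprocess: fraction arm (non-normalized) ------------------------
    missing_cellular = [
        f for f in CELLULAR_FRACTIONS if not frac_samples.samples_in_fraction(f)
    ]
    if missing_cellular:
        raise MircalError(
            f"catalogue requested but cellular class missing: {missing_cellular}"
        )
    frac_expr, frac_det = preprocess.preprocess_pipeline(
        frac_raw, annotation, mode="non_normalized",
        alpha=cfg["alpha"], offset=cfg["offset"],
    )
    pre_dir = out / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    io.write_probeset_matrix(frac_expr, pre_dir / "expr_fractions.tsv")
    io.write_detection(
        frac_det, pre_dir / "detection_p_fractions.tsv",
        pre_dir / "detection_calls_fractions.tsv",
    )
    manifest["stages"]["preprocess_fractions"] = {
        "mode": "non_normalized",
        "n_features": len(frac_expr.feature_ids),
        "n_samples": len(frac_expr.sample_ids),
    }

    # --- contaminant catalogue -------------------------------------------
    catalog = cont.build_catalog(frac_det, frac_samples)
    io.write_catalog(catalog.members, out / "catalog.txt")
    filtered = cont.filter_contaminants(frac_expr, catalog)
    io.write_probeset_matrix(filtered, pre_dir / "expr_fractions_filtered.tsv")
    manifest["stages"]["catalog"] = {
        "n_members": len(catalog),
        "per_class": {k: len(v) for k, v in sorted(catalog.per_class.items())},
        "n_features_in": len(frac_expr.feature_ids),
        "n_features_retained": len(filtered.feature_ids),
        "n_features_dropped": len(frac_expr.feature_ids) - len(filtered.feature_ids),
    }

    # --- concordance ------------------------------------------------------
    by_fraction = {
        f: frac_expr.restrict_samples(frac_samples.samples_in_fraction(f))
        for f in PLASMA_FRACTIONS
    }
    cellular_ids = [
        s for f in CELLULAR_FRACTIONS for s in frac_samples.samples_in_fraction(f)
    ]
    lwr = conc.contaminant_profile(
        frac_expr.restrict_features(sorted(catalog.members)), cellular_ids
    )
    plasma_pool = ProbesetMatrix(
        pd.concat([by_fraction[f].values for f in PLASMA_FRACTIONS], axis=1),
        scale=frac_expr.scale,
    )
    top100 = conc.top_n_features(plasma_pool, min(100, len(frac_expr.feature_ids)))
    contaminant_map = conc.fraction_correlation_map(
        by_fraction, sorted(catalog.members) or top100, extra_profiles={"LWR": lwr}
    )
    conc_dir = out / "concordance"
    conc_dir.mkdir(exist_ok=True)
    contaminant_map.to_csv(conc_dir / "map_contaminant_features.tsv", sep="\t")
    filtered_by_fraction = {
        f: cont.filter_contaminants(by_fraction[f], catalog)
        for f in ("CS", "S1", "P1")
    }
    strata = conc.StrataSpec(tuple(cfg["strata"]))
    maps = {}
    pool_filtered = cont.filter_contaminants(plasma_pool, catalog)
    for size in strata.sizes:
        k = min(size, len(pool_filtered.feature_ids))
        ref = conc.top_n_features(pool_filtered, k)
        maps[size] = conc.fraction_correlation_map(filtered_by_fraction, ref)
        maps[size].to_csv(conc_dir / f"map_filtered_top{size}.tsv", sep="\t")
    manifest["stages"]["concordance"] = {
        "strata": list(strata.sizes),
        "cs_vs_lwr": float(contaminant_map.loc["CS", "LWR"]),
        "s1_vs_lwr": float(contaminant_map.loc["S1", "LWR"]),
    }

    # --- preprocess: cohort arm (normalized) ------------------------------
    cohort_expr, cohort_det = preprocess.preprocess_pipeline(
        cohort_raw, annotation, mode="normalized",
        alpha=cfg["alpha"], offset=cfg["offset"],
    )
    io.write_probeset_matrix(cohort_expr, pre_dir / "expr_cohort.tsv")
    io.write_detection(
        cohort_det, pre_dir / "detection_p_cohort.tsv",
        pre_dir / "detection_calls_cohort.tsv",
    )
    manifest["stages"]["preprocess_cohort"] = {
        "mode": "normalized",
        "n_features": len(cohort_expr.feature_ids),
        "n_samples": len(cohort_expr.sample_ids),
    }

    # --- variability ------------------------------------------------------
    part = variability.partition_classes(cohort_det, catalog, rate=cfg["cohort_rate"])
    var_dir = out / "variability"
    var_dir.mkdir(exist_ok=True)
    var_stage: dict = {
        "n_s_plus_l": len(part.s_plus_l),
        "n_s_only": len(part.s_only),
    }
    if len(part.s_plus_l) >= 2 and len(part.s_only) >= 2:
        _, t_int, p_int = variability.class_intensity_compare(cohort_expr, part)
        cv_table, t_cv, p_cv = variability.class_cv_compare(cohort_expr, part)
        cv_table.to_csv(var_dir / "class_cv.tsv", sep="\t", index=False)
        var_stage.update(
            intensity_t=t_int, intensity_p=p_int, cv_t=t_cv, cv_p=p_cv
        )
    (var_dir / "classes.json").write_text(
        json.dumps(
            {"s_plus_l": sorted(part.s_plus_l), "s_only": sorted(part.s_only)},
            indent=2,
        )
    )
    manifest["stages"]["variability"] = var_stage

    # --- differential expression ------------------------------------------
    cohort_filtered = cont.filter_contaminants(cohort_expr, catalog)
    sam = diffexp.run_sam(
        cohort_filtered, cohort_samples,
        fdr_target=cfg["fdr_target"], n_perm=cfg["n_perm"], seed=cfg["seed"],
    )
    kept = diffexp.detection_filter(sam.significant, cohort_det)
    de_dir = out / "diffexp"
    de_dir.mkdir(exist_ok=True)
    sam.table().sort_index().to_csv(
        de_dir / "sam_scores.tsv", sep="\t", index_label="probeset_id",
        float_format="%.6f",
    )
    clustering = None
    if len(kept) >= 2:
        clustering = diffexp.cluster_features(
            cohort_filtered.restrict_features(sorted(kept))
        )
        (de_dir / "clustering.json").write_text(
            json.dumps(
                {
                    "heights": clustering["heights"],
                    "leaf_order": clustering["leaf_order"],
                    "linkage": clustering["linkage"].tolist(),
                },
                indent=2,
            )
        )
    manifest["stages"]["diffexp"] = {
        "n_features_tested": len(cohort_filtered.feature_ids),
        "s0": sam.s0,
        "delta": sam.delta if np.isfinite(sam.delta) else "inf",
        "n_significant": len(sam.significant),
        "n_after_detection_filter": len(kept),
        "significant": sorted(kept),
        "n_perm": sam.n_perm,
        "seed": sam.seed,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
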