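"""End-to-end pipeline: generate -> variants -> copy number -> origin score
-> clustering -> statistics, with a machine-readable JSON report.

Every stage persists its outputs under the run directory and communicates
only through those files plus the returned report dictionary. All
randomness flows from the master seed through the generator's documented
child-seed scheme. ``paper_checks`` recomputes the four in-paper
contingency tests from their embedded printed counts and needs no input
files.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cluster import consensus_partition, gene_modules, signature_genes
from .copynumber import call_homdels_cohort, compute_burden, purity_qc_table
from .genome import arm_model
from .origin import (compare_scores, normalize_rnaseq, score_cohort,
                     train_panel)
from .stats import (coxph_fit, fisher_exact_rxc, km_estimate, logistic_fit,
                    logrank_test, mann_whitney, pearson_chi2,
                    pearson_correlation)
from .synthetic import (SimulationConfig, simulate_cohort,
                        simulate_expression, write_cohort)
from .variants import build_driver_profiles, filter_quality, merge_callers

# 2x2 / r x 2 tables reconstructed from the printed group sizes (42 mutated
# vs 43 QWT; clusters of 14/16/14) and printed percentages.
PAPER_TABLES = {
    "recurrence_by_driver": [[28, 14], [16, 27]],   # 66.7% vs 37.2% recur
    "death_by_driver": [[11, 31], [4, 39]],         # 26.2% vs 9% died
    "death_by_cluster": [[0, 14], [7, 9], [3, 11]],  # 0 / 43.7 / 21.4% died
    "recurrence_by_cluster": [[5, 9], [13, 3], [8, 6]],  # 35.7/81.2/57.1%
}


# --------------------------------------------------------------------- config

_SCHEMA = {
    "source": str,
    "seed": int,
    "output_dir": str,
    "paper_checks": bool,
    "synthetic": dict,
    "variants": dict,
    "copynumber": dict,
    "clustering": dict,
}
_VARIANT_KEYS = {"min_baseq": (int, float), "capture_size_mb": (int, float)}
_CN_KEYS = {"broad_threshold": (int, float), "homdel_rule": str}
_CLUSTER_KEYS = {"feature_method": str, "base_method": str,
                 "k_range": list, "n_resamples": int,
                 "subsample_fraction": (int, float), "n_features": int}


@dataclass
class PipelineConfig:
    source: str = "synthetic"
    seed: int = 0
    output_dir: str = "acrotype_run"
    paper_checks: bool = False
    synthetic: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    copynumber: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)


def validate_config(document: dict) -> PipelineConfig:
    """Schema-validate a config document; collects every violation."""
    errors = []
    if not isinstance(document, dict):
        raise ValueError("config must be a mapping")
    for key in document:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, typ in _SCHEMA.items():
        if key in document and not isinstance(document[key], typ):
            errors.append(f"key {key!r} must be {typ.__name__}")
    if isinstance(document.get("seed"), int) and document["seed"] < 0:
        errors.append("seed must be non-negative")
    if document.get("source", "synthetic") not in ("synthetic",):
        errors.append("source must be 'synthetic'")
    for block, allowed in (("variants", _VARIANT_KEYS),
                           ("copynumber", _CN_KEYS),
                           ("clustering", _CLUSTER_KEYS)):
        sub = document.get(block, {})
        if isinstance(sub, dict):
            for k, v in sub.items():
                if k not in allowed:
                    errors.append(f"unknown key {block}.{k}")
                elif not isinstance(v, allowed[k]):
                    errors.append(f"{block}.{k} has wrong type")
    if isinstance(document.get("synthetic"), dict):
        known = set(SimulationConfig.__dataclass_fields__)
        for k in document["synthetic"]:
            if k not in known:
                errors.append(f"unknown key synthetic.{k}")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return PipelineConfig(**{k: document[k] for k in document})


# ----------------------------------------------------------------------- runs

def paper_checks() -> dict:
    """The four in-paper contingency checks from embedded printed counts."""
    out = {}
    for name in ("recurrence_by_driver", "death_by_driver",
                 "death_by_cluster"):
        r = pearson_chi2(PAPER_TABLES[name])
        out[name] = {"test": "pearson_chi2", "statistic": r.statistic,
                     "df": r.df, "p_value": r.p_value}
    r = fisher_exact_rxc(PAPER_TABLES["recurrence_by_cluster"])
    out["recurrence_by_cluster"] = {"test": "fisher_exact_rxc",
                                    "p_value": r.p_value}
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the report dict
    and writes it (plus per-stage tables) under the output directory."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed,
              "config": _jsonable(config.__dict__), "stages": {}}

    # stage 1: cohort
    sim_cfg = SimulationConfig(**config.synthetic, seed=config.seed)
    cohort = simulate_cohort(sim_cfg)
    write_cohort(cohort, outdir / "cohort")
    report["stages"]["synthetic"] = {
        "n_patients": sim_cfg.n_patients,
        "n_genes": int(cohort.expression.shape[0]),
    }

    # stage 2: variant consensus and driver profiles
    vkw = config.variants
    filtered = filter_quality(cohort.calls,
                              min_baseq=vkw.get("min_baseq", 30))
    consensus = merge_callers(filtered)
    capture = vkw.get("capture_size_mb", sim_cfg.capture_size_mb)
    profiles = build_driver_profiles(consensus, capture)
    profiles.to_csv(outdir / "driver_profiles.tsv", sep="\t", index=False)
    cat_counts = profiles["driver_category"].value_counts().to_dict()
    report["stages"]["variants"] = {
        "n_consensus_calls": int(len(consensus)),
        "filter_counts": filtered.attrs["filter_counts"],
        "driver_categories": cat_counts,
        "tmb_mean": float(profiles["tmb"].mean()),
    }

    # stage 3: copy number
    qc = purity_qc_table(cohort.purity_ploidy)
    passed = qc[qc.status == "pass"]["sample"]
    segs = cohort.segments[cohort.segments["sample"].isin(passed)]
    burden = compute_burden(segs, arm_model(), cohort.purity_ploidy,
                            broad_threshold=config.copynumber.get(
                                "broad_threshold", 0.2))
    burden.to_csv(outdir / "cn_burden.tsv", sep="\t", index=False)
    homdel_calls = {}
    for gene, rule in (("CDKN2A", "small-gene"), ("NF1", "large-gene")):
        calls = call_homdels_cohort(
            cohort.bins[cohort.bins["sample"].isin(passed)],
            cohort.purity_ploidy, gene, rule)
        calls.to_csv(outdir / f"homdel_{gene}.tsv", sep="\t", index=False)
        homdel_calls[gene] = int(calls["deleted"].sum())
    merged = burden.merge(profiles, left_on="sample", right_on="patient")
    corr = pearson_correlation(merged["gcs"], merged["tmb"])
    report["stages"]["copynumber"] = {
        "n_qc_pass": int(len(passed)),
        "homdel_counts": homdel_calls,
        "gcs_tmb_pearson_r": corr.effect,
        "gcs_tmb_p": corr.p_value,
    }

    # stage 4: origin score (panel trained on a two-lineage reference set)
    train_labels = pd.DataFrame({
        "sample": [f"T{i:02d}" for i in range(1, 21)],
        "origin": ["acral"] * 10 + ["cutaneous"] * 10,
        "cluster": 0, "braf": False,
    })
    train_counts = simulate_expression(train_labels, sim_cfg,
                                       config.seed + 101)
    norm_train = normalize_rnaseq(train_counts)
    panel = train_panel(norm_train, train_labels["origin"])
    norm = normalize_rnaseq(cohort.expression)
    braf = pd.Series(cohort.labels["braf"].map(
        {True: "BRAF-activating", False: "BRAF-WT"}).to_numpy(),
        index=cohort.labels["sample"])
    scores = score_cohort(norm, panel, groups=braf)
    scores.scores.to_csv(outdir / "ac_scores.tsv", sep="\t")
    with open(outdir / "panel.json", "w") as fh:
        json.dump(panel.to_dict(), fh, indent=1)
    cmp_res = compare_scores(scores, braf, alternative="less",
                             order=("BRAF-activating", "BRAF-WT"))
    report["stages"]["origin_score"] = {
        "component_index": panel.component_index,
        "median_score_braf": float(
            scores.scores[braf == "BRAF-activating"].median()),
        "median_score_wt": float(scores.scores[braf == "BRAF-WT"].median()),
        "mwu_one_sided_p": cmp_res.p_value,
    }

    # stage 5: consensus clustering + signatures
    ckw = config.clustering
    log_expr = np.log2(cohort.expression + 1.0)
    res = consensus_partition(
        log_expr,
        feature_method=ckw.get("feature_method", "sd"),
        base_method=ckw.get("base_method", "pam"),
        k_range=tuple(ckw.get("k_range", (2, 3, 4, 5, 6))),
        n_resamples=ckw.get("n_resamples", 50),
        subsample_fraction=ckw.get("subsample_fraction", 0.8),
        n_features=ckw.get("n_features", 2000),
        seed=config.seed,
    )
    labels = res.best_labels()
    pd.DataFrame({"sample": res.samples, "cluster": labels}).to_csv(
        outdir / "cluster_labels.tsv", sep="\t", index=False)
    res.metrics.to_csv(outdir / "cluster_metrics.tsv", sep="\t")
    sig = signature_genes(log_expr, labels)
    sig.to_csv(outdir / "signature_genes.tsv", sep="\t")
    sig_mat = log_expr.loc[sig[sig.significant].index]
    modules = gene_modules(sig_mat, labels, k=3, seed=config.seed) \
        if len(sig_mat) >= 3 else None
    report["stages"]["clustering"] = {
        "best_k": res.best_k,
        "one_minus_pac": float(res.metrics.loc[res.best_k, "one_minus_pac"]),
        "n_signature_genes": int(sig.significant.sum()),
        "module_sizes": {m: len(g) for m, g in modules.modules.items()}
        if modules else {},
    }

    # stage 6: association and survival statistics
    clin = cohort.clinical
    rec_tab = pd.crosstab(clin["has_driver"], clin["recurrence"]) \
        .reindex(index=[True, False]).to_numpy()[:, ::-1]
    chi = pearson_chi2(rec_tab)
    X = np.column_stack([
        clin["has_driver"].astype(float),
        (clin["stage"] == "advanced").astype(float),
    ])
    logi = logistic_fit(X, clin["recurrence"].to_numpy(),
                        exog_names=["driver", "stage_advanced"])
    km = km_estimate(clin["time_to_death"], clin["death"])
    lr = logrank_test(clin["time_to_death"], clin["death"],
                      clin["has_driver"])
    cox = coxph_fit(clin["time_to_death"], clin["death"],
                    np.column_stack([clin["has_driver"].astype(float),
                                     clin["age"] - clin["age"].mean()]),
                    exog_names=["driver", "age_centred"])
    cox_breslow = coxph_fit(
        clin["time_to_death"], clin["death"],
        np.column_stack([clin["has_driver"].astype(float),
                         clin["age"] - clin["age"].mean()]),
        exog_names=["driver", "age_centred"], ties="breslow")
    report["stages"]["statistics"] = {
        "recurrence_by_driver_chi2_p": chi.p_value,
        "recurrence_driver_or": float(logi.odds_ratios[1]),
        "recurrence_driver_or_ci": logi.or_conf_int()[1].tolist(),
        "logrank_p": lr.p_value,
        "cox_driver_hr_efron": float(cox.hazard_ratios[0]),
        "cox_driver_hr_breslow": float(cox_breslow.hazard_ratios[0]),
        "cox_driver_hr_ci": cox.hr_conf_int()[0].tolist(),
        "km_final_survival": float(km.survival[-1]) if len(km.survival)
        else 1.0,
    }

    if config.paper_checks:
        report["paper_checks"] = paper_checks()

    report["wall_time_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report
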