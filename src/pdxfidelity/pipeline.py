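"""Cohort-level orchestration and report assembly.

Runs the analysis stages in dependency order over a synthetic or supplied
cohort and assembles a machine-readable JSON report of headline metrics.
The report is deterministic for a fixed config and seed (stage timings go
to the log, not the report).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pdxfidelity import cna, expression as expr_mod, purity as purity_mod, subtype as subtype_mod
from pdxfidelity.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_expression,
    simulate_loh_sites,
    observations_to_calls,
    observations_to_pileup,
)
from pdxfidelity.variants import build_paired_table, retention_summary

REPORT_SCHEMA_VERSION = 1
STAGES = ("simulate", "variants", "purity", "cna", "expression", "subtype")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def cohort_summary(
    per_pair: pd.DataFrame,
    retention_threshold: float = 90.0,
) -> dict:
    """Cohort roll-up of per-pair metrics.

    `per_pair` needs a `pct_shared` column (overall shared %, 0-100);
    optional columns r_squared / cn_r / expr_r contribute medians and
    ranges. Reports the count and percentage of pairs at or above the
    retention threshold.
    """
    if len(per_pair) == 0:
        raise ValueError("need >= 1 pair")
    n = len(per_pair)
    passing = int((per_pair["pct_shared"] >= retention_threshold).sum())
    out = {
        "n_pairs": n,
        "retention_threshold_pct": retention_threshold,
        "n_pairs_passing": passing,
        "pct_pairs_passing": round(100.0 * passing / n, 1),
        "failing_pairs": per_pair.loc[
            per_pair["pct_shared"] < retention_threshold, "patient"
        ].tolist()
        if "patient" in per_pair.columns
        else [],
    }
    for col in ("r_squared", "cn_r", "expr_r"):
        if col in per_pair.columns:
            v = per_pair[col].dropna()
            if len(v):
                out[col] = {
                    "median": float(v.median()),
                    "min": float(v.min()),
                    "max": float(v.max()),
                }
    return out


def run_pipeline(
    config: dict | SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the synthetic cohort end to end and assemble the report.

    `config` is a SimulationConfig or a dict of its fields. Stage order is
    fixed; requesting a stage whose prerequisites are not requested raises
    before any computation. Writes per-stage TSVs plus report.json and
    log.txt when `out_dir` is given; returns the report dict.
    """
    if config is None:
        config = SimulationConfig()
    elif isinstance(config, dict):
        config = SimulationConfig(**config)
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    downstream = set(stages) - {"simulate"}
    if downstream and "simulate" not in stages:
        raise ValueError("requested stages need the 'simulate' stage for input")

    log: list[str] = []
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "stages": list(stages),
    }
    t0 = time.perf_counter()
    cohort = simulate_cohort(config)
    log.append(f"simulate: n_patients={config.n_patients} seed={config.seed} "
               f"({time.perf_counter() - t0:.2f}s)")
    pair_map = {
        p["patient"]: (f"{p['patient']}_tumor", f"{p['patient']}_pdx")
        for p in cohort["patients"]
    }

    per_pair_rows = []
    if "variants" in stages:
        t0 = time.perf_counter()
        for p in cohort["patients"]:
            obs = p["observations"]
            table = build_paired_table(
                observations_to_calls(obs, "tumor", config),
                observations_to_calls(obs, "pdx", config),
                observations_to_pileup(obs, "tumor", f"{p['patient']}_tumor"),
                observations_to_pileup(obs, "pdx", f"{p['patient']}_pdx"),
                depth_threshold=config.depth_threshold,
                vaf_threshold=config.vaf_threshold,
            )
            p["paired_table"] = table
            m = retention_summary(table, with_regression=True)
            per_pair_rows.append(
                {
                    "patient": p["patient"],
                    "purity": p["purity"],
                    "total": m.total,
                    "detected": m.detected,
                    "recovered": m.recovered,
                    "pct_detected": m.pct_detected,
                    "pct_recovered": m.pct_recovered,
                    "pct_shared": m.pct_shared,
                    "pdx_specific": m.pdx_specific,
                    "r_squared": m.r_squared,
                }
            )
        per_pair = pd.DataFrame(per_pair_rows)
        totals = per_pair[["total", "detected", "recovered"]].sum()
        from pdxfidelity.variants import retention_from_counts

        overall = retention_from_counts(
            int(totals["total"]), int(totals["detected"]), int(totals["recovered"])
        )
        report["variants"] = {
            "per_pair": _jsonable(per_pair.to_dict(orient="records")),
            "overall": {
                "total": overall.total,
                "detected": overall.detected,
                "recovered": overall.recovered,
                "pct_detected": overall.pct_detected,
                "pct_recovered": overall.pct_recovered,
                "pct_shared": overall.pct_shared,
            },
        }
        log.append(f"variants: {len(per_pair)} pairs ({time.perf_counter() - t0:.2f}s)")

    if "purity" in stages:
        t0 = time.perf_counter()
        rows = []
        for i, p in enumerate(cohort["patients"]):
            rng = np.random.default_rng([config.seed % (2**31), 1000 + i])
            sites = simulate_loh_sites(p["purity"], config.depth_mean, 500, rng)
            est = purity_mod.estimate_purity_loh(sites)
            rows.append(
                {
                    "patient": p["patient"],
                    "true_purity": p["purity"],
                    "estimated_purity": est.purity,
                    "maf_mode": est.maf_mode,
                    "abs_error": abs(est.purity - p["purity"]),
                }
            )
        report["purity"] = {
            "per_patient": _jsonable(rows),
            "max_abs_error": max(r["abs_error"] for r in rows),
        }
        log.append(f"purity: {len(rows)} patients ({time.perf_counter() - t0:.2f}s)")

    if "cna" in stages:
        t0 = time.perf_counter()
        profiles = []
        for p in cohort["patients"]:
            for key in ("segments_tumor", "segments_pdx"):
                profiles.append(
                    cna.segments_to_windows(p[key], config.genome)
                )
        corr = cna.cn_correlation_matrix(profiles, pair_map=pair_map)
        p_val = cna.matched_vs_unmatched_test(corr["matched"], corr["unmatched"])
        report["cna"] = {
            "median_matched_r": float(np.median(corr["matched"])),
            "median_unmatched_r": float(np.median(corr["unmatched"])),
            "matched_vs_unmatched_p": float(p_val),
            "n_matched": len(corr["matched"]),
            "n_unmatched": len(corr["unmatched"]),
        }
        cohort["cn_correlation"] = corr
        log.append(f"cna: {len(profiles)} profiles ({time.perf_counter() - t0:.2f}s)")

    if "expression" in stages:
        t0 = time.perf_counter()
        mat = cohort["expression"]
        pca = expr_mod.run_pca(mat)
        filtered, filt = expr_mod.remove_top_loading_genes(mat, pca.loadings)
        ec = expr_mod.expression_correlation_matrix(filtered, pair_map=pair_map)
        report["expression"] = {
            "n_genes": int(mat.shape[0]),
            "n_removed": len(filt.removed),
            "n_retained": len(filt.retained),
            "median_matched_r": float(np.median(ec["matched"])),
            "median_unmatched_r": float(np.median(ec["unmatched"])),
            "matched_vs_unmatched_p": float(ec["p_value"]),
        }
        cohort["expression_filtered"] = filtered
        log.append(f"expression: {mat.shape[0]} genes ({time.perf_counter() - t0:.2f}s)")

    if "subtype" in stages:
        t0 = time.perf_counter()
        train_labels = [s for s in subtype_mod.SUBTYPE_LABELS for _ in range(30)]
        train_rng = np.random.default_rng([config.seed % (2**31), 77])
        train_mat, train_meta = simulate_expression(
            config,
            train_labels,
            [1.0] * len(train_labels),
            cohort["centroids"],
            caf_genes=cohort["caf_genes"],
            rng=train_rng,
            patient_ids=[f"train{i}" for i in range(len(train_labels))],
        )
        train_tumors = train_meta[train_meta["role"] == "tumor"].index
        gmc_train = subtype_mod.gene_median_normalize(train_mat[train_tumors], log2=True)
        model = subtype_mod.train_subtype_model(
            gmc_train,
            train_meta.loc[train_tumors, "subtype"],
            cohort["signature_genes"],
            seed=config.seed % (2**31),
        )
        meta = cohort["expression_meta"]
        tumors = meta[meta["role"] == "tumor"].index
        gmc = subtype_mod.gene_median_normalize(cohort["expression"][tumors], log2=True)
        preds = subtype_mod.predict_subtype(model, gmc)
        truth_labels = meta.loc[tumors, "subtype"]
        acc = float((preds["label"] == truth_labels).mean())
        caf = subtype_mod.caf_signature_score(
            gmc, cohort["caf_genes"], subtype_labels=preds["label"]
        )
        report["subtype"] = {
            "oob_accuracy": model.oob_accuracy,
            "cohort_accuracy": acc,
            "predictions": _jsonable(
                {s: preds.loc[s, "label"] for s in preds.index}
            ),
            "n_marginal": int(preds["marginal"].sum()),
            "caf_mesenchymal_vs": _jsonable(caf.get("mesenchymal_vs", {})),
        }
        log.append(f"subtype: oob={model.oob_accuracy:.3f} ({time.perf_counter() - t0:.2f}s)")

    if "variants" in stages:
        report["cohort_summary"] = _jsonable(cohort_summary(pd.DataFrame(per_pair_rows)))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "variants" in stages:
            pd.DataFrame(per_pair_rows).to_csv(out / "retention.tsv", sep="\t", index=False)
        if "cna" in stages:
            cohort["cn_correlation"]["matrix"].to_csv(out / "cn_correlation.tsv", sep="\t")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(out / "log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
    report["_log"] = log
    return report


def report_json(report: dict) -> str:
    """Canonical JSON rendering of a report (log excluded, keys sorted)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=1, sort_keys=True)
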