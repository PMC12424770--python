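"""End-to-end orchestration of the four model families.

Four families link per-species retroelement metrics to cancer prevalence:

* **abundance** — counts of potentially active L1s / combined L1+SINEs;
* **proximity_mean** / **proximity_median** — IQR-trimmed mean (or median)
  distance from active elements to the nearest protein-coding gene or CGO;
* **genic_insertion** — counts of active elements inside genes / CGOs;
* **cgo_load** — cancer-gene-ortholog counts (total and functional subsets).

For every configured model the pipeline Tukey-transforms the response and
predictors, min-max scales the predictors, fits the weighted PGLS with
estimated Pagel's lambda (weights 1/sqrt(necropsy count)), tabulates the AIC
of the lambda in {0, lambda_hat, 1} fits, and applies Benjamini-Hochberg FDR
within each (family, response) group. Failures are captured per model; the
batch always completes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cgo as cgo_mod
from . import cohort as cohort_mod
from . import pgls
from . import proximity as prox_mod
from . import repeats as rep_mod
from . import transforms

logger = logging.getLogger(__name__)

__all__ = ["load_config", "build_predictor_table", "run_models", "write_report"]

RESPONSE_COLUMNS = {
    "neoplasia": "neoplasia_prevalence",
    "malignancy": "malignancy_prevalence",
}

FAMILY_PREDICTORS = {
    "abundance": ["n_active_l1", "n_combined"],
    "proximity_mean": [
        "prox_mean_pc_l1",
        "prox_mean_pc_combined",
        "prox_mean_cgo_l1",
        "prox_mean_cgo_combined",
    ],
    "proximity_median": [
        "prox_median_pc_l1",
        "prox_median_pc_combined",
        "prox_median_cgo_l1",
        "prox_median_cgo_combined",
    ],
    "genic_insertion": [
        "genic_pc_l1",
        "genic_pc_combined",
        "genic_cgo_l1",
        "genic_cgo_combined",
    ],
    "cgo_load": [
        "cgo_total",
        "cgo_somatic",
        "cgo_germline",
        "cgo_oncogene",
        "cgo_tsg",
        "cgo_fusion",
    ],
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    config["_base_dir"] = str(path.parent)
    return config


def _resolve(config: dict, key: str) -> Optional[Path]:
    rel = config.get("paths", {}).get(key)
    if rel is None:
        return None
    return Path(config["_base_dir"]) / rel


def build_predictor_table(config: dict) -> tuple[pd.DataFrame, list[dict]]:
    """Assemble the species x predictor table from the configured inputs.

    Returns (table indexed by species_id, exclusion log). Species lacking an
    upstream input (e.g. no gene annotation) keep NaN in the affected columns
    and are dropped per-model, not globally.
    """
    records = cohort_mod.load_cohort_table(_resolve(config, "cohort"))
    min_n = int(config.get("thresholds", {}).get("min_necropsies", 20))
    require_mal = bool(config.get("thresholds", {}).get("require_malignant", True))
    retained, log = cohort_mod.filter_cohort(records, min_records=min_n,
                                             require_malignant=require_mal)
    table = cohort_mod.cohort_to_frame(retained).set_index("species_id")

    dialect = config.get("paths", {}).get("repeat_dialect", "bed")
    repeats_dir = _resolve(config, "repeats_dir")
    genes_dir = _resolve(config, "genes_dir")
    cgo_flags_path = _resolve(config, "cgo_flags")
    cgo_flags = prox_mod.load_cgo_flags(cgo_flags_path) if cgo_flags_path and cgo_flags_path.exists() else {}

    for sp in table.index:
        rep_path = repeats_dir / f"{sp}.bed" if repeats_dir else None
        if dialect == "rmsk_out" and repeats_dir:
            rep_path = repeats_dir / f"{sp}.out"
        if rep_path is None or not rep_path.exists():
            logger.info("no repeat annotation for %s; abundance metrics missing", sp)
            continue
        reps = rep_mod.parse_repeat_annotation(rep_path, dialect=dialect)
        counts = rep_mod.count_active(reps, sp)
        table.loc[sp, "n_active_l1"] = counts.n_active_l1
        table.loc[sp, "n_active_sine"] = counts.n_active_sine
        table.loc[sp, "n_combined"] = counts.n_combined

        gene_path = genes_dir / f"{sp}.bed" if genes_dir else None
        if gene_path is None or not gene_path.exists():
            logger.info("no gene annotation for %s; proximity/genic metrics missing", sp)
            continue
        genes = prox_mod.load_gene_bed(gene_path, cgo_flags)
        cgo_genes = [g for g in genes if g.is_cgo]
        active_l1 = [
            r for r in reps if r.superfamily == "L1" and rep_mod.is_active_l1(r)
        ]
        active_sine = [
            r for r in reps if r.superfamily == "SINE" and rep_mod.is_active_sine(r)
        ]
        active_combined = active_l1 + active_sine
        for elem_label, elems in (("l1", active_l1), ("combined", active_combined)):
            for gene_label, targets in (("pc", genes), ("cgo", cgo_genes)):
                if not elems or not targets:
                    continue
                dists, _ = prox_mod.closest_distances(elems, targets)
                if dists.size:
                    st = prox_mod.proximity_stats(dists)
                    table.loc[sp, f"prox_mean_{gene_label}_{elem_label}"] = st.iqr_mean
                    table.loc[sp, f"prox_median_{gene_label}_{elem_label}"] = st.median
                table.loc[sp, f"genic_{gene_label}_{elem_label}"] = (
                    prox_mod.genic_insertion_count(elems, targets)
                )

    groups_path = _resolve(config, "orthogroups")
    counts_path = _resolve(config, "orthogroup_counts")
    genes_meta_path = _resolve(config, "cancer_genes")
    if groups_path and groups_path.exists() and counts_path and counts_path.exists():
        orthogroups = cgo_mod.parse_orthogroups(groups_path, counts_path)
        entries = cgo_mod.load_cancer_genes(genes_meta_path)
        query_sp = config.get("paths", {}).get("query_species", "human")
        for sp in table.index:
            profile = cgo_mod.count_cgo(entries, orthogroups, sp, query_sp)
            table.loc[sp, "cgo_total"] = profile.total
            table.loc[sp, "cgo_somatic"] = profile.somatic
            table.loc[sp, "cgo_germline"] = profile.germline
            table.loc[sp, "cgo_oncogene"] = profile.oncogene
            table.loc[sp, "cgo_tsg"] = profile.tsg
            table.loc[sp, "cgo_fusion"] = profile.fusion
    return table, log


def _fit_one_model(
    table: pd.DataFrame,
    tree,
    response: str,
    predictor: str,
    include_longevity: bool,
) -> dict:
    cols = [RESPONSE_COLUMNS[response], predictor, "weight"]
    if include_longevity:
        cols.append("longevity_months")
    sub = table[cols].dropna()
    n = len(sub)
    if n < 5:
        raise ValueError(f"only {n} usable species")

    y_raw = sub[RESPONSE_COLUMNS[response]].to_numpy()
    ty = transforms.tukey_transform(y_raw)
    pred_names = [predictor] + (["longevity_months"] if include_longevity else [])
    X_cols = [np.ones(n)]
    powers = {"response": ty.lambda_t}
    for name in pred_names:
        tp = transforms.tukey_transform(sub[name].to_numpy())
        powers[name] = tp.lambda_t
        X_cols.append(transforms.minmax_normalize(tp.transformed))
    X = np.column_stack(X_cols)
    species = list(sub.index)
    cov = pgls.vcv_from_tree(tree, species)
    w = sub["weight"].to_numpy()

    fit = pgls.fit_pgls(
        ty.transformed, X, cov.C, weights=w, lambda_mode="estimate",
        names=["intercept"] + pred_names,
    )
    aic_table = pgls.compare_lambda_models(ty.transformed, X, cov.C, weights=w)
    aics = dict(zip(aic_table["model"], aic_table["aic"]))
    row = {
        "n_species": n,
        "slope": float(fit.beta[1]),
        "slope_se": float(fit.se_beta[1]),
        "p": float(fit.p_values[1]),
        "lambda_hat": fit.lambda_hat,
        "sigma2_hat": fit.sigma2_hat,
        "r2": fit.r2,
        "r2_adj": fit.r2_adj,
        "loglik": fit.loglik,
        "aic_0": float(aics["lambda_0"]),
        "aic_hat": float(aics["lambda_hat"]),
        "aic_1": float(aics["lambda_1"]),
        "tukey_powers": powers,
        "diagnostics": fit.diagnostics,
    }
    if include_longevity:
        row["longevity_coef"] = float(fit.beta[2])
        row["longevity_p"] = float(fit.p_values[2])
    return row


def run_models(config: dict) -> dict:
    """Run every configured model and return the report dictionary."""
    table, exclusions = build_predictor_table(config)
    tree = pgls.read_tree(_resolve(config, "tree"))
    tip_labels = {t.taxon.label for t in tree.leaf_node_iter()}
    off_tree = sorted(set(table.index) - tip_labels)
    if off_tree:
        logger.info("dropping species absent from the tree: %s", off_tree)
        table = table.drop(index=off_tree)

    mconf = config.get("models", {})
    families = mconf.get("families", list(FAMILY_PREDICTORS))
    responses = mconf.get("responses", ["neoplasia", "malignancy"])
    include_longevity = bool(mconf.get("include_longevity", False))
    fdr_q = float(config.get("fdr_q", 0.05))

    model_rows: list[dict] = []
    for family in families:
        for response in responses:
            for predictor in FAMILY_PREDICTORS[family]:
                variants = [False] + ([True] if include_longevity else [])
                for with_lon in variants:
                    model_id = f"{family}:{response}~{predictor}" + (
                        "+longevity" if with_lon else ""
                    )
                    row = {
                        "model_id": model_id,
                        "family": family,
                        "response": response,
                        "predictor": predictor,
                        "with_longevity": with_lon,
                        "fdr_group": f"{family}:{response}",
                    }
                    if predictor not in table.columns or table[predictor].dropna().empty:
                        row.update(status="skipped", error="predictor unavailable")
                        model_rows.append(row)
                        continue
                    try:
                        row.update(
                            _fit_one_model(table, tree, response, predictor, with_lon)
                        )
                        row["status"] = "ok"
                    except Exception as exc:  # captured per model, batch continues
                        logger.warning("model %s failed: %s", model_id, exc)
                        row.update(status="error", error=str(exc))
                    model_rows.append(row)

    # BH-FDR within each (family, response) group
    for group in sorted({r["fdr_group"] for r in model_rows}):
        idx = [i for i, r in enumerate(model_rows)
               if r["fdr_group"] == group and r.get("status") == "ok"]
        if not idx:
            continue
        adjusted, reject = pgls.bh_fdr([model_rows[i]["p"] for i in idx], q=fdr_q)
        for j, i in enumerate(idx):
            model_rows[i]["p_adj"] = float(adjusted[j])
            model_rows[i]["fdr_significant"] = bool(reject[j])

    correlations = _predictor_correlations(table)
    report = {
        "n_species_cohort": int(len(table)),
        "exclusions": exclusions,
        "models": model_rows,
        "predictor_correlations": correlations,
        "fdr_q": fdr_q,
    }
    return report


def _predictor_correlations(table: pd.DataFrame) -> list[dict]:
    """Pearson interrelationships among key predictors (e.g. active L1 count
    vs fusion-gene ortholog count)."""
    panel = [
        ("n_active_l1", "cgo_fusion"),
        ("n_active_l1", "cgo_total"),
        ("cgo_oncogene", "cgo_tsg"),
        ("n_active_l1", "n_combined"),
    ]
    out = []
    for a, b in panel:
        if a in table.columns and b in table.columns:
            sub = table[[a, b]].dropna()
            if len(sub) >= 3 and sub[a].nunique() > 1 and sub[b].nunique() > 1:
                out.append({"x": a, "y": b,
                            "r": pgls.pearson_r(sub[a], sub[b]), "n": len(sub)})
    return out


def write_report(report: dict, out_dir: str | Path) -> None:
    """JSON report plus a flat TSV of the model rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")
    rows = []
    for r in report["models"]:
        flat = {k: v for k, v in r.items() if not isinstance(v, (dict, list))}
        rows.append(flat)
    pd.DataFrame(rows).to_csv(out / "models.tsv", sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
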