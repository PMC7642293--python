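"""End-to-end orchestration: simulate -> derive -> score -> associate -> co-IP.

``run_end_to_end`` drives the full synthetic reproduction: knock-down counts
through TMM/log2-CPM and the moderated t to a derived signature, cohort
scoring with quartile classification and the association statistics, and the
co-IP enrichment branch; every artifact lands in the run directory as TSV
plus a machine-readable JSON summary.  ``reproduce_tables`` rebuilds the two
published extreme-quartile contingency tables from their printed counts and
reports the exact Fisher statistics.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc_stats, coip_ms, diffexpr, io_core, signature as sigmod
from .synthetic_data import (
    CohortSimConfig,
    CoipSimConfig,
    DimethylSimConfig,
    KDSimConfig,
    gen_cohort,
    gen_coip_peptides,
    gen_dimethyl_psms,
    gen_kd_counts,
)

__all__ = ["stage_seed", "run_end_to_end", "reproduce_tables", "DEFAULT_CONFIG"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name.

    CRC32 of the stage name mixed with the global seed, reduced mod 2^31 so
    the result is a valid small seed everywhere.
    """
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "kd": {
        "n_genes": 2000,
        "n_replicates_per_arm": 4,
        "n_true_de": 400,
        "log2fc_magnitude": 2.0,
        "dispersion": 0.05,
    },
    "signature": {
        "lfc_threshold": 1.5,
        "fdr_threshold": 0.01,
        "top_n": 419,
        "weight_mode": "sign",
    },
    "cohort": {
        "n_samples_per_state": {"benign": 20, "PCa": 60, "CRPC-Adeno": 120, "CRPC-NE": 60},
        "effect_size_sd": 1.5,
        "n_background_genes": 900,
    },
    "coip": {
        "n_proteins": 400,
        "n_bait_partners": 20,
        "enrichment_log2": 3.0,
        "n_replicates": 3,
    },
    "dimethyl": {"n_proteins": 100, "n_partners": 10},
}


def _merge(default: dict, override: dict | None) -> dict:
    out = dict(default)
    for k, v in (override or {}).items():
        out[k] = v
    return out


def run_end_to_end(config: dict | None = None, outdir: str | Path = "run") -> dict:
    """Run the full synthetic pipeline and write all artifacts to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Deterministic for a fixed config: every stochastic stage draws its seed
    from the global seed and its stage name.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    for key in ("kd", "signature", "cohort", "coip", "dimethyl"):
        cfg[key] = _merge(DEFAULT_CONFIG[key], cfg.get(key))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gseed = int(cfg["seed"])
    summary: dict = {"seed": gseed}

    # --- stage 1: knock-down experiment ------------------------------------
    kd_cfg = KDSimConfig(**cfg["kd"], seed=stage_seed(gseed, "kd"))
    counts, kd_ann, kd_truth = gen_kd_counts(kd_cfg)
    io_core.write_matrix(counts, outdir / "kd_counts.tsv")
    kd_ann.to_csv(outdir / "kd_design.tsv", sep="\t", lineterminator="\n")

    filtered = diffexpr.filter_low_expression(counts)
    factors = diffexpr.tmm_factors(filtered)
    lcpm = diffexpr.log2_cpm(filtered, factors)
    de = diffexpr.moderated_t_test(
        lcpm, kd_ann["group"].tolist(), kd_ann["batch"].tolist()
    )
    de.to_csv(outdir / "de_results.tsv", sep="\t", lineterminator="\n")
    n_sig = int(((de["fdr"] < 0.05) & (de["log2fc"].abs() > 1)).sum())
    summary["kd"] = {
        "n_genes_after_filter": int(filtered.shape[0]),
        "n_de_fdr05_2fold": n_sig,
        "n_true_de": len(kd_truth.true_de_genes),
    }

    # --- stage 2: signature derivation -------------------------------------
    sig = sigmod.derive_signature(de, **cfg["signature"])
    io_core.write_signature(sig, outdir / "signature.tsv")
    truth_lfc = kd_truth.true_de_genes
    recovered = sum(g in truth_lfc for g in sig.genes)
    summary["signature"] = {
        "n_genes": len(sig.genes),
        "n_true_positive": int(recovered),
        "precision": recovered / len(sig.genes),
    }

    # --- stage 3: cohort scoring and association ----------------------------
    co_cfg = CohortSimConfig(
        **cfg["cohort"],
        signature_genes={g: sig.directions[g] for g in sig.genes},
        seed=stage_seed(gseed, "cohort"),
    )
    expr, annotation, co_truth = gen_cohort(co_cfg)
    io_core.write_matrix(expr, outdir / "cohort_expression.tsv")
    io_core.write_annotation(annotation, outdir / "cohort_annotation.tsv")

    raw = sigmod.score_samples(expr, sig)
    rescaled = sigmod.rescale_scores(raw)
    classes = sigmod.classify_quartiles(rescaled)
    scores = pd.DataFrame(
        {"raw_score": raw, "rescaled_score": rescaled, "class": classes}
    )
    scores.index.name = "sample"
    scores.to_csv(outdir / "scores.tsv", sep="\t", lineterminator="\n")

    assoc = associate(scores, annotation)
    pd.DataFrame(assoc["tests"]).to_csv(
        outdir / "association_tests.tsv", sep="\t", index=False, lineterminator="\n"
    )
    summary["association"] = {
        t["name"]: {"statistic": t["statistic"], "p": t["p"], "n": t["n"]}
        for t in assoc["tests"]
    }
    summary["association_tables"] = assoc["tables"]

    # --- stage 4: co-IP enrichment ------------------------------------------
    coip_cfg = CoipSimConfig(**cfg["coip"], seed=stage_seed(gseed, "coip"))
    peptides, coip_truth = gen_coip_peptides(coip_cfg)
    norm = coip_ms.normalize_peptides(peptides)
    top3 = coip_ms.top3_quantify(norm, value_col="log_intensity")
    wide = top3.pivot_table(
        index="protein", columns=["condition", "replicate"], values="top3", aggfunc="first"
    )
    wide.columns = [f"{c}_{r}" for c, r in wide.columns]
    groups = {col: col.split("_")[0] for col in wide.columns}
    imputed = coip_ms.impute_missing(
        wide, groups, level="protein", seed=stage_seed(gseed, "impute")
    )
    enr = coip_ms.enrichment_test(imputed, groups, test_group="IP")
    enr = coip_ms.significance_curve(enr)
    enr.to_csv(outdir / "coip_enrichment.tsv", sep="\t", lineterminator="\n")
    called = set(enr.index[enr["significant"]])
    partners = set(coip_truth.true_partner_proteins)
    summary["coip"] = {
        "n_proteins_tested": int(len(enr)),
        "n_significant": int(len(called)),
        "n_partners_recovered": int(len(called & partners)),
        "n_partners_planted": len(partners),
    }

    # --- stage 5: dimethyl ratios -------------------------------------------
    dm_cfg = DimethylSimConfig(**cfg["dimethyl"], seed=stage_seed(gseed, "dimethyl"))
    psms, dm_truth = gen_dimethyl_psms(dm_cfg)
    psms.to_csv(outdir / "dimethyl_psms.tsv", sep="\t", index=False, lineterminator="\n")
    ratios = coip_ms.dimethyl_ratios(
        psms, experimental_channel=dm_truth.extra["experimental_channel"]
    )
    ratios.to_csv(outdir / "dimethyl_ratios.tsv", sep="\t", index=False, lineterminator="\n")
    top_by_ratio = ratios.nlargest(dm_cfg.n_partners, "log2_ratio")["protein"]
    summary["dimethyl"] = {
        "n_proteins_quantified": int(len(ratios)),
        "n_partners_in_top": int(top_by_ratio.isin(dm_truth.true_partner_proteins).sum()),
        "n_partners_planted": dm_cfg.n_partners,
    }

    io_core.write_config(
        {**cfg, "stage_seeds": {s: stage_seed(gseed, s) for s in
                               ("kd", "cohort", "coip", "impute", "dimethyl")}},
        outdir / "config.yaml",
    )
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def associate(scores: pd.DataFrame, annotation: pd.DataFrame) -> dict:
    """Run the association battery of score vs phenotype.

    Builds the extreme-quartile 2x2 table (CRPC-NE vs CRPC-Adeno by low vs
    high score class, mid dropped), Fisher exact test, Mann-Whitney of score
    across states, Mann-Kendall trend of the fraction of low scores across
    risk-score deciles, and (when outcome columns exist) the log-rank test of
    low vs rest.
    """
    ann = annotation.loc[scores.index]
    tests = []
    tables = {}

    ne = scores.index[ann["state"] == "CRPC-NE"]
    adeno = scores.index[ann["state"] == "CRPC-Adeno"]
    if len(ne) and len(adeno):
        cls = scores["class"]
        table = [
            [int((cls[ne] == "low").sum()), int((cls[ne] == "high").sum())],
            [int((cls[adeno] == "low").sum()), int((cls[adeno] == "high").sum())],
        ]
        if min(sum(table[0]), sum(table[1]), table[0][0] + table[1][0],
               table[0][1] + table[1][1]) > 0:
            odds, p = assoc_stats.fisher_exact_2x2(table)
            n_extreme = sum(map(sum, table))
            tests.append({"name": "fisher_extreme_quartiles", "statistic": odds,
                          "p": p, "n": n_extreme})
            tables["extreme_quartiles"] = table

        u, p = assoc_stats.mann_whitney_u(
            scores.loc[ne, "rescaled_score"], scores.loc[adeno, "rescaled_score"]
        )
        tests.append({"name": "mannwhitney_ne_vs_adeno", "statistic": u, "p": p,
                      "n": int(len(ne) + len(adeno))})

    if "risk_score" in ann.columns:
        deciles = pd.qcut(ann["risk_score"], 10, labels=False, duplicates="drop")
        frac_low = (
            (scores["class"] == "low").groupby(deciles).mean().sort_index()
        )
        if len(frac_low) >= 3:
            s, z, p = assoc_stats.mann_kendall(frac_low.to_numpy())
            tests.append({"name": "mannkendall_lowfrac_by_risk_decile",
                          "statistic": float(s), "p": p, "n": int(len(frac_low))})

    if "gleason_group" in ann.columns:
        hi_g = scores.loc[ann["gleason_group"] >= 4, "rescaled_score"]
        lo_g = scores.loc[ann["gleason_group"] <= 2, "rescaled_score"]
        if len(hi_g) and len(lo_g):
            u, p = assoc_stats.mann_whitney_u(hi_g, lo_g)
            tests.append({"name": "mannwhitney_gleason_high_vs_low",
                          "statistic": u, "p": p, "n": int(len(hi_g) + len(lo_g))})

    if {"time", "event"} <= set(ann.columns):
        grp = np.where(scores["class"] == "low", "low", "other")
        _, chi2, p = assoc_stats.km_logrank(ann["time"], ann["event"], grp)
        tests.append({"name": "logrank_low_vs_rest", "statistic": chi2, "p": p,
                      "n": int(len(ann))})

    return {"tests": tests, "tables": tables}


# published extreme-quartile tables, reconstructed from the printed counts:
# rows = (CRPC-NE, CRPC-Adeno), columns = (low score, high score)
PUBLISHED_TABLES = {
    # SU2C-PCF CRPC cohort, extreme quartiles of 332 cases (table n = 138):
    # 16/16 CRPC-NE low; 57 of 122 CRPC-Adeno low (46.7%)
    "fig3a": [[16, 0], [57, 65]],
    # WCM CRPC cohort, extreme half of 47 cases (table n = 25):
    # 8/9 CRPC-NE low (89%); 5/16 CRPC-Adeno low (31%)
    "fig3b": [[8, 1], [5, 11]],
}


def reproduce_tables(source: str) -> dict:
    """Fisher statistics on a published extreme-quartile table.

    ``source`` is ``'fig3a'`` (SU2C-PCF, n=138) or ``'fig3b'`` (WCM, n=25).
    """
    if source not in PUBLISHED_TABLES:
        raise ValueError(f"unknown table {source!r}; choose from {sorted(PUBLISHED_TABLES)}")
    table = PUBLISHED_TABLES[source]
    odds, p = assoc_stats.fisher_exact_2x2(table)
    return {
        "source": source,
        "table": table,
        "n": int(sum(map(sum, table))),
        "odds_ratio": odds,
        "p_two_sided": p,
    }
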