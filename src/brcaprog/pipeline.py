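"""End-to-end analysis pipeline on a (synthetic or real) cohort.

simulate -> cohort classification -> receptor subtyping -> differential
expression against normal tissue for each prognosis group -> selection of
prognosis-group-specific genes -> tertile survival screen -> clinical
statistics.  Each stage writes its standard tabular artifact into the
output directory.
"""

from __future__ import annotations

import json
import os
import warnings

import pandas as pd

from . import (
    CohortConfig,
    classify_prognosis,
    cohort_summary,
    differential_expression,
    fit_receptor_thresholds,
    call_receptors,
    gene_survival_screen,
    logistic_prognosis,
    pca2,
    select_group_specific,
    simulate_cell_fractions,
    simulate_cohort,
    subtype_calls,
    table_one,
    write_clinical,
    write_expression,
)
from .io_cohort import write_cohort


def run_pipeline(
    outdir: str,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Simulate a cohort and run every analysis stage, writing artifacts.

    Returns a mapping of artifact name to file path.  All randomness
    derives from ``seed``.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "expression": "expr.tsv",
        "clinical": "clinical.tsv",
        "truth": "truth.json",
        "cohort": "cohort.json",
        "thresholds": "thresholds.json",
        "subtypes": "subtypes.tsv",
        "de_pp": "de_pp.tsv",
        "de_gp": "de_gp.tsv",
        "gene_sets": "sets.json",
        "pca": "pca.tsv",
        "screen": "screen.tsv",
        "table1": "table1.json",
        "cellcomp": "cellcomp.tsv",
    }.items()}

    expr, clinical, truth = simulate_cohort(config, seed=seed)
    write_expression(expr, paths["expression"])
    write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["truth"])

    groups = classify_prognosis(clinical)
    write_cohort(groups, paths["cohort"])

    thresholds = fit_receptor_thresholds(expr, seed=seed)
    with open(paths["thresholds"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                g: {
                    "threshold": t.threshold,
                    "in_interval": t.in_interval,
                    "weights": t.fit.weights.tolist(),
                    "means": t.fit.means.tolist(),
                    "sds": t.fit.sds.tolist(),
                    "converged": t.fit.converged,
                }
                for g, t in thresholds.items()
            },
            fh, indent=1,
        )
    status = call_receptors(expr, thresholds, samples=expr.tumor_samples())
    subtypes = subtype_calls(status)
    subtypes.to_csv(paths["subtypes"], sep="\t")

    normal = expr.samples_in_group("Normal")
    gp = expr.samples_in_group("GP")
    pp = expr.samples_in_group("PP")
    de_pp = differential_expression(expr, normal, pp)
    de_gp = differential_expression(expr, normal, gp)
    de_pp.to_csv(paths["de_pp"], sep="\t")
    de_gp.to_csv(paths["de_gp"], sep="\t")

    sets = select_group_specific(de_pp, de_gp)
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        json.dump(sets.to_dict(), fh, indent=1)

    signature = sorted(sets.pp_signature())
    if len(signature) >= 2:
        scores, explained = pca2(expr, signature)
        scores.assign(group=[expr.sample_group.get(s) for s in scores.index]) \
            .to_csv(paths["pca"], sep="\t")
    else:
        warnings.warn("fewer than 2 signature genes; PCA skipped")
        pd.DataFrame(columns=["PC1", "PC2", "group"]).to_csv(
            paths["pca"], sep="\t"
        )

    screen_genes = signature if signature else expr.genes[: min(50, len(expr.genes))]
    screen = gene_survival_screen(expr, clinical, screen_genes)
    screen.to_csv(paths["screen"], sep="\t")

    t1 = table_one(clinical, groups, subtypes=subtypes["subtype"])
    try:
        fit = logistic_prognosis(clinical, groups, predictors=("age", "stage"))
        t1["logistic"] = {
            "converged": fit.converged,
            "n": fit.n,
            "n_events": fit.n_events,
            "predictors": {
                name: {
                    "coef": float(row["coef"]),
                    "odds_ratio": float(row["or_"]),
                    "p": float(row["p"]),
                }
                for name, row in fit.table.iterrows()
            },
        }
    except ValueError as exc:
        t1["logistic"] = {"error": str(exc)}
    with open(paths["table1"], "w", encoding="utf-8") as fh:
        json.dump(t1, fh, indent=1)

    fractions = simulate_cell_fractions(groups, seed=seed)
    from .clinstats import anova_tukey

    rows = []
    for cell in fractions.columns:
        try:
            F, p, tukey = anova_tukey(fractions, cell, groups)
        except ValueError:
            continue
        rows.append({
            "cell_type": cell, "F": F, "p_anova": p,
            **{f"tukey_{a}_vs_{b}": v for (a, b), v in tukey.items()},
        })
    pd.DataFrame(rows).set_index("cell_type").to_csv(paths["cellcomp"], sep="\t")

    return paths
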