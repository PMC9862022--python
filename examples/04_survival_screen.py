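"""Tertile Kaplan-Meier / log-rank survival screen.

Splits patients into lowest / middle / highest expression thirds per
gene, tests top vs bottom tertile survival by log-rank and reads the
five-year survival fraction of each extreme tertile off its
Kaplan-Meier curve.  The planted hazard gene should dominate the screen.
"""

import warnings

import brcaprog as bp

warnings.simplefilter("ignore")

expr, clinical, truth = bp.simulate_cohort(bp.CohortConfig(n_genes=300), seed=3)

genes = ["PPG_OVER00", "PPG_UNDER00"] + [
    g for g in expr.genes if g.startswith("BG")
][:48]
screen = bp.gene_survival_screen(expr, clinical, genes)

print(screen.head(5).round(4).to_string())
row = screen.loc["PPG_OVER00"]
print(
    f"\nplanted risk gene PPG_OVER00: 5-year survival "
    f"{row['s5_high']:.2f} (high tertile) vs {row['s5_low']:.2f} (low), "
    f"log-rank p = {row['p']:.2e}"
)
# High expression of the planted positive-coefficient gene carries a
# higher hazard, so its top tertile survives markedly worse -- the same
# pattern the screen is designed to surface in real cohorts.
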