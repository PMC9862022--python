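"""Clinical statistics: contingency tests, prognosis regression, cell
fractions.

Covers the demographic/staging comparison of the two prognosis groups
(two-sided Fisher exact tests on 2x2 tables, Welch t from summary
statistics), binomial logistic regression for independent prognosis
factors, one-way ANOVA with Tukey HSD post-tests for immune-cell fraction
tables, and Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import t_from_summary

STAGE_POOL = {"I": ("I", "IA", "IB"), "II": ("II", "IIA", "IIB"),
              "III": ("III", "IIIA", "IIIB", "IIIC"), "IV": ("IV",)}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups (GP, PP), columns = in-category / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of every table with the observed margins whose
    probability does not exceed that of the observed table.  A zero
    margin makes the table untestable and returns p = 1 with a warning.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin: Fisher test is degenerate, p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _pool_stage(stage: str) -> str | None:
    s = str(stage).strip().upper().removeprefix("STAGE").strip()
    for pooled, members in STAGE_POOL.items():
        if s in members:
            return pooled
    return None


def table_one(
    clinical: pd.DataFrame,
    groups: pd.Series,
    *,
    subtypes: pd.Series | None = None,
) -> dict:
    """GP-vs-PP clinical comparison in the style of a cohort Table 1.

    Age is compared by Welch t test; stage (pooled over sub-stages),
    subtype and race categories by two-sided Fisher exact tests of each
    category against the rest.  Returns a nested dict (JSON-serializable).
    """
    gp = groups.index[groups == "GP"]
    pp = groups.index[groups == "PP"]
    gp = [s for s in gp if s in clinical.index]
    pp = [s for s in pp if s in clinical.index]
    n_gp, n_pp = len(gp), len(pp)
    out: dict = {"n": {"GP": n_gp, "PP": n_pp}}

    age_gp = clinical.loc[gp, "age"].astype(float)
    age_pp = clinical.loc[pp, "age"].astype(float)
    t, df, p = t_from_summary(
        age_gp.mean(), age_gp.std(ddof=1), n_gp,
        age_pp.mean(), age_pp.std(ddof=1), n_pp,
    )
    out["age"] = {
        "mean_gp": float(age_gp.mean()), "sd_gp": float(age_gp.std(ddof=1)),
        "mean_pp": float(age_pp.mean()), "sd_pp": float(age_pp.std(ddof=1)),
        "t": t, "df": df, "p": p, "test": "t",
    }

    def fisher_rows(labels_gp: pd.Series, labels_pp: pd.Series, cats) -> dict:
        rows = {}
        for cat in cats:
            a = int((labels_gp == cat).sum())
            c = int((labels_pp == cat).sum())
            tbl = ContingencyTable2x2(a, n_gp - a, c, n_pp - c)
            rows[str(cat)] = {
                "gp": a, "pp": c, "p": fisher_exact(tbl), "test": "fisher",
            }
        return rows

    stage_gp = clinical.loc[gp, "stage"].map(_pool_stage)
    stage_pp = clinical.loc[pp, "stage"].map(_pool_stage)
    out["stage"] = fisher_rows(stage_gp, stage_pp, ("I", "II", "III", "IV"))

    race_gp = clinical.loc[gp, "race"]
    race_pp = clinical.loc[pp, "race"]
    cats = sorted(set(race_gp.dropna()) | set(race_pp.dropna()))
    out["race"] = fisher_rows(race_gp, race_pp, cats)

    if subtypes is not None:
        sub_gp = subtypes.reindex(gp)
        sub_pp = subtypes.reindex(pp)
        from .receptor_subtyping import SUBTYPES

        out["subtype"] = fisher_rows(sub_gp, sub_pp, SUBTYPES)
    return out


@dataclass
class LogisticFit:
    """Per-predictor Wald summaries of a binomial logistic regression."""

    table: pd.DataFrame  # coef, se, or_, ci_low, ci_high, p per predictor
    converged: bool
    n: int
    n_events: int


def _design_matrix(clinical: pd.DataFrame, samples, predictors) -> pd.DataFrame:
    X = pd.DataFrame(index=pd.Index(samples))
    sub = clinical.loc[samples]
    for pred in predictors:
        if pred == "age":
            med = sub["age"].median()
            X[f"age_gt_{med:g}"] = (sub["age"] > med).astype(float)
        elif pred == "stage":
            late = sub["stage"].map(_pool_stage).isin(["III", "IV"])
            X["stage_late"] = late.astype(float)
        elif pred == "sex":
            if "sex" not in sub.columns:
                continue
            lv = sub["sex"].astype(str)
            ref = lv.mode().iloc[0]
            for cat in sorted(set(lv) - {ref}):
                X[f"sex_{cat}"] = (lv == cat).astype(float)
        elif pred == "race":
            lv = sub["race"].astype(str)
            ref = lv.mode().iloc[0]
            for cat in sorted(set(lv) - {ref}):
                X[f"race_{cat}"] = (lv == cat).astype(float)
        else:
            X[pred] = pd.to_numeric(sub[pred])
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant predictors dropped: {dropped}", stacklevel=3)
    return X[keep]


def logistic_prognosis(
    clinical: pd.DataFrame,
    groups: pd.Series,
    predictors=("age", "stage", "sex", "race"),
) -> LogisticFit:
    """Binomial logistic regression of PP (vs GP) on clinical factors.

    Default predictors: age dichotomized at the tumor-cohort median,
    stage dichotomized early (I-II) / late (III-IV), and sex/race
    indicator contrasts against the most frequent level.  Fitted by
    maximum likelihood (IRLS); on perfect separation a lightly
    ridge-penalized fit is substituted, flagged as non-converged, with
    Wald quantities unavailable.
    """
    import statsmodels.api as sm

    samples = [
        s for s in groups.index if groups[s] in ("GP", "PP") and s in clinical.index
    ]
    y = pd.Series([1.0 if groups[s] == "PP" else 0.0 for s in samples],
                  index=samples)
    if int(y.sum()) < 10:
        raise ValueError("need at least 10 events (PP samples)")
    X = _design_matrix(clinical, samples, predictors)
    Xc = sm.add_constant(X, has_constant="add")

    model = sm.Logit(y, Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        coefs, ses, ps = res.params, res.bse, res.pvalues
    except Exception:
        warnings.warn(
            "separation or non-convergence; ridge-penalized fallback used",
            stacklevel=2,
        )
        res = model.fit_regularized(
            method="l1", alpha=1e-4, disp=0, trim_mode="off"
        )
        converged = False
        coefs = res.params
        ses = pd.Series(np.nan, index=coefs.index)
        ps = pd.Series(np.nan, index=coefs.index)

    zcrit = stats.norm.ppf(0.975)
    rows = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "or_": np.exp(coefs),
            "ci_low": np.exp(coefs - zcrit * ses),
            "ci_high": np.exp(coefs + zcrit * ses),
            "p": ps,
        }
    ).drop(index="const")
    return LogisticFit(
        table=rows, converged=converged, n=len(samples), n_events=int(y.sum())
    )


LM22_CELL_TYPES = [
    "B cells naive", "B cells memory", "Plasma cells", "T cells CD8",
    "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta", "NK cells resting",
    "NK cells activated", "Monocytes", "Macrophages M0", "Macrophages M1",
    "Macrophages M2", "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated", "Eosinophils", "Neutrophils",
]


def anova_tukey(
    fractions: pd.DataFrame,
    cell_type: str,
    groups: pd.Series,
    group_order=("Normal", "GP", "PP"),
):
    """One-way ANOVA across sample groups with Tukey HSD post-tests.

    ``fractions`` is a samples x cell-types table (CIBERSORTx-style).
    Returns ``(F, p_anova, tukey)`` where ``tukey`` maps each group pair
    to its studentized-range adjusted p-value.
    """
    if cell_type not in fractions.columns:
        raise KeyError(f"cell type {cell_type!r} absent from fraction table")
    data, labels = [], []
    for g in group_order:
        members = [s for s in groups.index[groups == g] if s in fractions.index]
        vals = fractions.loc[members, cell_type].to_numpy(dtype=float)
        if vals.size >= 2:
            data.append(vals)
            labels.append(g)
    if len(data) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    if all(np.ptp(v) == 0 for v in data):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*data)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    flat = np.concatenate(data)
    grp = np.concatenate([[lab] * len(v) for lab, v in zip(labels, data)])
    hsd = pairwise_tukeyhsd(flat, grp)
    tukey = {}
    for row in hsd.summary().data[1:]:
        g1, g2, _, padj = row[0], row[1], row[2], row[3]
        tukey[(str(g1), str(g2))] = float(padj)
    return float(F), float(p), tukey


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
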