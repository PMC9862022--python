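"""Differential expression, gene-set selection and 2-component PCA.

Per-gene Welch t tests between two sample groups on log2(x+1) expression,
Benjamini–Hochberg FDR adjustment, and a volcano classification: a gene is
*over*-expressed when its linear fold change is at least 2 and the
adjusted p-value below 0.05, *under*-expressed when the fold change is at
most 0.5 at the same significance, otherwise *ns*.  Genes significant in
the poor-prognosis (PP) vs normal contrast but not in the good-prognosis
(GP) vs normal contrast form the PP-specific signature (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import ExpressionMatrix

#: pseudocount on linear-scale group means before the fold-change ratio
FC_EPS = 1e-3

#: volcano thresholds: linear fold change 2 (over) / 0.5 (under), q < 0.05
FC_OVER = 2.0
FC_UNDER = 0.5
Q_THRESHOLD = 0.05


def welch_t(a, b):
    """Welch unequal-variance t test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p-value.  When both groups have zero variance and equal
    means the test is degenerate and ``(0, df, 1)`` is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.inf if b.mean() < a.mean() else -np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch t test from summary statistics (mean, SD, n per group)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _volcano_class(log2fc: np.ndarray, q: np.ndarray) -> np.ndarray:
    cls = np.full(log2fc.shape, "ns", dtype=object)
    sig = q < Q_THRESHOLD
    cls[sig & (log2fc >= np.log2(FC_OVER))] = "over"
    cls[sig & (log2fc <= np.log2(FC_UNDER))] = "under"
    return cls


def differential_expression(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    *,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-gene Welch t tests of group B against group A.

    Tests run on ``log2(x+1)`` values by default (``scale="linear"`` tests
    raw abundances); the fold change is always the ratio of linear-scale
    group means (B over A) with a small pseudocount.  Genes constant across
    all tested samples get ``t=0, p=1`` and class ``ns``.  Returns a frame
    indexed by gene with columns t, df, p, q, log2fc, volcano_class.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    missing = [s for s in group_a + group_b if s not in expr.values.columns]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing}")

    lin_a = expr.values[group_a].to_numpy(dtype=float)
    lin_b = expr.values[group_b].to_numpy(dtype=float)
    if scale == "log2":
        xa, xb = np.log2(lin_a + 1), np.log2(lin_b + 1)
    elif scale == "linear":
        xa, xb = lin_a, lin_b
    else:
        raise ValueError(f"unknown scale: {scale!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        t = np.array(res.statistic, dtype=float, copy=True)
        p = np.array(res.pvalue, dtype=float, copy=True)
        df = np.array(res.df, dtype=float, copy=True)
    # constant genes: zero variance in both groups -> nan from scipy
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    df[degenerate] = float(len(group_a) + len(group_b) - 2)

    log2fc = np.log2(
        (lin_b.mean(axis=1) + FC_EPS) / (lin_a.mean(axis=1) + FC_EPS)
    )
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "log2fc": log2fc,
            "volcano_class": _volcano_class(log2fc, q),
        },
        index=expr.values.index.copy(),
    )


@dataclass(frozen=True)
class GeneSetSelection:
    """Group-specific and shared significant gene sets."""

    pp_only_under: frozenset
    pp_only_over: frozenset
    gp_only_under: frozenset
    gp_only_over: frozenset
    shared_under: frozenset
    shared_over: frozenset

    def pp_signature(self) -> frozenset:
        """Genes dysregulated in PP but not GP (the survival-screen input)."""
        return self.pp_only_under | self.pp_only_over

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: sorted(getattr(self, name))
            for name in (
                "pp_only_under", "pp_only_over", "gp_only_under",
                "gp_only_over", "shared_under", "shared_over",
            )
        }


def select_group_specific(
    de_pp_vs_n: pd.DataFrame, de_gp_vs_n: pd.DataFrame
) -> GeneSetSelection:
    """Set differences of the volcano-significant genes of two contrasts.

    ``pp_only_over`` are genes over-expressed in PP-vs-normal but not in
    GP-vs-normal, etc.; ``shared_*`` are the intersections.
    """
    if not de_pp_vs_n.index.equals(de_gp_vs_n.index):
        if set(de_pp_vs_n.index) != set(de_gp_vs_n.index):
            raise ValueError("gene universes of the two contrasts differ")
        de_gp_vs_n = de_gp_vs_n.reindex(de_pp_vs_n.index)

    def sig(de: pd.DataFrame, cls: str) -> set:
        return set(de.index[de["volcano_class"] == cls])

    pp_over, pp_under = sig(de_pp_vs_n, "over"), sig(de_pp_vs_n, "under")
    gp_over, gp_under = sig(de_gp_vs_n, "over"), sig(de_gp_vs_n, "under")
    return GeneSetSelection(
        pp_only_under=frozenset(pp_under - gp_under),
        pp_only_over=frozenset(pp_over - gp_over),
        gp_only_under=frozenset(gp_under - pp_under),
        gp_only_over=frozenset(gp_over - pp_over),
        shared_under=frozenset(pp_under & gp_under),
        shared_over=frozenset(pp_over & gp_over),
    )


def pca2(
    expr: ExpressionMatrix,
    genes,
    *,
    standardize: bool = True,
    samples=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-component PCA of samples in the space of the given genes.

    Works on column-centered (and, by default, per-gene standardized)
    log2(x+1) expression; scores come from the top-2 right singular
    directions with a deterministic sign convention (the largest-magnitude
    gene loading of each component is positive).  Returns (scores frame
    with columns PC1/PC2, fraction of variance explained per component).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if samples is None:
        samples = expr.samples
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    X = np.log2(expr.values.loc[genes, samples].to_numpy(dtype=float).T + 1)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("matrix has no variance")
    scores = np.zeros((X.shape[0], 2))
    explained = np.zeros(2)
    ncomp = min(2, s.size)
    for j in range(ncomp):
        sign = np.sign(Vt[j, np.argmax(np.abs(Vt[j]))]) or 1.0
        scores[:, j] = sign * U[:, j] * s[j]
        explained[j] = s[j] ** 2 / total
    if ncomp < 2 or np.isclose(s[1], 0):
        import warnings

        warnings.warn("rank < 2: second component has zero variance", stacklevel=2)
    return (
        pd.DataFrame(scores, index=pd.Index(samples, name="sample"),
                     columns=["PC1", "PC2"]),
        explained,
    )
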