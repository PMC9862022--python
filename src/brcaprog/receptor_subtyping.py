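"""Receptor positivity thresholds and surrogate intrinsic subtypes.

Hormone-receptor and HER2 status are read off the transcriptome: the
log10 expression of *ESR1* (ER), *PGR* (PR) and *ERBB2* (HER2) in tumor
samples is bimodal, with the lower mode the receptor-negative population
and the upper mode the receptor-positive one.  A two-component Gaussian
mixture is fitted by expectation–maximisation and the point between the
two means where the weighted component densities are equal is the
positivity threshold.  Samples are then called +/- per receptor and
combined into the clinical surrogate subtypes (Luminal A, Luminal B,
HER2 enriched, Triple Negative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cohort import ExpressionMatrix

RECEPTOR_GENES = {"er": "ESR1", "pr": "PGR", "her2": "ERBB2"}

#: pseudocount admitting zeros under the log10 transform
LOG_EPS = 1e-3

SUBTYPES = ("Luminal A", "Luminal B", "HER2 enriched", "Triple Negative")


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    variance_floored: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def k(self) -> int:
        return len(self.means)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        z = (x - self.means) / self.sds
        comp = self.weights * np.exp(-0.5 * z**2) / (self.sds * math.sqrt(2 * math.pi))
        return comp.sum(axis=-1)


@dataclass
class ReceptorThreshold:
    gene: str
    threshold: float  # log10 expression units
    fit: MixtureFit
    in_interval: bool = True


def _em_run(
    x: np.ndarray, resp: np.ndarray, tol: float, max_iter: int, var_floor: float
) -> MixtureFit:
    n = x.size
    loglik_prev = -np.inf
    floored = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        if (var < var_floor).any():
            floored = True
            var = np.maximum(var, var_floor)
        sd = np.sqrt(var)
        # E step / log-likelihood
        z = (x[:, None] - mu) / sd
        logcomp = (
            np.log(w) - np.log(sd) - 0.5 * math.log(2 * math.pi) - 0.5 * z**2
        )
        m = logcomp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logcomp - m).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logcomp - lse[:, None])
        if loglik < loglik_prev - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased ({loglik_prev} -> {loglik})"
            )
        if loglik - loglik_prev < tol:
            converged = True
            loglik_prev = loglik
            break
        loglik_prev = loglik
    order = np.argsort(mu)
    return MixtureFit(
        weights=w[order],
        means=mu[order],
        sds=sd[order],
        loglik=loglik_prev,
        n_iter=it,
        converged=converged,
        variance_floored=floored,
    )


def fit_gmm1d(
    values,
    k: int = 2,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 1,
    var_floor: float = 1e-6,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture to 1-D data by EM.

    Initial responsibilities come from a median split (values below the
    median to the low component); additional random-responsibility
    restarts are drawn from ``seed`` and the best log-likelihood wins.
    The log-likelihood is asserted non-decreasing across iterations, and
    component variances are floored at ``var_floor`` (flagged on the fit).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite values, got {x.size}")
    if np.var(x) <= 0:
        raise ValueError("degenerate input: zero sample variance")
    if k == 1:
        mu, sd = float(np.mean(x)), float(np.std(x))
        z = (x - mu) / sd
        ll = float(
            (-np.log(sd) - 0.5 * math.log(2 * math.pi) - 0.5 * z**2).sum()
        )
        return MixtureFit(
            weights=np.array([1.0]), means=np.array([mu]), sds=np.array([sd]),
            loglik=ll, n_iter=0, converged=True,
        )
    if k != 2:
        raise ValueError("only k in (1, 2) is supported")

    # median-split initial responsibilities
    resp0 = np.zeros((x.size, 2))
    low = x <= np.median(x)
    resp0[low, 0] = 1.0
    resp0[~low, 1] = 1.0
    fits = [_em_run(x, resp0, tol, max_iter, var_floor)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            r = rng.uniform(size=x.size)
            resp = np.column_stack([r, 1 - r])
            fits.append(_em_run(x, resp, tol, max_iter, var_floor))
    return max(fits, key=lambda f: f.loglik)


def gaussian_intersection(fit: MixtureFit) -> tuple[float, bool]:
    """Expression threshold where the two weighted Gaussian densities meet.

    Solves ``w1 N(x; mu1, s1) = w2 N(x; mu2, s2)``; with unequal SDs this
    is a quadratic in x and the root between the two means is returned.
    With equal SDs the closed linear form applies.  If no root falls in
    ``(mu1, mu2)`` the root nearest the interval is returned and the
    result flagged (``in_interval=False``).
    """
    if fit.k != 2:
        raise ValueError("intersection requires a 2-component fit")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if m1 == m2:
        raise ValueError("component means coincide; no boundary exists")

    if np.isclose(s1, s2):
        s = 0.5 * (s1 + s2)
        x = 0.5 * (m1 + m2) + s**2 * math.log(w1 / w2) / (m2 - m1)
        roots = np.array([x])
    else:
        a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = (
            m2**2 / (2 * s2**2)
            - m1**2 / (2 * s1**2)
            + math.log((w1 * s2) / (w2 * s1))
        )
        roots = np.roots([a, b, c])
        roots = np.real(roots[np.isreal(roots)])
        if roots.size == 0:
            raise ValueError("no real intersection between components")

    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size:
        return float(inside[0]), True
    nearest = roots[np.argmin(np.minimum(np.abs(roots - m1), np.abs(roots - m2)))]
    warnings.warn(
        "no density intersection between the component means; returning the "
        "nearest root",
        stacklevel=2,
    )
    return float(nearest), False


def fit_receptor_thresholds(
    expr: ExpressionMatrix,
    genes=("ESR1", "PGR", "ERBB2"),
    *,
    tumor_only: bool = True,
    eps: float = LOG_EPS,
    seed: int | None = 0,
) -> dict[str, ReceptorThreshold]:
    """Fit per-receptor mixtures on log10 tumor expression and derive
    positivity thresholds."""
    samples = expr.tumor_samples() if tumor_only and len(expr.sample_group) else expr.samples
    out = {}
    for gene in genes:
        if gene not in expr.values.index:
            raise KeyError(f"receptor gene {gene!r} absent from matrix")
        vals = np.log10(expr.values.loc[gene, samples].to_numpy(dtype=float) + eps)
        fit = fit_gmm1d(vals, k=2, seed=seed)
        thr, inside = gaussian_intersection(fit)
        out[gene] = ReceptorThreshold(gene=gene, threshold=thr, fit=fit, in_interval=inside)
    return out


def call_receptors(
    expr: ExpressionMatrix,
    thresholds: dict[str, ReceptorThreshold],
    *,
    samples=None,
    eps: float = LOG_EPS,
) -> pd.DataFrame:
    """Call +/- per sample and receptor gene.

    A sample is positive iff ``log10(value + eps)`` strictly exceeds the
    threshold; a value exactly at the threshold is negative.
    """
    if samples is None:
        samples = expr.samples
    out = {}
    for gene, thr in thresholds.items():
        if gene not in expr.values.index:
            raise KeyError(f"receptor gene {gene!r} absent from matrix")
        logv = np.log10(expr.values.loc[gene, samples].to_numpy(dtype=float) + eps)
        out[gene] = np.where(logv > thr.threshold, "+", "-")
    return pd.DataFrame(out, index=pd.Index(samples, name="sample"))


def receptor_crosstab(status: pd.DataFrame, gene_a: str, gene_b: str) -> pd.DataFrame:
    """Percent of samples in each +/- combination of two receptors."""
    tab = pd.crosstab(status[gene_a], status[gene_b])
    tab = tab.reindex(index=["+", "-"], columns=["+", "-"], fill_value=0)
    return 100.0 * tab / len(status)


def assign_subtype(er: str, pr: str, her2: str) -> str:
    """Surrogate intrinsic subtype from the three receptor statuses.

    Luminal A: (ER+ and/or PR+) and HER2-; Luminal B: (ER+ and/or PR+)
    and HER2+; HER2 enriched: ER-, PR-, HER2+; Triple Negative: all
    negative.
    """
    def _pos(v) -> bool:
        if isinstance(v, str):
            return v == "+"
        return bool(v)

    hormone = _pos(er) or _pos(pr)
    if hormone:
        return "Luminal B" if _pos(her2) else "Luminal A"
    return "HER2 enriched" if _pos(her2) else "Triple Negative"


def subtype_calls(status: pd.DataFrame) -> pd.DataFrame:
    """Per-sample receptor statuses plus the derived subtype.

    ``status`` columns are the receptor gene symbols (ESR1, PGR, ERBB2).
    """
    er, pr, her2 = (status[RECEPTOR_GENES[k]] for k in ("er", "pr", "her2"))
    subtype = [assign_subtype(e, p, h) for e, p, h in zip(er, pr, her2)]
    return pd.DataFrame(
        {"ER": er, "PR": pr, "HER2": her2, "subtype": subtype}, index=status.index
    )
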