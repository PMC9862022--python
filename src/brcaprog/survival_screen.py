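"""Kaplan–Meier estimation, log-rank testing and tertile survival screens.

The screen ranks genes by how strongly expression stratifies overall
survival: patients are split into lowest/middle/highest expression thirds
and the top third is compared with the bottom third by a two-group
log-rank test, reporting the chi-square p-value and the five-year survival
fraction of each extreme tertile from the product-limit (Kaplan–Meier)
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import ExpressionMatrix


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct observed times in ascending order;
    ``survival[i]`` is S(t) just after ``times[i]`` (right-continuous
    step function, S(0) = 1).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)

    @property
    def n(self) -> int:
        return int(self.at_risk[0]) if len(self.at_risk) else 0


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimator under right censoring.

    At tied times deaths are processed before censorings (both count in
    the risk set at that time; censored subjects leave afterwards).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")

    uniq = np.unique(t)
    d = np.array([(e & (t == u)).sum() for u in uniq])
    c = np.array([(~e & (t == u)).sum() for u in uniq])
    n_at_risk = np.empty_like(d)
    alive = t.size
    for i in range(uniq.size):
        n_at_risk[i] = alive
        alive -= d[i] + c[i]
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(times=uniq, survival=surv, at_risk=n_at_risk, events=d, censored=c)


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t).

    At an event time the post-jump value applies; beyond the last observed
    time the last value is carried forward with a warning.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > curve.times[-1]:
        warnings.warn(
            f"t={t} beyond last observed time {curve.times[-1]}; "
            "extrapolating the last value",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    p: float
    df: int = 1
    observed: np.ndarray = field(default_factory=lambda: np.zeros(2))
    expected: np.ndarray = field(default_factory=lambda: np.zeros(2))
    degenerate: bool = False


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time the observed group-A deaths are compared
    with the expectation under the null of a common hazard, with the
    hypergeometric variance; the chi-square statistic has one degree of
    freedom.  With no events at all the test is degenerate and (0, 1)
    is returned with a flag.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])

    event_times = np.unique(t_all[e_all])
    o1 = e1 = v = 0.0
    obs = np.array([ea.sum(), eb.sum()], dtype=float)
    exp = np.zeros(2)
    for u in event_times:
        at_risk = t_all >= u
        n = at_risk.sum()
        n1 = (at_risk & ~grp).sum()
        d = (e_all & (t_all == u)).sum()
        d1 = (e_all & (t_all == u) & ~grp).sum()
        e1_u = d * n1 / n
        o1 += d1
        e1 += e1_u
        exp[0] += e1_u
        exp[1] += d - e1_u
        if n > 1:
            v += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if v == 0:
        return LogrankResult(
            chi2=0.0, p=1.0, observed=obs, expected=exp, degenerate=True
        )
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)),
        observed=obs,
        expected=exp,
    )


def tertile_stratify(values: pd.Series) -> pd.Series:
    """Rank-split samples into low / mid / high expression thirds.

    Group sizes are as equal as possible; when n is not divisible by 3
    the spare slots go to the lower tertiles first (n=10 -> 4/3/3).
    Ties are broken deterministically by position in the input order; a
    tie spanning a tertile boundary still splits by rank, with a warning.
    """
    v = pd.Series(values)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 samples")
    order = np.argsort(v.to_numpy(), kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (rem > 0), base + (rem > 1), base]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, ("low", "mid", "high")):
        labels[order[start:start + size]] = name
        start += size
    arr = v.to_numpy()
    lo_max = arr[order[sizes[0] - 1]]
    mid_lo = arr[order[sizes[0]]]
    mid_hi = arr[order[sizes[0] + sizes[1] - 1]]
    hi_min = arr[order[sizes[0] + sizes[1]]]
    if lo_max == mid_lo or mid_hi == hi_min:
        warnings.warn(
            "ties span a tertile boundary; split is by stable rank order",
            stacklevel=2,
        )
    return pd.Series(labels, index=v.index, name="tertile")


def gene_survival_screen(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    genes,
    *,
    horizon: float = 5.0,
    add_bh: bool = True,
) -> pd.DataFrame:
    """Tertile log-rank screen over a gene list.

    For each gene, tumor samples with survival data are stratified into
    expression tertiles; the top third is tested against the bottom third
    by log-rank and the five-year survival fraction of each extreme
    tertile is read off its Kaplan–Meier curve.  Rows are sorted by
    p-value; a BH-adjusted column is appended by default (the raw p is
    the screening statistic).
    """
    tumor = [
        s
        for s in expr.samples
        if str(clinical.loc[s, "tissue_type"]).lower() != "normal"
        and pd.notna(clinical.loc[s, "time_years"])
        and pd.notna(clinical.loc[s, "vital_status"])
    ]
    times = clinical.loc[tumor, "time_years"].to_numpy(dtype=float)
    events = (
        clinical.loc[tumor, "vital_status"].astype(str).str.lower() == "dead"
    ).to_numpy()

    rows = []
    for gene in genes:
        if gene not in expr.values.index:
            warnings.warn(f"gene {gene!r} absent from matrix; skipped", stacklevel=2)
            continue
        tert = tertile_stratify(expr.values.loc[gene, tumor])
        lo = (tert == "low").to_numpy()
        hi = (tert == "high").to_numpy()
        res = logrank(times[hi], events[hi], times[lo], events[lo])
        s5_hi = survival_at(km_estimate(times[hi], events[hi]), horizon)
        s5_lo = survival_at(km_estimate(times[lo], events[lo]), horizon)
        rows.append(
            {
                "gene": gene,
                "n_low": int(lo.sum()),
                "n_high": int(hi.sum()),
                "chi2": res.chi2,
                "p": res.p,
                "s5_low": s5_lo,
                "s5_high": s5_hi,
            }
        )
    if not rows:
        raise ValueError("no screened gene was present in the matrix")
    out = pd.DataFrame(rows).set_index("gene")
    if add_bh:
        from .diffexp import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable")
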