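"""Synthetic breast-cancer cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes in
a real tumor transcriptome cohort: three sample arms (normal tissue, a
good-prognosis tumor arm and a poor-prognosis tumor arm, default sizes
105 / 200 / 101), log10-normal expression per gene, bimodal receptor
genes (*ESR1*, *PGR*, *ERBB2*) whose positive-component weights match
the positivity rates the analysis expects to recover, planted
differentially-expressed gene sets specific to each tumor arm or shared,
exponential proportional-hazards survival whose log-hazard is linear in
the standardized log expression of chosen genes, independent exponential
censoring truncated at a follow-up horizon, and Table-1-like age / stage
/ race covariates.

Final GP/PP labels are re-derived from the simulated outcomes with the
same five-year rule the real pipeline applies, so the labels the
downstream stages see are consistent with the survival data; the
intended arm of every tumor sample is kept in the returned ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_cohort import ExpressionMatrix, classify_prognosis

LOG10_2 = float(np.log10(2.0))

#: two (mean, sd, weight) log10-scale components per receptor gene; the
#: positive-component weights mirror typical ER/PR/HER2 positivity rates
DEFAULT_RECEPTOR_SPEC = {
    "ESR1": ((0.5, 0.4, 0.2658), (2.5, 0.5, 0.7342)),
    "PGR": ((0.3, 0.5, 0.4220), (2.2, 0.5, 0.5780)),
    "ERBB2": ((2.0, 0.3, 0.8904), (3.3, 0.35, 0.1096)),
}

# covariate distributions per arm, shaped like a typical cohort table
DEFAULT_AGE = {
    "Normal": (58.2, 14.0), "GP": (54.3, 11.7), "PP": (63.7, 14.5),
}
AGE_RANGE = (27.0, 90.0)

DEFAULT_STAGE_PROBS = {
    "GP": {
        "I": 0.18, "IA": 0.055, "IB": 0.01, "II": 0.01, "IIA": 0.305,
        "IIB": 0.23, "III": 0.0, "IIIA": 0.16, "IIIB": 0.02, "IIIC": 0.02,
        "IV": 0.01,
    },
    "PP": {
        "I": 0.07, "IA": 0.02, "IB": 0.0, "II": 0.0, "IIA": 0.225,
        "IIB": 0.185, "III": 0.02, "IIIA": 0.195, "IIIB": 0.08, "IIIC": 0.07,
        "IV": 0.135,
    },
}

DEFAULT_RACE_PROBS = {
    "Normal": {"Caucasian": 0.933, "African": 0.048, "Asian": 0.010,
               "Other": 0.009},
    "GP": {"Caucasian": 0.80, "African": 0.15, "Asian": 0.035, "Other": 0.015},
    "PP": {"Caucasian": 0.743, "African": 0.178, "Asian": 0.030,
           "Other": 0.049},
}


@dataclass
class DESpec:
    """Planted log2 effect sizes, per gene, for each tumor arm.

    Positive effects are over-expression in the tumor arm relative to
    normal tissue; ``shared`` effects apply to both arms.  The three
    gene sets must be disjoint.
    """

    pp_only: dict[str, float] = field(default_factory=dict)
    gp_only: dict[str, float] = field(default_factory=dict)
    shared: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        sets = [set(self.pp_only), set(self.gp_only), set(self.shared)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"DE gene sets overlap: {sorted(overlap)}")

    def all_genes(self) -> set[str]:
        return set(self.pp_only) | set(self.gp_only) | set(self.shared)


def default_de_spec(n_per_set: int = 10, effect: float = 2.0) -> DESpec:
    """Symmetric default: n over- and n under-expressed genes per set."""

    def block(prefix: str) -> dict[str, float]:
        d = {f"{prefix}_OVER{i:02d}": effect for i in range(n_per_set)}
        d.update({f"{prefix}_UNDER{i:02d}": -effect for i in range(n_per_set)})
        return d

    return DESpec(pp_only=block("PPG"), gp_only=block("GPG"), shared=block("SHG"))


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the cohort the analysis targets."""

    n_normal: int = 105
    n_gp: int = 200
    n_pp: int = 101
    n_genes: int = 2000
    receptor_spec: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_RECEPTOR_SPEC.items()}
    )
    de_spec: DESpec = field(default_factory=default_de_spec)
    #: (gene, log-hazard coefficient per SD of log10 expression)
    hazard_spec: list = field(
        default_factory=lambda: [("PPG_OVER00", 1.1), ("PPG_UNDER00", -1.1)]
    )
    baseline_hazard: float = 0.08  # deaths per year at average expression
    censor_rate: float = 0.03  # losses to follow-up per year
    followup_horizon: float = 10.0  # years; administrative censoring
    age: dict = field(default_factory=lambda: dict(DEFAULT_AGE))
    stage_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STAGE_PROBS.items()}
    )
    race_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RACE_PROBS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_normal, self.n_gp, self.n_pp, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        for gene, comps in self.receptor_spec.items():
            if len(comps) != 2:
                raise ValueError(f"{gene}: need exactly two components")
            wsum = 0.0
            for mu, sd, w in comps:
                if sd <= 0:
                    raise ValueError(f"{gene}: component SD must be > 0")
                if not 0 < w < 1:
                    raise ValueError(f"{gene}: weights must lie in (0, 1)")
                wsum += w
            if abs(wsum - 1.0) > 1e-8:
                raise ValueError(f"{gene}: component weights must sum to 1")
        self.de_spec.validate()
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("hazard rates must be positive")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        for probs in (*self.stage_probs.values(), *self.race_probs.values()):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError("covariate probabilities must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    thresholds: dict[str, float]  # log10 positivity threshold per receptor
    de_sets: DESpec
    arm: pd.Series  # intended arm per sample (Normal / GP / PP)
    receptor_positive: pd.DataFrame  # bool, tumor samples x receptor genes
    subtype: pd.Series  # true subtype per tumor sample
    hazard_coefs: dict[str, float]

    def to_json(self, path: str) -> None:
        payload = {
            "thresholds": self.thresholds,
            "de_sets": asdict(self.de_sets),
            "arm": {str(k): str(v) for k, v in self.arm.items()},
            "receptor_positive": {
                g: self.receptor_positive[g].astype(bool).tolist()
                for g in self.receptor_positive.columns
            },
            "receptor_samples": [str(s) for s in self.receptor_positive.index],
            "subtype": {str(k): str(v) for k, v in self.subtype.items()},
            "hazard_coefs": dict(self.hazard_coefs),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def true_threshold(comp_neg, comp_pos) -> float:
    """Numeric root of the weighted density difference between components.

    Independent of the analytic intersection used by the fitting code:
    bisection (Brent) on ``w1 N(x; m1, s1) - w2 N(x; m2, s2)`` over the
    open interval between the two means.
    """
    (m1, s1, w1), (m2, s2, w2) = comp_neg, comp_pos
    if m1 >= m2:
        raise ValueError("negative component mean must lie below positive")

    def diff(x: float) -> float:
        return w1 * stats.norm.pdf(x, m1, s1) - w2 * stats.norm.pdf(x, m2, s2)

    lo, hi = m1 + 1e-9, m2 - 1e-9
    if diff(lo) * diff(hi) > 0:  # no sign change: fall back to midpoint
        return 0.5 * (m1 + m2)
    return float(optimize.brentq(diff, lo, hi, xtol=1e-12))


def _categorical(rng, probs: dict[str, float], size: int) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=size, p=p)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic cohort.

    Returns the expression matrix (linear scale, genes x samples, group
    labels re-derived from outcomes), the clinical table and the ground
    truth.  Deterministic given the seed (``seed`` overrides
    ``config.seed``).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_norm, n_gp, n_pp = config.n_normal, config.n_gp, config.n_pp
    n_tumor = n_gp + n_pp
    samples = (
        [f"N{i:04d}" for i in range(n_norm)]
        + [f"T{i:04d}" for i in range(n_tumor)]
    )
    arm = pd.Series(
        ["Normal"] * n_norm + ["GP"] * n_gp + ["PP"] * n_pp,
        index=samples, name="arm",
    )
    is_tumor = np.array([a != "Normal" for a in arm])
    gp_arm = np.array([a == "GP" for a in arm])
    pp_arm = np.array([a == "PP" for a in arm])

    receptor_genes = list(config.receptor_spec)
    planted = sorted(config.de_spec.all_genes())
    n_background = config.n_genes - len(receptor_genes) - len(planted)
    if n_background < 0:
        raise ValueError("n_genes too small for receptors plus planted sets")
    background = [f"BG{i:05d}" for i in range(n_background)]
    genes = receptor_genes + planted + background
    n_samples = len(samples)

    # background/planted genes: per-gene log10-normal baseline
    base_mean = rng.normal(1.5, 0.8, size=len(genes))
    base_sd = rng.uniform(0.2, 0.6, size=len(genes))
    log10x = base_mean[:, None] + base_sd[:, None] * rng.standard_normal(
        (len(genes), n_samples)
    )

    # receptor genes: two-component mixture in tumors, negative component
    # in normal tissue
    thresholds: dict[str, float] = {}
    positive = {}
    for gi, gene in enumerate(receptor_genes):
        comp_neg, comp_pos = config.receptor_spec[gene]
        thresholds[gene] = true_threshold(comp_neg, comp_pos)
        z = rng.uniform(size=n_samples) < comp_pos[2]
        z[~is_tumor] = False
        mu = np.where(z, comp_pos[0], comp_neg[0])
        sd = np.where(z, comp_pos[1], comp_neg[1])
        log10x[gi] = mu + sd * rng.standard_normal(n_samples)
        positive[gene] = z[is_tumor]
    receptor_positive = pd.DataFrame(
        positive, index=pd.Index(np.array(samples)[is_tumor], name="sample")
    )

    # planted differential expression (log2 effects, applied on log10 scale)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene, eff in config.de_spec.pp_only.items():
        log10x[gene_pos[gene], pp_arm] += eff * LOG10_2
    for gene, eff in config.de_spec.gp_only.items():
        log10x[gene_pos[gene], gp_arm] += eff * LOG10_2
    for gene, eff in config.de_spec.shared.items():
        log10x[gene_pos[gene], is_tumor] += eff * LOG10_2

    values = pd.DataFrame(
        10.0 ** log10x, index=pd.Index(genes, name="gene"), columns=samples
    )

    # survival: exponential proportional hazards on standardized log10
    # expression of the hazard genes, over tumor samples
    eta = np.zeros(is_tumor.sum())
    for gene, coef in config.hazard_spec:
        if gene not in gene_pos:
            raise ValueError(f"hazard gene {gene!r} not in matrix")
        x = log10x[gene_pos[gene], is_tumor]
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta += coef * z
    lam = config.baseline_hazard * np.exp(eta)
    t_death = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=lam.size)
    else:
        t_cens = np.full(lam.size, np.inf)
    t_cens = np.minimum(t_cens, config.followup_horizon)
    time = np.minimum(t_death, t_cens)
    event = t_death <= t_cens

    # clinical covariates per intended arm
    age = np.empty(n_samples)
    stage = np.empty(n_samples, dtype=object)
    race = np.empty(n_samples, dtype=object)
    for a in ("Normal", "GP", "PP"):
        mask = (arm == a).to_numpy()
        mu, sd = config.age[a]
        age[mask] = np.clip(
            rng.normal(mu, sd, size=mask.sum()), *AGE_RANGE
        ).round(0)
        race[mask] = _categorical(rng, config.race_probs[a], mask.sum())
        if a == "Normal":
            stage[mask] = ""
        else:
            stage[mask] = _categorical(rng, config.stage_probs[a], mask.sum())

    time_years = np.zeros(n_samples)
    vital = np.array(["alive"] * n_samples, dtype=object)
    time_years[is_tumor] = time
    vital[is_tumor] = np.where(event, "dead", "alive")
    clinical = pd.DataFrame(
        {
            "age": age,
            "stage": stage,
            "race": race,
            "vital_status": vital,
            "time_years": time_years,
            "tissue_type": np.where(is_tumor, "tumor", "normal"),
        },
        index=pd.Index(samples, name="sample"),
    )

    groups = classify_prognosis(clinical)
    expr = ExpressionMatrix(values=values, sample_group=groups)

    er, pr, her2 = (
        receptor_positive.get(g, pd.Series(False, index=receptor_positive.index))
        for g in ("ESR1", "PGR", "ERBB2")
    )
    from .receptor_subtyping import assign_subtype

    subtype = pd.Series(
        [assign_subtype(e, p, h) for e, p, h in zip(er, pr, her2)],
        index=receptor_positive.index, name="subtype",
    )
    truth = SyntheticTruth(
        thresholds=thresholds,
        de_sets=config.de_spec,
        arm=arm,
        receptor_positive=receptor_positive,
        subtype=subtype,
        hazard_coefs=dict(config.hazard_spec),
    )
    return expr, clinical, truth


def simulate_cell_fractions(
    groups: pd.Series,
    seed: int = 0,
    *,
    pp_depleted=("Macrophages M1", "T cells CD8", "Plasma cells",
                 "Dendritic cells activated"),
    depletion: float = 0.45,
    coupled=("Macrophages M1", "T cells CD8"),
    coupling_sd: float = 0.75,
) -> pd.DataFrame:
    """Dirichlet immune-cell fraction table (LM22-style, rows sum to 1).

    The poor-prognosis group has the ``pp_depleted`` cell types scaled
    down by ``depletion``; the two ``coupled`` cell types share a
    log-normal latent factor so their fractions correlate across samples,
    mimicking co-recruitment.
    """
    from .clinstats import LM22_CELL_TYPES

    rng = np.random.default_rng(seed)
    base = np.full(len(LM22_CELL_TYPES), 2.0)
    idx = {c: i for i, c in enumerate(LM22_CELL_TYPES)}
    rows = []
    for sample in groups.index:
        alpha = base.copy()
        if groups[sample] == "PP":
            for c in pp_depleted:
                alpha[idx[c]] *= depletion
        latent = np.exp(coupling_sd * rng.standard_normal())
        for c in coupled:
            alpha[idx[c]] *= latent
        rows.append(rng.dirichlet(alpha))
    return pd.DataFrame(
        rows, index=groups.index.copy(), columns=LM22_CELL_TYPES
    )
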