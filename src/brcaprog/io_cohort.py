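"""Cohort construction and tabular I/O.

Expression matrices are FPKM-UQ-like normalized abundances, genes as rows
and samples as columns.  The clinical table carries the demographics and
follow-up information needed to split tumor samples into a Good Prognosis
(GP) group — alive with more than ``horizon`` years of follow-up — and a
Poor Prognosis (PP) group — dead before ``horizon`` years.  Tumor samples
whose outcome is indeterminate at the horizon (alive, short follow-up) are
excluded; normal-tissue samples form their own group.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("Normal", "GP", "PP", "Excluded")

#: days per year used when converting GDC-style day counts
DAYS_PER_YEAR = 365.25

CLINICAL_COLUMNS = [
    "age", "stage", "race", "vital_status", "time_years", "tissue_type",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized expression.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample ids as columns.
    sample_group
        Optional per-sample group label (``Normal``/``GP``/``PP``/
        ``Excluded``); empty until a cohort has been classified.
    """

    values: pd.DataFrame
    sample_group: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def samples_in_group(self, *groups: str) -> list[str]:
        sg = self.sample_group
        return [s for s in self.samples if sg.get(s) in groups]

    def tumor_samples(self) -> list[str]:
        return self.samples_in_group("GP", "PP", "Excluded")


def _dedupe_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate gene symbols by keeping the highest-mean row."""
    if not df.index.has_duplicates:
        return df
    dup = df.index[df.index.duplicated()].unique().tolist()
    warnings.warn(
        f"duplicate gene symbols resolved by highest mean expression: {dup}",
        stacklevel=3,
    )
    order = df.mean(axis=1).to_numpy()
    keep = (
        pd.DataFrame({"gene": df.index, "mean": order})
        .reset_index(drop=True)
        .sort_values(["gene", "mean"], kind="stable")
        .groupby("gene", sort=False)
        .tail(1)
        .index
    )
    out = df.iloc[sorted(keep)]
    return out


def read_expression(path: str, layout: str = "matrix") -> ExpressionMatrix:
    """Read an expression matrix from a TSV file or a GDC-style directory.

    ``layout="matrix"``: one TSV, first column named ``gene``, one column
    per sample.  ``layout="gdc"``: a directory of two-column per-sample
    files (gene, value); the file stem is the sample id and every file must
    cover the same gene set.
    """
    if layout == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene"
    elif layout == "gdc":
        columns: dict[str, pd.Series] = {}
        genes_ref: pd.Index | None = None
        for fname in sorted(os.listdir(path)):
            fpath = os.path.join(path, fname)
            if not os.path.isfile(fpath):
                continue
            sample = os.path.splitext(fname)[0]
            if sample in columns:
                raise ValueError(f"duplicate sample id: {sample}")
            col = pd.read_csv(fpath, sep="\t", index_col=0, header=None).iloc[:, 0]
            if genes_ref is None:
                genes_ref = col.index
            else:
                missing = genes_ref.difference(col.index)
                extra = col.index.difference(genes_ref)
                if len(missing) or len(extra):
                    bad = missing.tolist() + extra.tolist()
                    raise ValueError(
                        f"sample {sample!r} gene set mismatch: {bad}"
                    )
            columns[sample] = col.reindex(genes_ref)
        if genes_ref is None:
            raise ValueError(f"no per-sample files found in {path!r}")
        df = pd.DataFrame(columns)
        df.index.name = "gene"
    else:
        raise ValueError(f"unknown layout: {layout!r}")

    df = df.apply(pd.to_numeric, errors="raise")
    df = _dedupe_genes(df)
    return ExpressionMatrix(values=df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    """Write the canonical TSV dialect: tab-separated, UTF-8, '.' decimal,
    no quoting, gene column named ``gene``."""
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_clinical(path: str) -> pd.DataFrame:
    """Read a clinical table (TSV, one row per sample, index = sample id).

    GDC-style ``days_to_death`` / ``days_to_last_follow_up`` columns are
    converted to a single ``time_years`` column when absent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "time_years" not in df.columns:
        days = pd.Series(np.nan, index=df.index)
        if "days_to_death" in df.columns:
            days = days.fillna(pd.to_numeric(df["days_to_death"], errors="coerce"))
        if "days_to_last_follow_up" in df.columns:
            days = days.fillna(
                pd.to_numeric(df["days_to_last_follow_up"], errors="coerce")
            )
        df["time_years"] = days / DAYS_PER_YEAR
    if "tissue_type" not in df.columns:
        df["tissue_type"] = "tumor"
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_clinical(clinical: pd.DataFrame, path: str) -> None:
    df = clinical.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", lineterminator="\n")


def classify_prognosis(
    clinical: pd.DataFrame,
    horizon: float = 5.0,
    deaths_after_horizon: str = "GP",
) -> pd.Series:
    """Assign each sample to Normal / GP / PP / Excluded.

    Tumor samples: dead with ``time < horizon`` -> PP; alive with
    ``time > horizon`` -> GP; alive with ``time <= horizon`` -> Excluded
    (outcome indeterminate).  Deaths at or after the horizon did survive
    past it and default to GP (``deaths_after_horizon`` may be set to
    ``"Excluded"`` instead).  Normal-tissue samples -> Normal.  Missing
    vital status or time -> Excluded with a warning.
    """
    if deaths_after_horizon not in ("GP", "Excluded"):
        raise ValueError("deaths_after_horizon must be 'GP' or 'Excluded'")
    out = {}
    n_missing = 0
    for sample, row in clinical.iterrows():
        if str(row.get("tissue_type", "tumor")).lower() == "normal":
            out[sample] = "Normal"
            continue
        vital = row.get("vital_status")
        time = row.get("time_years")
        if pd.isna(vital) or pd.isna(time):
            out[sample] = "Excluded"
            n_missing += 1
            continue
        vital = str(vital).lower()
        if vital == "dead":
            out[sample] = "PP" if time < horizon else deaths_after_horizon
        else:
            out[sample] = "GP" if time > horizon else "Excluded"
    if n_missing:
        warnings.warn(
            f"{n_missing} tumor sample(s) lacked vital status or follow-up "
            "time and were excluded",
            stacklevel=2,
        )
    return pd.Series(out, name="group")


def cohort_summary(groups: pd.Series) -> dict[str, int]:
    """Counts per group, with every group present."""
    counts = groups.value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def write_cohort(groups: pd.Series, path: str) -> None:
    payload = {
        "counts": cohort_summary(groups),
        "groups": {str(k): str(v) for k, v in groups.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_cohort(path: str) -> pd.Series:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return pd.Series(payload["groups"], name="group")
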