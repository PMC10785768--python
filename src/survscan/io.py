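"""Readers/writers for the pipeline's tabular formats, with strict validation.

All tables are tab-separated with "." decimals. Gene symbols are upper-cased
on load (symbol-style normalisation only — no synonym resolution). Patients
lacking a survival time or censoring status are excluded at load with a
logged count; other missing covariates are retained and handled model-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "read_clinical", "write_clinical",
           "read_expression", "write_expression", "read_gmt", "write_gmt",
           "read_weights", "write_weights", "align"]

CLINICAL_COLUMNS = ["patient_id", "cohort", "os_months", "event", "age",
                    "sex", "stage", "site", "msi_mantis"]
REQUIRED_CLINICAL = ["patient_id", "cohort", "os_months", "event"]


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix with a record of what the values are."""

    values: pd.DataFrame
    kind: str = "counts"  # "counts" | "normalized"

    def __post_init__(self):
        if self.kind not in ("counts", "normalized"):
            raise ValueError(f"unknown value kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids: {list(dups[:5])}")


def read_clinical(path, time_col: str = "os_months",
                  event_col: str = "event") -> pd.DataFrame:
    """Load and validate the clinical table (TSV, one row per patient).

    Rows with missing/unparseable survival time or event status are dropped
    with a logged count; duplicate patient ids are an error. The endpoint
    columns are configurable (a study may record several survival columns).
    Returns a frame indexed by patient_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "cohort", time_col, event_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks required column(s): {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient_id: {sorted(dup.unique())[:5]}")

    t = pd.to_numeric(df[time_col], errors="coerce")
    e = pd.to_numeric(df[event_col], errors="coerce")
    keep = t.notna() & e.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("read_clinical: excluded %d patient(s) lacking survival "
                    "time or event status", n_drop)
    df = df.loc[keep].copy()
    df[time_col] = t[keep]
    df[event_col] = e[keep].astype(int)
    if (df[time_col] < 0).any():
        raise ValueError("negative survival time")
    if not df[event_col].isin((0, 1)).all():
        raise ValueError("event status must be 0 or 1")
    for col in ("age", "msi_mantis"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    out = df.set_index("patient_id").sort_index()
    logger.info("read_clinical: %d patients retained", len(out))
    return out


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="patient_id")


def read_expression(path, kind: str = "counts") -> ExpressionMatrix:
    """Load a genes-as-rows expression TSV (first column = gene id).

    Negative entries are an error reported with their coordinates; gene
    symbols are upper-cased.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(f"negative expression value at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    logger.info("read_expression: %d genes x %d samples", *df.shape)
    return ExpressionMatrix(values=df, kind=kind)


def write_expression(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict:
    """Parse a GMT file into an ordered mapping set-name → member list.

    Standard format: name, description, then members, tab-separated.
    Members repeated within one set are stored once (warning logged);
    symbols are upper-cased.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = parts[0]
            members = []
            seen = set()
            for sym in parts[2:]:
                sym = sym.strip().upper()
                if not sym:
                    continue
                if sym in seen:
                    logger.warning("read_gmt: %s repeats member %s; stored once",
                                   name, sym)
                    continue
                seen.add(sym)
                members.append(sym)
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_weights(path) -> pd.DataFrame:
    """Load a genes × pathways weight TSV; weights must be finite,
    pathway names unique."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    if df.columns.duplicated().any():
        raise ValueError("duplicate pathway names in weight matrix")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("weight matrix contains non-finite values")
    return df


def write_weights(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index_label="gene")


def align(clinical: pd.DataFrame, expression: ExpressionMatrix | pd.DataFrame):
    """Restrict both tables to their common patients, sorted by patient id.

    Idempotent; the dropped-id counts are logged per side. An empty
    intersection is an error.
    """
    expr_df = expression.values if isinstance(expression, ExpressionMatrix) else expression
    common = clinical.index.intersection(expr_df.columns).sort_values()
    common.name = clinical.index.name
    if common.empty:
        raise ValueError("no patients shared between clinical and expression tables")
    n_clin = len(clinical) - len(common)
    n_expr = expr_df.shape[1] - len(common)
    if n_clin or n_expr:
        logger.info("align: dropped %d clinical-only and %d expression-only "
                    "patient(s)", n_clin, n_expr)
    clin_out = clinical.loc[common]
    expr_out = expr_df[common]
    if isinstance(expression, ExpressionMatrix):
        expr_out = ExpressionMatrix(values=expr_out, kind=expression.kind)
    return clin_out, expr_out
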