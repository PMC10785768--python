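"""Multivariable Cox models with gene × cohort interaction terms.

Builds dummy-coded design matrices from the clinical table (continuous
terms, categorical terms against a stated reference level, and elementwise
product interaction terms), fits them with the in-house Newton–Raphson Cox
solver, and projects the fit into a forest-style table with R-convention
significance codes. Missing covariates are handled by listwise deletion per
model, with the dropped count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import CoxFit, cox_fit

logger = logging.getLogger(__name__)

__all__ = ["DesignSpec", "build_design", "fit_model", "forest_table",
           "significance_code", "stage_collapse"]

#: R-style significance-code legend: 0 "***" 0.001 "**" 0.01 "*" 0.05 "." 0.1
SIG_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_code(p: float) -> str:
    for cut, code in SIG_CODES:
        if p < cut:
            return code
    return ""


@dataclass
class DesignSpec:
    """Model formula description.

    ``continuous`` — clinical column names entered as-is (gene expression
    should already be on the log scale). ``categorical`` — mapping column →
    reference level; each non-reference level becomes an indicator.
    ``interactions`` — pairs of already-declared term/column names whose
    product is added (an indicator column is referenced as
    ``"col[level]"``).
    """

    continuous: list = field(default_factory=list)
    categorical: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)


def stage_collapse(stage: pd.Series) -> pd.Series:
    """Collapse tumour stage to the I–III vs IV grouping."""
    return stage.map(lambda s: "IV" if s == "IV" else ("I-III" if pd.notna(s) else s))


def build_design(clinical: pd.DataFrame, spec: DesignSpec,
                 gene_vector: pd.Series | None = None,
                 time_col: str = "os_months", event_col: str = "event"):
    """Assemble (X, times, events, n_dropped) for a Cox model.

    ``gene_vector`` is an optional per-patient covariate (e.g. log-scale
    expression of one gene) addressable in the spec under its series name.
    Complete cases only; the dropped-for-missingness count is returned.
    """
    data = clinical.copy()
    if gene_vector is not None:
        data[gene_vector.name] = gene_vector.reindex(data.index)

    cols_needed = list(spec.continuous) + list(spec.categorical)
    for c in cols_needed:
        if c not in data.columns:
            raise ValueError(f"term {c!r} not found in the clinical table")

    model_cols = cols_needed + [time_col, event_col]
    complete = data[model_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_design: %d observation(s) deleted for missingness",
                    n_dropped)
    data = data.loc[complete]

    X = pd.DataFrame(index=data.index)
    for c in spec.continuous:
        X[c] = pd.to_numeric(data[c], errors="raise").astype(float)
    for c, ref in spec.categorical.items():
        levels = sorted(data[c].astype(str).unique())
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {c!r}")
        others = [lv for lv in levels if lv != ref]
        if not others:
            raise ValueError(f"categorical term {c!r} has a single level "
                             f"({ref!r}) — constant column")
        for lv in others:
            X[f"{c}[{lv}]"] = (data[c].astype(str) == lv).astype(float)
    for a, b in spec.interactions:
        for t in (a, b):
            if t not in X.columns:
                raise ValueError(f"interaction references unknown term {t!r}")
        X[f"{a}:{b}"] = X[a] * X[b]

    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant design column(s) after deletion: {const}")
    return X, data[time_col].to_numpy(float), data[event_col].to_numpy(int), n_dropped


def fit_model(X: pd.DataFrame, times, events, ties: str = "breslow") -> CoxFit:
    """Fit the assembled design with the Newton–Raphson Cox solver."""
    return cox_fit(times, events, X.to_numpy(dtype=float), ties=ties,
                   term_names=list(X.columns))


def forest_table(fit: CoxFit, dropped: int = 0) -> pd.DataFrame:
    """Forest-style projection of a Cox fit (no numeric recomputation).

    One row per term: HR, 95% CI, Wald p and its significance code; the
    fit-level quantities (n, events, observations dropped for missingness,
    AIC, convergence) ride along in ``DataFrame.attrs``.
    """
    df = pd.DataFrame({
        "term": fit.terms,
        "hr": fit.hr,
        "ci_lower": fit.ci_lower,
        "ci_upper": fit.ci_upper,
        "p": fit.p,
        "code": [significance_code(p) for p in fit.p],
    }).set_index("term")
    df.attrs.update({
        "n": fit.n, "n_events": fit.n_events, "dropped_missing": int(dropped),
        "aic": fit.aic, "converged": fit.converged, "message": fit.message,
    })
    if not fit.converged:
        logger.warning("forest_table: fit not converged (%s)", fit.message)
    return df
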