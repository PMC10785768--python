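"""Optimal-cutoff (minimum-p) survival scanning with Storey's q-values.

Each continuous feature (gene expression, pathway activity score) is
dichotomised at every admissible threshold — midpoints between consecutive
distinct values whose induced low-group fraction lies within the scan bounds
(default 10–90%) — and the two-group survival difference is evaluated at each
threshold with the Yates-corrected log-rank test. The threshold minimising p
is reported together with the hazard ratio of the winning split (high vs low
expression) from a single-covariate Cox model.

Minimum-p selection over many candidate splits is anti-conservative: the
per-feature p-values are not uniform under the null. The false-discovery-rate
stage is applied to the min-p values as-is; the resulting inflation is
quantified (not corrected) by the calibration tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import ZERO_EVENT_SHIFT, cox_fit

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "QValueSet", "scan_feature", "scan_matrix",
           "scan_gene_set", "storey_qvalues"]


@dataclass
class ScanResult:
    """Best split found for one feature."""

    feature: str
    cutoff: float
    low_fraction: float
    n_low: int
    n_high: int
    chi2: float
    p: float
    hr: float
    ci_lower: float
    ci_upper: float
    se_log_hr: float
    n_candidates: int
    scannable: bool = True
    q: float = np.nan
    cox_converged: bool = True


def _yates_chi2_vec(U, V):
    corrected = np.maximum(0.0, np.abs(U) - 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, corrected**2 / np.where(V > 0, V, 1.0), 0.0)
    p = np.where(V > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def _candidate_table(values, times, events, bounds):
    """Log-rank O/E/V for every admissible prefix split, fully vectorised.

    Patients are ordered by feature value; a candidate split puts the first
    k of them into the low group. For each distinct event time t_i the
    low-group at-risk and event counts over all k are prefix sums, so the
    whole scan is two cumulative-sum matrices of shape
    (distinct event times x candidates).
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    v, t, e = values[order], times[order], events[order]

    lo, hi = bounds
    ks = np.arange(1, n)                       # low-group size after k patients
    frac = ks / n
    admissible = (frac >= lo - 1e-12) & (frac <= hi + 1e-12) & (v[1:] > v[:-1])
    ks = ks[admissible]
    if ks.size == 0:
        return None
    cutoffs = 0.5 * (v[ks - 1] + v[ks])

    event_times = np.unique(t[e == 1])
    at_risk = t[None, :] >= event_times[:, None]           # (m, n) value-ordered
    is_event = (t[None, :] == event_times[:, None]) & (e[None, :] == 1)

    n_risk = at_risk.sum(axis=1).astype(float)             # (m,)
    d = is_event.sum(axis=1).astype(float)
    n1 = np.cumsum(at_risk, axis=1, dtype=float)[:, ks - 1]   # (m, C)
    d1 = np.cumsum(is_event, axis=1, dtype=float)[:, ks - 1]

    frac1 = n1 / n_risk[:, None]
    E1 = d[:, None] * frac1
    with np.errstate(invalid="ignore", divide="ignore"):
        var_term = np.where(
            n_risk[:, None] > 1,
            d[:, None] * frac1 * (1 - frac1)
            * (n_risk[:, None] - d[:, None]) / (n_risk[:, None] - 1),
            0.0,
        )
    U = d1.sum(axis=0) - E1.sum(axis=0)
    V = var_term.sum(axis=0)
    chi2, p = _yates_chi2_vec(U, V)
    return {"k": ks, "cutoff": cutoffs, "chi2": chi2, "p": p,
            "order": order, "n": n}


def scan_feature(values, times, events, bounds=(0.10, 0.90),
                 feature: str = "feature", ties: str = "breslow") -> ScanResult:
    """Scan one feature for its optimal survival-separating cutoff.

    Ties in the minimum p are broken toward the split closest to 50/50.
    A feature with no admissible split (e.g. constant) is returned flagged
    ``scannable=False`` and excluded from downstream FDR.
    """
    v = np.asarray(values, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if not (v.size == t.size == e.size):
        raise ValueError("values/times/events length mismatch")
    if v.size < 10:
        raise ValueError("scan requires at least 10 patients")
    if not np.all(np.isfinite(v)):
        raise ValueError("feature values must be finite")
    if e.sum() < 1:
        raise ValueError("scan requires at least one event")
    t = np.where((t == 0) & (e == 1), ZERO_EVENT_SHIFT, t)

    table = _candidate_table(v, t, e, bounds)
    if table is None:
        return ScanResult(feature=feature, cutoff=np.nan, low_fraction=np.nan,
                          n_low=0, n_high=0, chi2=np.nan, p=np.nan, hr=np.nan,
                          ci_lower=np.nan, ci_upper=np.nan, se_log_hr=np.nan,
                          n_candidates=0, scannable=False)

    n = table["n"]
    p = table["p"]
    best_p = p.min()
    tied = np.flatnonzero(p <= best_p + 0.0)
    balance = np.abs(table["k"][tied] / n - 0.5)
    best = tied[np.lexsort((table["k"][tied], balance))][0]

    k = int(table["k"][best])
    cutoff = float(table["cutoff"][best])
    high = (v > cutoff).astype(float)
    try:
        fit = cox_fit(t, e, high.reshape(-1, 1), ties=ties, term_names=["high"])
        hr, lo_ci, hi_ci = float(fit.hr[0]), float(fit.ci_lower[0]), float(fit.ci_upper[0])
        se, conv = float(fit.se[0]), bool(fit.converged)
    except ValueError:
        hr = lo_ci = hi_ci = se = np.nan
        conv = False
    return ScanResult(feature=feature, cutoff=cutoff, low_fraction=k / n,
                      n_low=k, n_high=n - k, chi2=float(table["chi2"][best]),
                      p=float(p[best]), hr=hr, ci_lower=lo_ci, ci_upper=hi_ci,
                      se_log_hr=se, n_candidates=int(p.size),
                      scannable=True, cox_converged=conv)


def _results_frame(results) -> pd.DataFrame:
    rows = [vars(r).copy() for r in results]
    return pd.DataFrame(rows).set_index("feature")


def scan_matrix(values: pd.DataFrame, times, events, bounds=(0.10, 0.90),
                alpha: float = 0.05, fdr_method: str = "smoother",
                ties: str = "breslow") -> pd.DataFrame:
    """Scan every row of a features×samples frame; attach joint q-values.

    q-values are computed across the scannable features only; features
    flagged not-scannable keep q = NaN. A ``significant`` flag records
    p < alpha (the q-value is reported alongside).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    results = [scan_feature(values.loc[f].to_numpy(), t, e, bounds=bounds,
                            feature=str(f), ties=ties)
               for f in values.index]
    df = _results_frame(results)
    mask = df["scannable"] & np.isfinite(df["p"])
    n_skipped = int((~mask).sum())
    if n_skipped:
        logger.info("scan: %d feature(s) not scannable, excluded from FDR", n_skipped)
    if mask.any():
        qset = storey_qvalues(df.loc[mask, "p"].to_numpy(), method=fdr_method)
        df.loc[mask, "q"] = qset.qvalues
    df["significant"] = mask & (df["p"] < alpha)
    return df


def scan_gene_set(expression: pd.DataFrame, clinical: pd.DataFrame,
                  gene_set, per_cohort: bool = True,
                  cohort_col: str = "cohort", time_col: str = "os_months",
                  event_col: str = "event", **scan_kw) -> dict:
    """Per-cohort optimal-cutoff scan over the members of a gene set.

    ``expression`` is genes×samples, aligned to ``clinical`` (indexed by
    patient id). Members absent from the matrix are logged and skipped.
    Returns a mapping cohort-label → results frame (a single ``"pooled"``
    entry when ``per_cohort`` is false).
    """
    members = [g for g in gene_set if g in expression.index]
    missing = [g for g in gene_set if g not in expression.index]
    if missing:
        logger.warning("scan_gene_set: %d member(s) absent from matrix: %s",
                       len(missing), ", ".join(map(str, missing[:10])))
    sub = expression.loc[members]
    out = {}
    if per_cohort:
        for label, grp in clinical.groupby(cohort_col, observed=True, sort=True):
            if grp.empty:
                raise ValueError(f"empty cohort {label!r}")
            cols = grp.index
            out[label] = scan_matrix(sub[cols], grp[time_col].to_numpy(),
                                     grp[event_col].to_numpy(), **scan_kw)
    else:
        out["pooled"] = scan_matrix(sub[clinical.index],
                                    clinical[time_col].to_numpy(),
                                    clinical[event_col].to_numpy(), **scan_kw)
    return out


@dataclass
class QValueSet:
    """Storey q-values with the π0 estimate behind them."""

    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray
    lambda_grid: np.ndarray
    method: str


def _estimate_pi0(p, method, lambda_grid):
    m = p.size
    if method == "fixed":
        lam = 0.5
        pi0 = (p > lam).sum() / (m * (1 - lam))
    elif method == "smoother":
        pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid])
        # cubic fit of pi0(lambda) evaluated at the right edge; points are
        # weighted ~ inverse variance (Var[pi0(lam)] grows like 1/(1-lam))
        # so the noisy high-lambda tail does not dominate the fit
        coeffs = np.polyfit(lambda_grid, pi0_lam, deg=3,
                            w=np.sqrt(1.0 - lambda_grid))
        pi0 = float(np.polyval(coeffs, lambda_grid[-1]))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))


def storey_qvalues(pvals, method: str = "smoother", pi0: float | None = None) -> QValueSet:
    """Positive-FDR q-values (Storey).

    π0 — the proportion of true nulls — is estimated from the p-value
    histogram on a λ grid (0.01…0.95): either a cubic smoother evaluated at
    λ = 0.95 (``method="smoother"``) or the single point λ = 0.5
    (``method="fixed"``). With ``pi0`` forced to 1 the q-values coincide
    exactly with Benjamini–Hochberg adjusted p-values.

    q_(i) = min_{j >= i} π0 · m · p_(j) / j over the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = np.arange(0.01, 0.9501, 0.01)
    if pi0 is None:
        pi0_hat = _estimate_pi0(p, method, grid)
    else:
        if not (0 < pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0_hat * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueSet(pvalues=p, pi0=pi0_hat, qvalues=q, lambda_grid=grid,
                     method=method if pi0 is None else "forced")
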