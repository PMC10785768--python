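"""Simplified negative-binomial Wald differential expression.

A deliberately transparent two-group NB test: median-of-ratios library-size
normalisation, per-gene method-of-moments dispersion on normalised counts,
an NB log-link GLM (intercept + cohort indicator, library sizes as offsets)
fitted by Fisher scoring, and a Wald test on the cohort coefficient with
Benjamini–Hochberg adjustment. There is no dispersion or fold-change
shrinkage, no independent filtering and no outlier handling; a
externally produced differential-expression table with the same columns can
be imported in their place (:func:`import_de_table`).

The GLM is fitted for all genes simultaneously (vectorised 2×2 Fisher
scoring), which makes label-swap antisymmetry of the fold changes exact and
keeps genome-scale null calibrations fast. The test suite cross-checks the
fits against an independent GLM implementation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["size_factors", "nb_wald", "call_deg", "import_de_table"]

LN2 = np.log(2.0)

DE_COLUMNS = ["baseMean", "log2FC", "se", "stat", "p", "padj", "significant"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes g with all-positive counts of
    K_gj / geometric-mean_j'(K_gj').
    """
    K = counts.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    Kp = K[all_pos]
    log_geo = np.mean(np.log(Kp), axis=1, keepdims=True)
    s = np.exp(np.median(np.log(Kp) - log_geo, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def _mom_dispersion(norm_counts, groups):
    """Per-gene NB dispersion alpha with Var = mu + alpha mu^2.

    Method of moments within each cohort (the cohorts may differ in mean),
    pooled with weights n_c - 1 and floored at 1e-8.
    """
    alphas = np.zeros(norm_counts.shape[0])
    weights = 0.0
    num = np.zeros(norm_counts.shape[0])
    for g in (0, 1):
        Y = norm_counts[:, groups == g]
        nc = Y.shape[1]
        if nc < 2:
            continue
        mu = Y.mean(axis=1)
        var = Y.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / mu**2, 0.0)
        num += (nc - 1) * a
        weights += nc - 1
    alphas = num / max(weights, 1.0)
    return np.clip(alphas, 1e-8, None)


def _nb_glm_two_group(K, g, offsets, alpha, tol=1e-10, max_iter=100):
    """Fisher scoring for the NB log-link GLM, vectorised over genes.

    Model: K_gj ~ NB(mu_gj, alpha_g), log mu_gj = o_j + b0_g + b1_g * g_j.
    Returns (b0, b1, se1, converged).
    """
    m, n = K.shape
    x = g.astype(float)
    # moment-based start
    off = np.exp(offsets)
    y = K / off
    muA = y[:, g == 0].mean(axis=1)
    muB = y[:, g == 1].mean(axis=1)
    eps = 1e-8
    b0 = np.log(np.clip(muA, eps, None))
    b1 = np.log(np.clip(muB, eps, None)) - b0

    a = alpha[:, None]
    ok = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        eta = offsets[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        denom = 1.0 + a * mu
        r = (K - mu) / denom              # score residuals
        W = mu / denom                    # Fisher weights
        U0 = r.sum(axis=1)
        U1 = (r * x[None, :]).sum(axis=1)
        I00 = W.sum(axis=1)
        I01 = (W * x[None, :]).sum(axis=1)
        I11 = (W * (x**2)[None, :]).sum(axis=1)
        det = I00 * I11 - I01**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        db0 = (I11 * U0 - I01 * U1) / det
        db1 = (I00 * U1 - I01 * U0) / det
        step = np.clip(np.stack([db0, db1]), -5, 5)
        b0 = b0 + step[0]
        b1 = b1 + step[1]
        b1 = np.clip(b1, -50, 50)
        if max(np.max(np.abs(U0), initial=0), np.max(np.abs(U1), initial=0)) < tol:
            break
    converged = (np.abs(U0) < 1e-4) & (np.abs(U1) < 1e-4)
    # standard errors from the expected information at the optimum
    eta = offsets[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    W = mu / (1.0 + a * mu)
    I00 = W.sum(axis=1)
    I01 = (W * x[None, :]).sum(axis=1)
    I11 = (W * (x**2)[None, :]).sum(axis=1)
    det = I00 * I11 - I01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, I00 / det, np.nan))
    return b0, b1, se1, converged & ok


def nb_wald(counts: pd.DataFrame, cohort_labels, factors: pd.Series | None = None,
            lfc_thresh: float = 0.1, p_thresh: float = 0.05) -> pd.DataFrame:
    """Two-group NB Wald differential-expression test.

    ``cohort_labels`` is a length-n-samples vector with exactly two levels;
    fold changes are reported for the second level (sorted order) versus the
    first. Genes with zero counts in every sample are skipped. Returns a
    frame indexed by gene with columns ``baseMean, log2FC, se, stat, p,
    padj, significant``.
    """
    labels = pd.Series(np.asarray(cohort_labels), index=counts.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two cohorts required, got {len(levels)}")
    gvec = (labels == levels[1]).to_numpy().astype(int)
    if (gvec == 0).sum() < 3 or (gvec == 1).sum() < 3:
        raise ValueError("each cohort needs at least 3 samples")
    if factors is None:
        factors = size_factors(counts)
    s = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(s <= 0) or np.any(~np.isfinite(s)):
        raise ValueError("size factors must be positive and finite")

    K = counts.to_numpy(dtype=float)
    nonzero = K.sum(axis=1) > 0
    n_skip = int((~nonzero).sum())
    if n_skip:
        logger.info("nb_wald: skipping %d all-zero gene(s)", n_skip)
    Kn = K[nonzero]
    offsets = np.log(s)
    norm = Kn / s[None, :]
    alpha = _mom_dispersion(norm, gvec)
    b0, b1, se1, conv = _nb_glm_two_group(Kn, gvec, offsets, alpha)

    log2fc = b1 / LN2
    se_log2 = se1 / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({
        "baseMean": norm.mean(axis=1),
        "log2FC": log2fc,
        "se": se_log2,
        "stat": z,
        "p": np.clip(p, np.finfo(float).tiny, 1.0),
        "padj": padj,
        "converged": conv,
    }, index=counts.index[nonzero])
    out.index.name = "gene"
    return call_deg(out, lfc_thresh=lfc_thresh, p_thresh=p_thresh)


def call_deg(results: pd.DataFrame, lfc_thresh: float = 0.1,
             p_thresh: float = 0.05) -> pd.DataFrame:
    """Flag differentially expressed genes: p < p_thresh and |log2FC| > lfc_thresh."""
    if lfc_thresh < 0 or p_thresh < 0:
        raise ValueError("thresholds must be non-negative")
    out = results.copy()
    out["significant"] = (out["p"] < p_thresh) & (out["log2FC"].abs() > lfc_thresh)
    n_deg = int(out["significant"].sum())
    logger.info("call_deg: %d DEG, %d non-DEG (p<%g, |log2FC|>%g)",
                n_deg, len(out) - n_deg, p_thresh, lfc_thresh)
    return out


def import_de_table(path, lfc_thresh: float = 0.1, p_thresh: float = 0.05) -> pd.DataFrame:
    """Load an externally produced differential-expression table.

    Expects a TSV with a gene index column and at least ``log2FC`` and ``p``
    columns (``baseMean, se, stat, padj`` carried through when present);
    significance flags are (re)derived from the stated thresholds.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"log2FC", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"external DE table lacks columns: {sorted(missing)}")
    if "padj" not in df.columns:
        df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return call_deg(df, lfc_thresh=lfc_thresh, p_thresh=p_thresh)
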