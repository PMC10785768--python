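"""Weight-matrix pathway-activity scoring (PROGENy-style).

Pathway activity for a sample is a weighted sum of that sample's z-scored
expression over the pathway's most responsive genes. The weight matrix
(genes × pathways, e.g. PROGENy's colorectal model matrix) is an input; its
training is out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scan import ScanResult, scan_feature, scan_matrix

logger = logging.getLogger(__name__)

__all__ = ["normalize_log", "zscore_genes", "progeny_scores", "score_survival"]


def normalize_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Library-size-corrected log transform: log2(count / s_j + 1)."""
    s = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(s <= 0) or np.any(~np.isfinite(s)):
        raise ValueError("size factors must be positive and finite")
    return pd.DataFrame(np.log2(counts.to_numpy(dtype=float) / s[None, :] + 1.0),
                        index=counts.index, columns=counts.columns)


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each gene row to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance genes are set to all-zero rows (logged) rather than NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("zscore_genes: %d constant gene row(s) set to zero", flat.sum())
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    Z[flat, :] = 0.0
    return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)


def progeny_scores(zmatrix: pd.DataFrame, weights: pd.DataFrame,
                   top_k: int = 100, ranks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample pathway activity: score_{p,j} = sum_g z_{g,j} w_{g,p}.

    For each pathway only its ``top_k`` most responsive member genes are
    used — by the supplied responsiveness ``ranks`` when given, by |weight|
    otherwise — restricted to genes present in the expression matrix.

    Returns a pathways × samples frame.
    """
    if weights.shape[1] == 0:
        raise ValueError("weight matrix has zero pathways")
    common = weights.index.intersection(zmatrix.index)
    scores = {}
    for pw in weights.columns:
        if common.empty:
            raise ValueError(f"pathway {pw!r} has no overlapping genes")
        w = weights.loc[common, pw]
        w = w[w != 0]
        if w.empty:  # an all-zero pathway column scores zero by linearity
            logger.info("progeny_scores: pathway %s has all-zero weights", pw)
            scores[pw] = pd.Series(0.0, index=zmatrix.columns)
            continue
        if ranks is not None and pw in ranks.columns:
            keyed = ranks.loc[w.index, pw].sort_values()
            keep = keyed.index[:top_k]
        else:
            keep = w.abs().sort_values(ascending=False).index[:top_k]
        logger.info("progeny_scores: pathway %s uses %d gene(s)", pw, len(keep))
        scores[pw] = zmatrix.loc[keep].mul(w.loc[keep], axis=0).sum(axis=0)
    out = pd.DataFrame(scores).T
    out.index.name = "pathway"
    return out


def score_survival(scores: pd.DataFrame, clinical: pd.DataFrame,
                   per_cohort: bool = True, cohort_col: str = "cohort",
                   time_col: str = "os_months", event_col: str = "event",
                   **scan_kw) -> dict:
    """Optimal-cutoff survival scan of each pathway's activity score.

    Returns a mapping cohort label → scan results frame (``"pooled"`` when
    ``per_cohort`` is false), tabulating HR, CI, p and SE per pathway.
    """
    out = {}
    if per_cohort:
        groups = clinical.groupby(cohort_col, observed=True, sort=True)
        items = [(label, grp) for label, grp in groups]
    else:
        items = [("pooled", clinical)]
    for label, grp in items:
        if grp.empty:
            raise ValueError(f"empty cohort {label!r}")
        out[label] = scan_matrix(scores[grp.index], grp[time_col].to_numpy(),
                                 grp[event_col].to_numpy(), **scan_kw)
    return out


def cohort_mean_differences(scores: pd.DataFrame, clinical: pd.DataFrame,
                            cohort_col: str = "cohort") -> pd.DataFrame:
    """Per-pathway cohort mean scores and their absolute difference."""
    labels = sorted(clinical[cohort_col].unique())
    if len(labels) != 2:
        raise ValueError("exactly two cohorts required")
    a, b = labels
    mean_a = scores[clinical.index[clinical[cohort_col] == a]].mean(axis=1)
    mean_b = scores[clinical.index[clinical[cohort_col] == b]].mean(axis=1)
    return pd.DataFrame({f"mean_{a}": mean_a, f"mean_{b}": mean_b,
                         "abs_difference": (mean_a - mean_b).abs()})
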