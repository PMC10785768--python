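"""Cross-cohort synthesis: concordance/discordance classes, Venn regions
and the integer summary arithmetic.

A gene scanned in both cohorts falls into one of five categories driven
solely by the two significance flags and the sign agreement of the log
hazard ratios:

* ``both-concordant``  — significant in both cohorts, same log-HR sign;
* ``both-discordant``  — significant in both, opposite log-HR sign (the
  survival association flips direction between cohorts);
* ``exclusive-A`` / ``exclusive-B`` — significant in one cohort only;
* ``neither``.

All percentages are carried with their integer numerator and denominator so
summary reports are exactly reproducible arithmetic, never re-measured.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["classify_genes", "venn_deg_survival", "summarize_fractions", "fraction"]

CATEGORIES = ["both-concordant", "both-discordant", "exclusive-A",
              "exclusive-B", "neither"]


def classify_genes(scan_a: pd.DataFrame, scan_b: pd.DataFrame,
                   alpha: float = 0.05, use_q: bool = False,
                   labels: tuple = ("A", "B")) -> pd.DataFrame:
    """Classify each gene by its two-cohort survival-association pattern.

    ``scan_a``/``scan_b`` are scan-result frames indexed by gene with
    ``hr`` and ``p`` (and ``q``) columns over the same gene universe.
    Significance is p < alpha by default, q < alpha with ``use_q``.
    """
    genes = scan_a.index
    if not genes.equals(scan_b.index):
        common = genes.intersection(scan_b.index)
        if len(common) != len(genes) or len(common) != len(scan_b.index):
            raise ValueError("scans must cover the same gene universe")
        scan_b = scan_b.loc[genes]
    col = "q" if use_q else "p"
    sig_a = (scan_a[col] < alpha).fillna(False).to_numpy()
    sig_b = (scan_b[col] < alpha).fillna(False).to_numpy()
    log_hr_a = np.log(scan_a["hr"].to_numpy(dtype=float))
    log_hr_b = np.log(scan_b["hr"].to_numpy(dtype=float))
    same_sign = np.sign(log_hr_a) == np.sign(log_hr_b)

    category = np.full(len(genes), "neither", dtype=object)
    category[sig_a & ~sig_b] = "exclusive-A"
    category[~sig_a & sig_b] = "exclusive-B"
    category[sig_a & sig_b & same_sign] = "both-concordant"
    category[sig_a & sig_b & ~same_sign] = "both-discordant"

    out = pd.DataFrame({
        f"hr_{labels[0]}": scan_a["hr"], f"p_{labels[0]}": scan_a["p"],
        f"hr_{labels[1]}": scan_b["hr"], f"p_{labels[1]}": scan_b["p"],
        f"significant_{labels[0]}": sig_a, f"significant_{labels[1]}": sig_b,
        "category": category,
    }, index=genes)
    counts = out["category"].value_counts()
    logger.info("classify_genes: %s", counts.to_dict())
    return out


def venn_deg_survival(classifications: pd.DataFrame,
                      deg_flags: pd.Series | None = None,
                      labels: tuple = ("A", "B")) -> dict:
    """All 2^3 region counts of the DEG × significant-A × significant-B Venn.

    ``deg_flags`` (boolean per gene) may be supplied separately or as a
    ``deg`` column of the classification frame; genes absent from the flag
    vector count as non-DEG.
    """
    df = classifications
    if deg_flags is None:
        if "deg" not in df.columns:
            raise ValueError("DEG flags required (deg_flags or a 'deg' column)")
        deg = df["deg"].astype(bool)
    else:
        deg = deg_flags.reindex(df.index).fillna(False).astype(bool)
    sa = df[f"significant_{labels[0]}"].astype(bool)
    sb = df[f"significant_{labels[1]}"].astype(bool)
    regions = {}
    for d in (False, True):
        for a in (False, True):
            for b in (False, True):
                key = (f"{'deg' if d else 'nondeg'}"
                       f"_{'sigA' if a else 'nsA'}_{'sigB' if b else 'nsB'}")
                regions[key] = int(((deg == d) & (sa == a) & (sb == b)).sum())
    regions["universe"] = int(len(df))
    regions["deg_total"] = int(deg.sum())
    regions[f"sig_{labels[0]}_total"] = int(sa.sum())
    regions[f"sig_{labels[1]}_total"] = int(sb.sum())
    return regions


def fraction(numerator: int, denominator: int) -> dict:
    """A percentage carried with its exact integer provenance."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    return {"numerator": int(numerator), "denominator": int(denominator),
            "percent": int(round(pct)), "percent_1dp": round(pct, 1)}


def summarize_fractions(n_sig_a: int, n_sig_b: int, overlap: int,
                        n_features: int | None = None,
                        n_unique_genes: int | None = None,
                        n_deg: int | None = None) -> dict:
    """Derived two-cohort summary quantities, as pure integer arithmetic.

    ``total_associations`` counts each cohort's significant associations
    (n_A + n_B, a gene significant in both cohorts counted twice);
    ``non_common`` subtracts the overlap once from that total — numerically
    this coincides with the set-theoretic union ``union_unique``, reported
    under its own key; ``symmetric_difference`` counts genes significant in
    exactly one cohort (n_A + n_B − 2·overlap), which is the strictly
    set-theoretic notion of "non-common".
    """
    if min(n_sig_a, n_sig_b, overlap) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(n_sig_a, n_sig_b):
        raise ValueError("overlap cannot exceed either cohort count")
    total = n_sig_a + n_sig_b
    out = {
        "n_significant_A": int(n_sig_a),
        "n_significant_B": int(n_sig_b),
        "overlap": int(overlap),
        "total_associations": int(total),
        "non_common": int(total - overlap),
        "union_unique": int(total - overlap),
        "symmetric_difference": int(total - 2 * overlap),
    }
    if n_features:
        out["frac_significant_A"] = fraction(n_sig_a, n_features)
        out["frac_significant_B"] = fraction(n_sig_b, n_features)
    if n_unique_genes and n_deg is not None:
        out["frac_deg"] = fraction(n_deg, n_unique_genes)
        out["n_non_deg"] = int(n_unique_genes - n_deg)
        out["frac_non_deg"] = fraction(n_unique_genes - n_deg, n_unique_genes)
    return out
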