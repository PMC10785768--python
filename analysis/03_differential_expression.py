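#!/usr/bin/env python
"""Simplified NB Wald differential expression between the two cohorts.

Median-of-ratios normalisation, per-gene moment dispersions, Wald test on
the cohort coefficient, BH adjustment; genes with p < 0.05 and
|log2FC| > 0.1 are flagged differentially expressed. Writes
results/de_results.tsv.
"""

import sys
from pathlib import Path

from survscan import io
from survscan.de import nb_wald

DATA = Path("results/data")
OUT = Path("results")


def main() -> int:
    clinical = io.read_clinical(DATA / "clinical.tsv")
    expr = io.read_expression(DATA / "expression.tsv")
    clinical, expr = io.align(clinical, expr)
    gene_sets = io.read_gmt(DATA / "gene_sets.gmt")
    universe = sorted({g for m in gene_sets.values() for g in m})

    res = nb_wald(expr.values.loc[universe],
                  clinical["cohort"].astype(str).to_numpy())
    res.to_csv(OUT / "de_results.tsv", sep="\t", float_format="%.10g")

    n_deg = int(res["significant"].sum())
    print(f"{n_deg}/{len(res)} genes differentially expressed "
          f"({100 * n_deg / len(res):.0f}%) at p<0.05, |log2FC|>0.1")
    top = res.nsmallest(4, "p")[["log2FC", "p", "padj"]]
    print("top 4 DEG:")
    print(top.round(4).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
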