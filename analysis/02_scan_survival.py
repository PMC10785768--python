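#!/usr/bin/env python
"""Per-cohort optimal-cutoff survival scan over the gene-set universe.

For every gene in the nine gene sets, each cohort's patients are split at
every admissible 10–90% expression threshold; the split minimising the
Yates-corrected log-rank p is kept, with its Cox hazard ratio and a Storey
q-value computed jointly per cohort. Writes one table per cohort under
results/ mirroring the scan-summary layout (gene, cutoff, group sizes,
chi2, p, q, HR, CI, SE).
"""

import sys
from pathlib import Path

from survscan import io
from survscan.scan import scan_gene_set

DATA = Path("results/data")
OUT = Path("results")


def main() -> int:
    clinical = io.read_clinical(DATA / "clinical.tsv")
    expr = io.read_expression(DATA / "expression.tsv")
    clinical, expr = io.align(clinical, expr)
    gene_sets = io.read_gmt(DATA / "gene_sets.gmt")
    universe = sorted({g for m in gene_sets.values() for g in m})

    scans = scan_gene_set(expr.values, clinical, universe, per_cohort=True)
    sig = {}
    for label, df in scans.items():
        safe = "".join(c if c.isalnum() else "_" for c in label)
        df.to_csv(OUT / f"scan_{safe}.tsv", sep="\t", float_format="%.10g")
        sig[label] = set(df.index[df["significant"]])
        print(f"{label}: {len(sig[label])}/{len(df)} genes associated with "
              f"overall survival at p<0.05 "
              f"(min q = {df['q'].min():.2e})")
    labels = sorted(sig)
    overlap = sig[labels[0]] & sig[labels[1]]
    total = sum(len(s) for s in sig.values())
    print(f"total associations: {total}; common genes: {len(overlap)}; "
          f"non-common: {total - len(overlap)}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
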