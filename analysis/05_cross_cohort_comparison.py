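#!/usr/bin/env python
"""Cross-cohort synthesis: concordance classes, DEG×survival Venn regions
and the integer summary report.

Joins the two scan tables with the DE flags, classifies every gene
(concordant / discordant / exclusive / neither), counts all eight Venn
regions, and emits the derived summary fractions with explicit
numerators/denominators. Recovery of the planted discordant genes is
checked against the ground-truth sidecar. Writes results/classification.tsv,
results/venn.json and results/overlap_summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from survscan.compare import classify_genes, summarize_fractions, venn_deg_survival

DATA = Path("results/data")
OUT = Path("results")


def main() -> int:
    scan_files = sorted(OUT.glob("scan_*.tsv"))
    if len(scan_files) != 2:
        print("run 02_scan_survival.py first", file=sys.stderr)
        return 1
    scan_a = pd.read_csv(scan_files[0], sep="\t", index_col=0)
    scan_b = pd.read_csv(scan_files[1], sep="\t", index_col=0)
    de = pd.read_csv(OUT / "de_results.tsv", sep="\t", index_col=0)

    la = scan_files[0].stem.replace("scan_", "")
    lb = scan_files[1].stem.replace("scan_", "")
    classes = classify_genes(scan_a, scan_b, labels=(la, lb))
    classes = classes.rename(columns={f"significant_{la}": "significant_A",
                                      f"significant_{lb}": "significant_B"})
    classes["deg"] = de["significant"].reindex(classes.index).fillna(False)
    classes.to_csv(OUT / "classification.tsv", sep="\t", float_format="%.10g")

    counts = classes["category"].value_counts()
    print("category counts:", counts.to_dict())
    discordant = sorted(classes.index[classes["category"] == "both-discordant"])
    print(f"discordant genes ({len(discordant)}): {discordant}")

    truth = json.loads((DATA / "ground_truth.json").read_text())

    def slug(x):
        return "".join(c if c.isalnum() else "_" for c in x)

    planted = []
    for g, b in truth["log_hr"].items():
        vals = {slug(k): v for k, v in b.items()}
        if (vals[la] > 0) != (vals[lb] > 0):
            planted.append(g)
    planted = sorted(planted)
    if planted:
        hit = set(discordant) & set(planted)
        print(f"planted discordant recovered: {len(hit)}/{len(planted)}")

    venn = venn_deg_survival(classes)
    (OUT / "venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
    print("venn regions:", {k: v for k, v in venn.items()
                            if k.startswith("deg_") and k != "deg_total"})

    sig_a, sig_b = classes["significant_A"], classes["significant_B"]
    summary = summarize_fractions(
        n_sig_a=int(sig_a.sum()), n_sig_b=int(sig_b.sum()),
        overlap=int((sig_a & sig_b).sum()),
        n_unique_genes=len(classes), n_deg=int(classes["deg"].sum()))
    (OUT / "overlap_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    print("summary:", json.dumps(summary))
    return 0


if __name__ == "__main__":
    sys.exit(main())
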