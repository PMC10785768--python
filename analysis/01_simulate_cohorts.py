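#!/usr/bin/env python
"""Generate the study-shaped synthetic dataset every later step analyses.

Two unbalanced cohorts (61 "Black/AA", 272 "White"), 1000 genes of
negative-binomial counts, nine overlapping gene sets (1143 memberships over
893 unique genes) and a five-pathway weight matrix. Planted truth:

* 12 genes with concordant survival effects (same log-HR sign in both
  cohorts), 8 genes with discordant effects (sign flips between cohorts),
* 30 genes differentially expressed between cohorts (|log2FC| 0.5–1),
* the WNT pathway's three driver genes carry weight-aligned effects.

Inputs are written to results/data/ in the pipeline's standard formats.
"""

import sys
from pathlib import Path

import numpy as np

from survscan import io
from survscan.simulate import SimConfig, generate_cohorts, generate_gene_sets, \
    generate_weight_matrix

SEED = 2024
OUT = Path("results/data")


def build_config() -> tuple:
    base = SimConfig(n_genes=1000, seed=SEED)
    genes = base.gene_ids()
    rng = np.random.default_rng(SEED)
    picks = rng.choice(len(genes), size=50, replace=False)

    effects = {}
    for i in picks[:12]:                        # concordant
        s = rng.choice([-1.0, 1.0])
        effects[genes[i]] = (0.5 * s, 0.5 * s)
    for i in picks[12:20]:                      # discordant
        s = rng.choice([-1.0, 1.0])
        effects[genes[i]] = (0.6 * s, -0.6 * s)
    de = {genes[i]: float(rng.choice([-1.0, -0.5, 0.5, 1.0]))
          for i in picks[20:50]}

    W, drivers = generate_weight_matrix(base)
    for g in drivers["WNT"]:
        w = float(W.loc[g, "WNT"])
        effects.setdefault(g, (0.7 * np.sign(w), 0.7 * np.sign(w)))

    cfg = SimConfig(n_genes=1000, seed=SEED, effect_table=effects, de_table=de)
    return cfg, W, drivers


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg, W, drivers = build_config()
    clinical, expression, truth = generate_cohorts(cfg)
    gene_sets = generate_gene_sets(cfg)
    truth.driver_genes = drivers

    io.write_clinical(clinical, OUT / "clinical.tsv")
    io.write_expression(expression, OUT / "expression.tsv")
    io.write_gmt(gene_sets, OUT / "gene_sets.gmt")
    io.write_weights(W, OUT / "weights.tsv")
    truth.to_json(OUT / "ground_truth.json")

    n_events = int(clinical["event"].sum())
    print(f"cohorts: {dict(clinical['cohort'].value_counts())}")
    print(f"events: {n_events}/{len(clinical)} "
          f"({100 * n_events / len(clinical):.0f}%)")
    print(f"gene sets: {len(gene_sets)} sets, "
          f"{sum(len(m) for m in gene_sets.values())} memberships, "
          f"{len(set().union(*map(set, gene_sets.values())))} unique genes")
    print(f"planted: {len(cfg.effect_table)} survival effects "
          f"(8 discordant), {len(cfg.de_table)} DE genes, "
          f"WNT drivers {drivers['WNT']}")
    print(f"wrote inputs to {OUT}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
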