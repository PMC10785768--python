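"""End-to-end orchestration of the two-cohort survival-disparity analysis.

Stage order: simulate-or-load → align → per-cohort optimal-cutoff scans over
the gene-set universe → differential expression → pathway-activity scoring
and score-survival scans → cross-cohort classification and Venn synthesis →
multivariable Cox models (including the gene × cohort interaction model).
Every stage is deterministic given the run seed; stage-level child seeds are
derived by stable hashing of the stage name so adding a stage never shifts
another stage's stream. Any stage error halts the run (fail-fast).
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, de, io, models, pathways, scan, simulate
from .config import ModelSpec, RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_all", "stage_seed"]

FLOAT_FMT = "%.10g"


def stage_seed(seed: int, stage: str) -> int:
    """Child seed for a named stage, stable across stage reordering."""
    return (zlib.crc32(f"{stage}:{seed}".encode()) ^ seed) & 0x7FFFFFFF


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _prepare_inputs(cfg: RunConfig, outdir: Path):
    if cfg.simulation is not None:
        sim_cfg = simulate.SimConfig(seed=stage_seed(cfg.seed, "simulate"),
                                     **cfg.simulation.model_dump())
        clinical, expression, truth = simulate.generate_cohorts(sim_cfg)
        if sim_cfg.n_genes >= simulate.PAPER_UNIQUE_GENES:
            gene_sets = simulate.generate_gene_sets(sim_cfg)
        else:
            k = max(2, sim_cfg.n_genes // 4)
            gene_sets = simulate.generate_gene_sets(
                sim_cfg, set_sizes={"SetA": k, "SetB": k},
                n_unique=min(sim_cfg.n_genes, 2 * k - max(1, k // 4)))
        weights, drivers = simulate.generate_weight_matrix(sim_cfg)
        truth.driver_genes = drivers

        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io.write_clinical(clinical, inputs / "clinical.tsv")
        io.write_expression(expression, inputs / "expression.tsv")
        io.write_gmt(gene_sets, inputs / "gene_sets.gmt")
        io.write_weights(weights, inputs / "weights.tsv")
        truth.to_json(inputs / "ground_truth.json")
        expr = io.ExpressionMatrix(values=expression, kind="counts")
    else:
        clinical = io.read_clinical(cfg.clinical_path, time_col=cfg.endpoint_col,
                                    event_col=cfg.event_col)
        expr = io.read_expression(cfg.expression_path)
        gene_sets = io.read_gmt(cfg.gene_sets_path) if cfg.gene_sets_path else {}
        weights = io.read_weights(cfg.weights_path) if cfg.weights_path else None
    return clinical, expr, gene_sets, weights


def _scan_stage(cfg, clinical, expr, gene_sets, outdir):
    universe = sorted({g for members in gene_sets.values() for g in members}
                      if gene_sets else set(expr.values.index))
    present = [g for g in universe if g in expr.values.index]
    scans = scan.scan_gene_set(
        expr.values, clinical, present, per_cohort=True,
        cohort_col=cfg.cohort_col, time_col=cfg.endpoint_col,
        event_col=cfg.event_col, bounds=tuple(cfg.scan_bounds),
        alpha=cfg.alpha, fdr_method=cfg.fdr_method, ties=cfg.ties)
    per_set = {}
    for name, members in gene_sets.items():
        per_set[name] = {
            str(label): compare.fraction(
                int(df.loc[df.index.intersection(members), "significant"].sum()),
                max(1, len(df.index.intersection(members))))
            for label, df in scans.items()
        }
    for label, df in scans.items():
        _write(df, outdir / f"scan_{_slug(label)}.tsv")
    return scans, per_set, present


def _slug(label) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in str(label))


def _model_stage(cfg, clinical, expr, scans, outdir):
    """Fit the configured multivariable models (or a default battery)."""
    labels = sorted(clinical[cfg.cohort_col].unique())
    gene = cfg.model_gene
    if gene is None:
        # default focus gene: smallest combined scan p across cohorts
        combined = None
        for df in scans.values():
            p = df["p"]
            combined = p if combined is None else combined * p
        gene = str(combined.idxmin())
    sf = de.size_factors(expr.values) if expr.kind == "counts" else None
    logexpr = (pathways.normalize_log(expr.values, sf)
               if sf is not None else expr.values)
    gvec = logexpr.loc[gene]
    gvec.name = gene

    specs = [ModelSpec.model_validate(m) if not isinstance(m, ModelSpec) else m
             for m in cfg.models]
    if not specs:
        base_cont = [gene, "age", "msi_mantis"]
        base_cat = {"sex": "Female", "stage": "I", cfg.cohort_col: str(labels[0])}
        cohort_ind = f"{cfg.cohort_col}[{labels[1]}]"
        strat_cat = {"sex": "Female", "stage": "I"}
        specs = [
            ModelSpec(name="main", continuous=base_cont, categorical=base_cat),
            ModelSpec(name="interaction", continuous=base_cont,
                      categorical=base_cat,
                      interactions=[(gene, cohort_ind)]),
            ModelSpec(name=f"stratified_{_slug(labels[0])}",
                      continuous=base_cont, categorical=strat_cat,
                      cohort=str(labels[0])),
            ModelSpec(name=f"stratified_{_slug(labels[1])}",
                      continuous=base_cont, categorical=strat_cat,
                      cohort=str(labels[1])),
        ]

    tables = {}
    for ms in specs:
        clin = clinical if ms.cohort is None else clinical[
            clinical[cfg.cohort_col].astype(str) == ms.cohort]
        spec = models.DesignSpec(continuous=list(ms.continuous),
                                 categorical=dict(ms.categorical),
                                 interactions=[tuple(x) for x in ms.interactions])
        X, t, e, dropped = models.build_design(
            clin, spec, gene_vector=gvec, time_col=cfg.endpoint_col,
            event_col=cfg.event_col)
        fit = models.fit_model(X, t, e, ties=cfg.ties)
        table = models.forest_table(fit, dropped)
        _write(table, outdir / f"forest_{_slug(ms.name)}.tsv")
        tables[ms.name] = {"table": table, "fit": fit, "dropped": dropped}
    return gene, tables


def run_all(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the run-summary dict (also written
    to ``<out_dir>/run_summary.json``)."""
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    clinical, expr, gene_sets, weights = _prepare_inputs(cfg, outdir)
    clinical, expr = io.align(clinical, expr)
    labels = sorted(clinical[cfg.cohort_col].unique())
    if cfg.cohort_labels is not None:
        want = set(map(str, cfg.cohort_labels))
        have = set(map(str, labels))
        if want != have:
            raise ValueError(f"cohort labels {sorted(want)} not found; table has {sorted(have)}")

    # --- per-cohort optimal-cutoff scans ---
    scans, per_set, universe = _scan_stage(cfg, clinical, expr, gene_sets, outdir)
    sig_sets = {label: set(df.index[df["significant"]]) for label, df in scans.items()}
    la, lb = labels[0], labels[1]

    # --- differential expression ---
    if expr.kind != "counts":
        raise ValueError("differential expression requires raw counts")
    de_tab = de.nb_wald(expr.values.loc[universe],
                        clinical[cfg.cohort_col].astype(str).to_numpy(),
                        lfc_thresh=cfg.de_lfc_thresh, p_thresh=cfg.de_p_thresh)
    _write(de_tab, outdir / "de_results.tsv")

    # --- pathway activity ---
    pathway_block = {}
    if weights is not None and weights.shape[1] > 0:
        sf = de.size_factors(expr.values)
        logm = pathways.normalize_log(expr.values, sf)
        score_cols = []
        for label in labels:
            cols = clinical.index[clinical[cfg.cohort_col] == label]
            z = pathways.zscore_genes(logm[cols])
            score_cols.append(pathways.progeny_scores(z, weights, top_k=cfg.top_k))
        scores = pd.concat(score_cols, axis=1)[clinical.index]
        _write(scores, outdir / "pathway_scores.tsv")
        surv = pathways.score_survival(scores, clinical, per_cohort=True,
                                       cohort_col=cfg.cohort_col,
                                       time_col=cfg.endpoint_col,
                                       event_col=cfg.event_col,
                                       bounds=tuple(cfg.scan_bounds),
                                       alpha=cfg.alpha, fdr_method="fixed",
                                       ties=cfg.ties)
        rows = []
        for label, df in surv.items():
            df = df.copy()
            df.insert(0, "cohort", str(label))
            rows.append(df)
        _write(pd.concat(rows), outdir / "pathway_survival.tsv")
        # cohort means of per-cohort z-scored activity are zero by
        # construction; the mean comparison uses pooled-z scores
        pooled_scores = pathways.progeny_scores(
            pathways.zscore_genes(logm), weights, top_k=cfg.top_k)
        mean_diff = pathways.cohort_mean_differences(pooled_scores, clinical,
                                                     cohort_col=cfg.cohort_col)
        _write(mean_diff, outdir / "pathway_mean_differences.tsv")
        pathway_block = {
            "survival": {str(label): df[["p", "hr"]].round(6).to_dict("index")
                         for label, df in surv.items()},
            "mean_abs_differences": mean_diff["abs_difference"].round(6).to_dict(),
        }

    # --- cross-cohort synthesis ---
    classes = compare.classify_genes(scans[la], scans[lb], alpha=cfg.alpha,
                                     labels=(str(la), str(lb)))
    classes = classes.rename(columns={
        f"significant_{la}": "significant_A", f"significant_{lb}": "significant_B"})
    classes["deg"] = de_tab["significant"].reindex(classes.index).fillna(False)
    _write(classes, outdir / "classification.tsv")
    venn = compare.venn_deg_survival(classes)
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True, default=_json_default)

    summary_counts = compare.summarize_fractions(
        n_sig_a=len(sig_sets[la]), n_sig_b=len(sig_sets[lb]),
        overlap=len(sig_sets[la] & sig_sets[lb]),
        n_features=sum(len(m) for m in gene_sets.values()) or len(universe),
        n_unique_genes=len(universe),
        n_deg=int(de_tab["significant"].sum()))

    # --- multivariable Cox models ---
    focus_gene, model_tables = _model_stage(cfg, clinical, expr, scans, outdir)

    summary = {
        "seed": cfg.seed,
        "cohorts": {str(la): int((clinical[cfg.cohort_col] == la).sum()),
                    str(lb): int((clinical[cfg.cohort_col] == lb).sum())},
        "n_events": int(clinical[cfg.event_col].sum()),
        "universe_genes": len(universe),
        "gene_sets": {name: len(m) for name, m in gene_sets.items()},
        "per_set_significant": per_set,
        "overlap_summary": summary_counts,
        "category_counts": classes["category"].value_counts().to_dict(),
        "venn": venn,
        "pathways": pathway_block,
        "focus_gene": focus_gene,
        "models": {name: {"aic": blk["fit"].aic,
                          "converged": bool(blk["fit"].converged),
                          "n": blk["fit"].n, "n_events": blk["fit"].n_events,
                          "dropped_missing": blk["dropped"]}
                   for name, blk in model_tables.items()},
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    logger.info("run_all: complete; outputs in %s", outdir)
    return summary
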