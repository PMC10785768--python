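"""Synthetic two-cohort clinical + expression generator with known truth.

Emulates the input structure of an unbalanced two-cohort TCGA-style study:
negative-binomial mRNA counts with per-sample library-size factors, and
overall-survival times from a proportional-hazards model whose per-gene
log-hazard coefficients may differ — including in sign — between cohorts,
under independent exponential censoring plus an administrative horizon.

Defaults reproduce the study regime the pipeline is designed for: cohorts
of 61 and 272 patients and an event fraction near 25% (roughly 80 events
across 333 patients) over a 120-month horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .de import size_factors as estimate_size_factors
from .pathways import normalize_log, zscore_genes

__all__ = ["SimConfig", "GroundTruth", "generate_cohorts", "generate_gene_sets",
           "generate_weight_matrix", "PAPER_SET_SIZES", "CRC_PATHWAYS"]

#: member counts of the nine signalling-pathway gene sets of the reference
#: study design (1143 memberships over 893 unique genes).
PAPER_SET_SIZES: dict = {
    "WNT": 117, "TP53": 26, "TGFB": 134, "PI3K-Akt": 338, "mTOR": 26,
    "MAPK": 253, "Cell Cycle": 119, "Apoptosis": 84, "Notch": 46,
}
PAPER_UNIQUE_GENES = 893

#: the five colorectal-cancer-relevant pathways of the weight-matrix scorer.
CRC_PATHWAYS = ("PI3K", "MAPK", "TGFB", "WNT", "p53")

STAGES = ("I", "II", "III", "IV")
STAGE_PROBS = (0.15, 0.33, 0.32, 0.20)
SITES = ("Ascending Colon", "Cecum", "Descending Colon", "Rectum",
         "Sigmoid Colon", "Transverse Colon")
SITE_PROBS = (0.14, 0.22, 0.04, 0.10, 0.30, 0.20)


@dataclass
class SimConfig:
    """Parameters of the two-cohort simulation.

    ``effect_table`` maps gene id → (log-HR in cohort A, log-HR in cohort B)
    per standard deviation of log-normalised expression; unlisted genes have
    no survival effect. ``de_table`` maps gene id → true log2 fold change of
    cohort B relative to cohort A. Cohort order is the insertion order of
    ``n_per_cohort``.
    """

    n_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: {"Black/AA": 61, "White": 272})
    n_genes: int = 200
    effect_table: Mapping[str, tuple] = field(default_factory=dict)
    baseline_hazard: float = 0.01      # events per month
    censor_rate: float = 0.03          # censorings per month
    admin_cutoff: float = 120.0        # months
    nb_mean_range: tuple = (20.0, 2000.0)
    nb_dispersion: float = 0.4         # Var = mu + alpha mu^2
    libsize_sigma: float = 0.25
    de_table: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_cohort) != 2:
            raise ValueError("exactly two cohorts required")
        if any(n < 2 for n in self.n_per_cohort.values()):
            raise ValueError("each cohort needs at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0 or self.nb_dispersion < 0:
            raise ValueError("censor_rate and nb_dispersion must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def gene_ids(self):
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    log_hr: dict          # gene -> {cohort: true log-HR per SD}
    log2_fc: dict         # gene -> true log2 fold change (B vs A)
    z_latent: pd.DataFrame  # standardized log-expression used in the hazard
    size_factors: pd.Series
    driver_genes: dict = field(default_factory=dict)  # pathway -> [genes]

    def to_json(self, path):
        payload = {
            "log_hr": self.log_hr,
            "log2_fc": self.log2_fc,
            "driver_genes": self.driver_genes,
            "size_factors": self.size_factors.round(6).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _nb_draw(rng, mean, alpha):
    """NB draws with Var = mu + alpha mu^2 (Poisson when alpha == 0)."""
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_cohorts(config: SimConfig):
    """Simulate (clinical table, counts matrix, ground truth).

    Event times follow h_j = baseline_hazard · exp(Σ_g β_{g, cohort(j)} z_{gj})
    with z the per-gene standardized log-normalised expression, inverted in
    closed form (per-sample constant hazard ⇒ exponential event times).
    Observed time is min(event, censoring, administrative cutoff).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in list(config.effect_table) + list(config.de_table):
        if g not in gene_pos:
            raise ValueError(f"effect gene {g!r} outside the simulated universe")

    cohorts = list(config.n_per_cohort)
    sizes = [int(config.n_per_cohort[c]) for c in cohorts]
    n = sum(sizes)
    cohort_of = np.repeat(cohorts, sizes)
    patient_ids = [f"P{i:04d}" for i in range(1, n + 1)]

    # --- expression ---
    log_lo, log_hi = np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1])
    base_mean = np.exp(rng.uniform(log_lo, log_hi, size=config.n_genes))
    s = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
    mean_matrix = np.tile(base_mean[:, None], (1, n))
    is_b = cohort_of == cohorts[1]
    for g, lfc in config.de_table.items():
        mean_matrix[gene_pos[g], is_b] *= 2.0 ** lfc
    mu = mean_matrix * s[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    expression = pd.DataFrame(counts, index=genes, columns=patient_ids)

    # --- latent hazard covariates: standardized log-normalised expression ---
    sf = estimate_size_factors(expression)
    z = zscore_genes(normalize_log(expression, sf))

    log_h = np.full(n, np.log(config.baseline_hazard))
    for g, (beta_a, beta_b) in config.effect_table.items():
        beta = np.where(is_b, beta_b, beta_a)
        log_h = log_h + beta * z.loc[g].to_numpy()
    hazard = np.exp(log_h)

    # --- survival: exponential inversion, independent censoring ---
    event_time = rng.exponential(1.0, size=n) / hazard
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_months = np.minimum(np.minimum(event_time, censor_time), config.admin_cutoff)
    event = (event_time <= np.minimum(censor_time, config.admin_cutoff)).astype(int)

    # --- nuisance clinical covariates (no effect on the hazard) ---
    clinical = pd.DataFrame({
        "cohort": cohort_of,
        "os_months": np.round(os_months, 4),
        "event": event,
        "age": np.clip(np.round(rng.normal(65, 11, size=n)), 30, 90).astype(int),
        "sex": rng.choice(["Female", "Male"], size=n),
        "stage": rng.choice(STAGES, size=n, p=STAGE_PROBS),
        "site": rng.choice(SITES, size=n, p=SITE_PROBS),
        "msi_mantis": np.round(np.clip(rng.normal(0.35, 0.05, size=n), 0.25, 1.4), 4),
    }, index=pd.Index(patient_ids, name="patient_id"))

    truth = GroundTruth(
        log_hr={g: {cohorts[0]: float(b[0]), cohorts[1]: float(b[1])}
                for g, b in config.effect_table.items()},
        log2_fc={g: float(v) for g, v in config.de_table.items()},
        z_latent=z,
        size_factors=pd.Series(s, index=patient_ids, name="true_size_factor"),
    )
    return clinical, expression, truth


def generate_gene_sets(config: SimConfig, set_sizes: Mapping[str, int] | None = None,
                       n_unique: int | None = None) -> dict:
    """Named, overlapping gene sets over the simulated gene universe.

    By default the nine reference pathway sizes are used (1143 memberships,
    893 unique genes), which requires ``config.n_genes >= 893``. The first
    ``n_unique`` gene ids are all used at least once; the remaining
    ``sum(sizes) - n_unique`` memberships re-use already-placed genes, so at
    least one gene is shared between two sets whenever sizes allow.
    """
    if set_sizes is None:
        set_sizes = PAPER_SET_SIZES
        n_unique = PAPER_UNIQUE_GENES if n_unique is None else n_unique
    if any(sz <= 0 for sz in set_sizes.values()):
        raise ValueError("gene-set sizes must be positive")
    total = sum(set_sizes.values())
    if n_unique is None:
        n_unique = min(total, config.n_genes)
    if n_unique > config.n_genes:
        raise ValueError(f"{n_unique} unique genes requested but universe has "
                         f"{config.n_genes}")
    if n_unique > total:
        raise ValueError("n_unique cannot exceed the total membership count")
    if max(set_sizes.values()) > config.n_genes:
        raise ValueError("a set size exceeds the gene universe")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6753]))
    genes = config.gene_ids()[:n_unique]
    names = list(set_sizes)
    sets: dict = {name: [] for name in names}

    # deal fresh genes round-robin proportionally, then patch with re-uses
    fresh = list(genes)
    rng.shuffle(fresh)
    n_fresh_per_set = {}
    remaining_fresh = n_unique
    remaining_total = total
    for name in names:
        sz = set_sizes[name]
        take = min(sz, max(0, round(remaining_fresh * sz / remaining_total)))
        n_fresh_per_set[name] = take
        remaining_fresh -= take
        remaining_total -= sz
    # distribute any rounding remainder
    i = 0
    while remaining_fresh > 0:
        name = names[i % len(names)]
        if n_fresh_per_set[name] < set_sizes[name]:
            n_fresh_per_set[name] += 1
            remaining_fresh -= 1
        i += 1

    pos = 0
    placed: list = []
    for name in names:
        k = n_fresh_per_set[name]
        sets[name] = list(fresh[pos:pos + k])
        pos += k
        placed.extend(sets[name])
    for name in names:
        need = set_sizes[name] - len(sets[name])
        if need > 0:
            pool = [g for g in placed if g not in set(sets[name])]
            reused = rng.choice(pool, size=need, replace=False)
            sets[name] = sets[name] + list(reused)
    return {name: sorted(sets[name]) for name in names}


def generate_weight_matrix(config: SimConfig, pathways=CRC_PATHWAYS,
                           n_drivers: int = 3, n_background: int = 40,
                           driver_weight: float = 2.5,
                           all_zero: bool = False):
    """A sparse genes × pathways weight matrix with designated driver genes.

    Each pathway receives ``n_drivers`` disjoint driver genes carrying the
    largest |weight| (alternating sign around ``driver_weight``) plus
    ``n_background`` small N(0, 0.3) weights. Returns ``(weights, drivers)``
    where ``drivers`` maps pathway → driver gene list (for the ground truth).
    """
    pathways = list(pathways)
    if not pathways:
        raise ValueError("at least one pathway required")
    need = len(pathways) * n_drivers
    if need > config.n_genes:
        raise ValueError("not enough genes for the requested driver count")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x77a7]))
    genes = config.gene_ids()
    W = pd.DataFrame(0.0, index=genes, columns=pathways)
    drivers = {}
    perm = rng.permutation(config.n_genes)
    pos = 0
    for pw in pathways:
        idx = perm[pos:pos + n_drivers]
        pos += n_drivers
        drivers[pw] = sorted(genes[i] for i in idx)
        signs = np.where(np.arange(n_drivers) % 2 == 0, 1.0, -1.0)
        W.loc[[genes[i] for i in idx], pw] = signs * driver_weight
        bg_pool = np.setdiff1d(np.arange(config.n_genes), idx)
        bg = rng.choice(bg_pool, size=min(n_background, bg_pool.size), replace=False)
        W.iloc[bg, W.columns.get_loc(pw)] = rng.normal(0.0, 0.3, size=bg.size)
    if all_zero:
        W.loc[:, :] = 0.0
    return W, drivers
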