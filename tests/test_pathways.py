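"""Normalisation, z-scoring and weight-matrix pathway scoring."""

import numpy as np
import pandas as pd
import pytest

from survscan.de import size_factors
from survscan.pathways import (cohort_mean_differences, normalize_log,
                               progeny_scores, score_survival, zscore_genes)
from survscan.scan import scan_matrix
from survscan.simulate import SimConfig, generate_cohorts, generate_weight_matrix


def frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        out = normalize_log(frame([[0.0, 0.0]]), pd.Series([1.0, 2.0], index=["S0", "S1"]))
        assert (out.to_numpy() == 0).all()

    def test_hand_arithmetic(self):
        out = normalize_log(frame([[2.0, 4.0]]), pd.Series([1.0, 2.0], index=["S0", "S1"]))
        np.testing.assert_allclose(out.to_numpy(), [[np.log2(3), np.log2(3)]])

    def test_joint_scaling_invariance(self, rng):
        counts = frame(rng.poisson(50, size=(4, 6)))
        s = pd.Series(np.exp(rng.normal(0, 0.2, 6)), index=counts.columns)
        a = normalize_log(counts, s)
        b = normalize_log(counts * 2, s * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            normalize_log(frame([[1.0]]), pd.Series([0.0], index=["S0"]))


class TestZscore:
    def test_hand_zscore(self):
        out = zscore_genes(frame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeroed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = zscore_genes(frame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]]))
        assert (out.iloc[0] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_row_means_vanish(self, rng):
        out = zscore_genes(frame(rng.normal(size=(10, 8))))
        assert np.abs(out.mean(axis=1)).max() < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_genes(frame([[1.0]]))


class TestProgenyScores:
    def test_all_zero_weights_give_zero_scores(self, rng):
        z = frame(rng.normal(size=(5, 4)))
        W = pd.DataFrame(0.0, index=z.index, columns=["P1", "P2"])
        scores = progeny_scores(z, W)
        assert (scores.to_numpy() == 0).all()

    def test_single_gene_identity(self, rng):
        z = frame(rng.normal(size=(3, 4)))
        W = pd.DataFrame(0.0, index=z.index, columns=["P"])
        W.loc["G1", "P"] = 1.0
        scores = progeny_scores(z, W)
        np.testing.assert_allclose(scores.loc["P"], z.loc["G1"])

    def test_hand_matrix_product(self):
        z = frame([[1.0, -1.0], [2.0, 0.0], [0.0, 3.0]])
        W = pd.DataFrame({"P1": [1.0, 0.5, 0.0], "P2": [0.0, 0.0, 2.0]},
                         index=z.index)
        scores = progeny_scores(z, W)
        np.testing.assert_allclose(scores.loc["P1"], [1 + 1.0, -1 + 0.0])
        np.testing.assert_allclose(scores.loc["P2"], [0.0, 6.0])

    def test_linearity(self, rng):
        z1 = frame(rng.normal(size=(6, 5)))
        z2 = frame(rng.normal(size=(6, 5)))
        W = pd.DataFrame(rng.normal(size=(6, 2)), index=z1.index,
                         columns=["P1", "P2"])
        s12 = progeny_scores(z1 + z2, W)
        pd.testing.assert_frame_equal(s12, progeny_scores(z1, W) + progeny_scores(z2, W))

    def test_top_k_restricts_to_largest_weights(self, rng):
        z = frame(rng.normal(size=(4, 3)))
        W = pd.DataFrame({"P": [10.0, 0.1, 0.2, 0.3]}, index=z.index)
        s1 = progeny_scores(z, W, top_k=1)
        np.testing.assert_allclose(s1.loc["P"], 10.0 * z.loc["G0"])

    def test_sample_permutation_permutes_columns(self, rng):
        z = frame(rng.normal(size=(5, 6)))
        W = pd.DataFrame(rng.normal(size=(5, 2)), index=z.index, columns=["P1", "P2"])
        perm = ["S3", "S0", "S5", "S1", "S4", "S2"]
        pd.testing.assert_frame_equal(progeny_scores(z[perm], W),
                                      progeny_scores(z, W)[perm])

    def test_no_overlap_rejected(self, rng):
        z = frame(rng.normal(size=(3, 4)))
        W = pd.DataFrame({"P": [1.0]}, index=["ABSENT"])
        with pytest.raises(ValueError, match="no overlapping"):
            progeny_scores(z, W)


@pytest.fixture(scope="module")
def planted():
    """Drivers of one pathway carry survival effects aligned with their
    weights; the other four pathways are null."""
    base = SimConfig(n_per_cohort={"A": 75, "B": 75}, n_genes=60, seed=42)
    W, drivers = generate_weight_matrix(base)
    effects = {g: (0.7 * np.sign(W.loc[g, "WNT"]),) * 2 for g in drivers["WNT"]}
    cfg = SimConfig(n_per_cohort={"A": 75, "B": 75}, n_genes=60, seed=42,
                    effect_table=effects)
    return cfg, W


class TestScoreSurvival:
    def _pathway_pvalues(self, cfg, W):
        clin, expr, _ = generate_cohorts(cfg)
        z = zscore_genes(normalize_log(expr, size_factors(expr)))
        scores = progeny_scores(z, W)
        res = scan_matrix(scores, clin["os_months"].to_numpy(),
                          clin["event"].to_numpy(), fdr_method="fixed")
        return res["p"]

    def test_planted_pathway_most_significant(self, planted):
        cfg, W = planted
        p = self._pathway_pvalues(cfg, W)
        assert p.idxmin() == "WNT"
        assert p["WNT"] < 0.05

    def test_planted_separates_from_null(self, planted):
        """The planted pathway's p lies far below the same seed's null run."""
        cfg, W = planted
        p_planted = self._pathway_pvalues(cfg, W)
        null_cfg = SimConfig(n_per_cohort=cfg.n_per_cohort, n_genes=cfg.n_genes,
                             seed=cfg.seed)
        p_null = self._pathway_pvalues(null_cfg, W)
        assert p_planted["WNT"] < p_null.min()

    def test_constant_scores_flagged(self, rng):
        clin, _, _ = generate_cohorts(
            SimConfig(n_per_cohort={"A": 10, "B": 10}, n_genes=5, seed=1))
        scores = pd.DataFrame(1.0, index=["P1"], columns=clin.index)
        out = score_survival(scores, clin, per_cohort=False)
        assert not out["pooled"]["scannable"].iloc[0]

    def test_cohort_mean_difference_machinery(self, rng):
        cfg = SimConfig(n_per_cohort={"A": 10, "B": 12}, n_genes=20, seed=2)
        clin, expr, _ = generate_cohorts(cfg)
        z = zscore_genes(normalize_log(expr, size_factors(expr)))
        W, _ = generate_weight_matrix(cfg, n_drivers=1, n_background=10)
        scores = progeny_scores(z, W)
        diff = cohort_mean_differences(scores, clin)
        a_cols = clin.index[clin["cohort"] == "A"]
        b_cols = clin.index[clin["cohort"] == "B"]
        expected = (scores[a_cols].mean(axis=1) - scores[b_cols].mean(axis=1)).abs()
        np.testing.assert_allclose(diff["abs_difference"], expected)
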