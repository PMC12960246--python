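"""A:C origin score: normalization, panel training, scoring, comparisons."""

import numpy as np
import pandas as pd
import pytest

from acrotype.origin import (NormalizedExpression, ScorePanel, ac_score,
                             compare_scores, log_ac_score,
                             median_of_ratios_size_factors, normalize_counts,
                             normalize_rnaseq, panel_product, score_cohort,
                             train_panel)
from acrotype.synthetic import SimulationConfig, simulate_expression


def _toy_panel():
    a = [f"A{i}" for i in range(10)]
    c = [f"C{i}" for i in range(10)]
    loadings = {g: 1.0 for g in a} | {g: -1.0 for g in c}
    return ScorePanel(acral_genes=a, cutaneous_genes=c, loadings=loadings,
                      component_index=1)


def _col(acral_val, cut_val):
    p = _toy_panel()
    return pd.Series({**{g: acral_val for g in p.acral_genes},
                      **{g: cut_val for g in p.cutaneous_genes}})


class TestNormalizeCounts:
    def test_background_floor_applied_before_log(self):
        raw = pd.DataFrame({"s1": [12.0, 100], "s2": [40.0, 100]},
                           index=["g1", "HK1"])
        norm = normalize_counts(raw, housekeeping=["HK1"], background=20)
        assert norm.values.loc["g1", "s1"] == pytest.approx(np.log2(20))

    def test_identical_housekeeping_profiles_give_unit_factors(self):
        raw = pd.DataFrame({"s1": [50.0, 80], "s2": [50.0, 80]},
                           index=["HK1", "g"])
        norm = normalize_counts(raw, ["HK1"])
        assert np.allclose(norm.values.loc["g"], np.log2(80))

    def test_three_sample_factor_arithmetic(self):
        # housekeeping geometric means 10, 20, 40 -> cohort mean is their
        # arithmetic mean; factor for s2 must make scaled geomean equal it
        raw = pd.DataFrame({
            "s1": [10.0, 300], "s2": [20.0, 300], "s3": [40.0, 300]},
            index=["HK1", "g"])
        norm = normalize_counts(raw, ["HK1"], background=1)
        mean_geo = (10 + 20 + 40) / 3
        expected = np.log2(300 * mean_geo / np.array([10, 20, 40]))
        assert np.allclose(norm.values.loc["g"].to_numpy(), expected)

    def test_zero_housekeeping_count_names_gene(self):
        raw = pd.DataFrame({"s1": [0.0, 5]}, index=["HK7", "g"])
        with pytest.raises(ValueError, match="HK7"):
            normalize_counts(raw, ["HK7"])


class TestNormalizeRnaseq:
    def test_size_factors_proportional_to_scalar_multiples(self):
        base = np.array([10.0, 50, 200, 1000])
        counts = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": 0.5 * base})
        sf = median_of_ratios_size_factors(counts)
        assert np.allclose(sf / sf["s1"], [1.0, 2.0, 0.5])

    def test_single_batch_is_identity(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (30, 6)).astype(float),
                              columns=[f"s{i}" for i in range(6)])
        a = normalize_rnaseq(counts)
        b = normalize_rnaseq(counts, batch=["x"] * 6)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_batch_shift_removed(self, rng):
        base = rng.poisson(100, (40, 4)).astype(float) + 1
        counts = pd.DataFrame(
            np.hstack([base, base * 2.0]),     # +1 log2 unit per gene
            columns=[f"s{i}" for i in range(8)])
        norm = normalize_rnaseq(counts, batch=["a"] * 4 + ["b"] * 4)
        left = norm.values.iloc[:, :4].to_numpy()
        right = norm.values.iloc[:, 4:].to_numpy()
        assert np.allclose(left, right, atol=1e-9)

    def test_singleton_batch_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (10, 3)).astype(float),
                              columns=list("abc"))
        with pytest.raises(ValueError, match="batch"):
            normalize_rnaseq(counts, batch=["x", "x", "y"])


class TestTrainPanel:
    def _zero_noise_training(self, cfg=None, n=10):
        cfg = cfg or SimulationConfig()
        labels = pd.DataFrame({
            "sample": [f"T{i}" for i in range(2 * n)],
            "origin": ["acral"] * n + ["cutaneous"] * n,
            "cluster": 0, "braf": False,
        })
        counts = simulate_expression(labels, cfg, seed=3, zero_noise=True)
        return normalize_rnaseq(counts), labels

    def test_planted_lineage_genes_recovered_exactly(self):
        cfg = SimulationConfig()
        norm, labels = self._zero_noise_training(cfg)
        panel = train_panel(norm, labels["origin"])
        assert set(panel.acral_genes) == set(cfg.genes.acral)
        assert set(panel.cutaneous_genes) == set(cfg.genes.cutaneous)

    def test_loadings_match_svd_oracle_on_toy_matrix(self):
        X = pd.DataFrame(
            [[5.0, 5, 1, 1], [4.8, 5.2, 1.1, 0.9], [1.0, 1, 5, 5],
             [1.2, 0.8, 5.1, 4.9], [3.0, 3, 3, 3], [2.0, 2, 2, 2]],
            index=[f"g{i}" for i in range(6)],
            columns=["a1", "a2", "c1", "c2"])
        norm = NormalizedExpression(values=X, transform="log2-counts",
                                    floor=1.5)
        panel = train_panel(norm, ["acral", "acral", "cutaneous",
                                   "cutaneous"], n_genes=2)
        # independent SVD on the column-centred samples x genes matrix
        M = X.to_numpy().T
        Mc = M - M.mean(axis=0)
        _, _, vt = np.linalg.svd(Mc, full_matrices=False)
        lead = vt[0]
        got = np.array([panel.loadings[g] for g in X.index])
        assert np.allclose(np.abs(got), np.abs(lead), atol=1e-9)

    def test_label_associated_component_found_behind_nuisance_axis(self):
        """With a dominant label-independent nuisance gradient, the class
        split lives on the second component and is still found."""
        cfg = SimulationConfig()
        norm, labels = self._zero_noise_training(cfg)
        vals = norm.values.copy()
        rng = np.random.default_rng(0)
        nuisance_genes = rng.choice(cfg.genes.background, 200, replace=False)
        gradient = np.linspace(-4, 4, vals.shape[1])
        rng.shuffle(gradient)     # independent of the class labels
        vals.loc[nuisance_genes] += np.outer(np.ones(200), gradient)
        norm2 = NormalizedExpression(values=vals, transform="log2-TPM+1",
                                     floor=norm.floor)
        panel = train_panel(norm2, labels["origin"])
        assert panel.component_index == 2
        assert set(panel.acral_genes) == set(cfg.genes.acral)

    def test_too_few_genes_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((5, 6)),
                         index=[f"g{i}" for i in range(5)])
        norm = NormalizedExpression(values=X, transform="log2-counts",
                                    floor=1.1)
        with pytest.raises(ValueError):
            train_panel(norm, ["acral"] * 3 + ["cutaneous"] * 3, n_genes=10)


class TestScoring:
    def test_panel_product_arithmetic(self):
        s = pd.Series({"g1": 2.0, "g2": 3.0})
        assert panel_product(s, ["g1", "g2"]) == pytest.approx(6.0)
        assert panel_product(s, []) == 1.0
        s5 = pd.Series({f"g{i}": 2.0 for i in range(5)})
        assert panel_product(s5, list(s5.index)) == pytest.approx(2.0 ** 5)

    def test_symmetric_input_scores_one(self):
        assert ac_score(_col(3.0, 3.0), _toy_panel()) == pytest.approx(1.0)

    def test_five_over_four_to_the_tenth(self):
        score = ac_score(_col(5.0, 4.0), _toy_panel())
        assert score == pytest.approx((5 / 4) ** 10, rel=1e-12)
        assert score == pytest.approx(9.313, abs=1e-3)

    def test_log_score_consistent(self):
        col = _col(5.0, 4.0)
        assert 2 ** log_ac_score(col, _toy_panel()) == \
            pytest.approx(ac_score(col, _toy_panel()), rel=1e-9)

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError):
            panel_product(pd.Series({"g1": 2.0}), ["g1", "gX"])

    def test_global_multiplicative_shift_invariance(self):
        """Equal panel sizes: multiplying all log2 values by a constant
        leaves the score unchanged."""
        panel = _toy_panel()
        col = pd.Series({g: v for g, v in zip(
            panel.acral_genes + panel.cutaneous_genes,
            np.linspace(2, 6, 20))})
        assert ac_score(col * 1.7, panel) == \
            pytest.approx(ac_score(col, panel), rel=1e-9)


class TestPanelProperties:
    def _trained(self, labels_order=("acral", "cutaneous")):
        cfg = SimulationConfig()
        n = 10
        labels = pd.DataFrame({
            "sample": [f"T{i}" for i in range(2 * n)],
            "origin": [labels_order[0]] * n + [labels_order[1]] * n,
            "cluster": 0, "braf": False,
        })
        counts = simulate_expression(labels, cfg, seed=3, zero_noise=True)
        return normalize_rnaseq(counts), labels

    def test_swapping_class_labels_inverts_scores(self):
        norm, labels = self._trained()
        p1 = train_panel(norm, labels["origin"])
        swapped = labels["origin"].map(
            {"acral": "cutaneous", "cutaneous": "acral"})
        p2 = train_panel(norm, swapped)
        assert set(p2.acral_genes) == set(p1.cutaneous_genes)
        assert set(p2.cutaneous_genes) == set(p1.acral_genes)
        col = norm.values.iloc[:, 0]
        assert ac_score(col, p2) == pytest.approx(1 / ac_score(col, p1),
                                                  rel=1e-9)

    def test_noise_free_lineages_perfectly_separated(self):
        """AUROC = 1 on zero-noise two-lineage data."""
        norm, labels = self._trained()
        panel = train_panel(norm, labels["origin"])
        res = score_cohort(norm, panel)
        acral = res.scores[labels["origin"].to_numpy() == "acral"]
        cut = res.scores[labels["origin"].to_numpy() == "cutaneous"]
        assert acral.min() > cut.max()

    def test_oncogene_module_outside_panel_leaves_scores_unchanged(self):
        """A planted BRAF-downstream program disjoint from the panel must
        not move the score."""
        cfg = SimulationConfig()
        cfg.braf_shift = 0.0          # isolate the oncogene program
        labels = pd.DataFrame({
            "sample": [f"S{i}" for i in range(8)],
            "origin": "acral", "cluster": 0,
            "braf": [False] * 4 + [True] * 4,
        })
        counts = simulate_expression(labels, cfg, seed=9, zero_noise=True)
        # size-factor normalization removes the compositional shift the
        # extra oncogene expression induces on the rest of the transcriptome
        norm = normalize_rnaseq(counts)
        panel = ScorePanel(
            acral_genes=cfg.genes.acral, cutaneous_genes=cfg.genes.cutaneous,
            loadings={g: 1.0 for g in cfg.genes.acral}
            | {g: -1.0 for g in cfg.genes.cutaneous},
            component_index=2)
        scores = score_cohort(norm, panel).scores
        assert scores.iloc[:4].to_numpy() == \
            pytest.approx(scores.iloc[4:].to_numpy(), rel=1e-6)


class TestCompareScores:
    def _result(self, x, y):
        s = pd.Series(np.r_[x, y],
                      index=[f"s{i}" for i in range(len(x) + len(y))])
        groups = pd.Series(["a"] * len(x) + ["b"] * len(y), index=s.index)
        from acrotype.origin import OriginScoreResult
        return OriginScoreResult(scores=s, log_scores=np.log2(s)), groups

    def test_identical_groups_p_one(self):
        res, g = self._result([1.0, 2, 3], [1.0, 2, 3])
        assert compare_scores(res, g).p_value == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        res, g = self._result(np.arange(1.0, 11), np.arange(20.0, 30))
        r = compare_scores(res, g)
        assert r.p_value == pytest.approx(2 / 184756, rel=1e-9)

    def test_one_sided_power_near_planted_level(self):
        """Shift chosen for ~80% one-sided power at alpha=.05, n=10 vs 67."""
        rng = np.random.default_rng(17)
        # normal shift delta with n1=10, n2=67: power 0.80 at delta ~ 0.93 sd
        delta = 0.93
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            res, g = self._result(rng.normal(0, 1, 10) + 10,
                                  rng.normal(delta, 1, 67) + 10)
            r = compare_scores(res, g, alternative="less",
                               order=("a", "b"))
            hits += r.p_value < 0.05
        assert hits / n_rep == pytest.approx(0.80, abs=0.07)

    def test_empty_group_rejected(self):
        res, g = self._result([1.0, 2], [3.0])
        bad = pd.Series(["a", "a", "a"], index=g.index)
        with pytest.raises(ValueError):
            compare_scores(res, bad)
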