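"""Consensus clustering, stability metrics and two-level signatures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from acrotype.cluster import (consensus_partition, evaluate_stability,
                              gene_modules, jaccard_partitions,
                              ora_enrichment, pair_concordance,
                              preprocess_matrix, qc_rnaseq_samples,
                              signature_genes)


def _metrics_fixture():
    """77 samples, exactly 33 failing one of the two read-level rules."""
    rows = []
    for i in range(77):
        if i < 20:       # fail: under 25M reads
            rows.append((f"s{i}", 24_900_000, 1e6, 1e6, 20e6))
        elif i < 33:     # fail: ambiguous + no-feature > gene counts
            rows.append((f"s{i}", 30e6, 9e6, 8e6, 13e6))
        else:
            rows.append((f"s{i}", 30e6, 2e6, 1e6, 25e6))
    return pd.DataFrame(rows, columns=["sample", "total_reads",
                                       "ambiguous_reads",
                                       "no_feature_reads", "gene_reads"])


class TestSampleQC:
    def test_read_count_boundary(self):
        m = pd.DataFrame({
            "sample": ["lo", "hi"],
            "total_reads": [24_999_999, 25_000_000],
            "ambiguous_reads": [0, 0], "no_feature_reads": [0, 0],
            "gene_reads": [20e6, 20e6],
        })
        out = qc_rnaseq_samples(m).set_index("sample")
        assert not out.loc["lo", "keep"]
        assert out.loc["hi", "keep"]

    def test_ambiguous_rule_is_strict_inequality(self):
        m = pd.DataFrame({
            "sample": ["eq", "gt"],
            "total_reads": [30e6, 30e6],
            "ambiguous_reads": [5e6, 5e6], "no_feature_reads": [5e6, 5e6],
            "gene_reads": [10e6, 9_999_999],
        })
        out = qc_rnaseq_samples(m).set_index("sample")
        assert out.loc["eq", "keep"]          # equality keeps
        assert not out.loc["gt", "keep"]

    def test_77_sample_fixture_keeps_44(self):
        out = qc_rnaseq_samples(_metrics_fixture())
        assert int(out["keep"].sum()) == 44

    def test_negative_counts_rejected(self):
        m = _metrics_fixture()
        m.loc[0, "total_reads"] = -1
        with pytest.raises(ValueError):
            qc_rnaseq_samples(m)


class TestPreprocess:
    def test_na_rule_boundary(self):
        n = 20
        row_25 = [np.nan] * 5 + list(range(15))       # exactly 25%
        row_26 = [np.nan] * 6 + list(range(14))       # more than 25%
        m = pd.DataFrame([row_25, row_26, list(range(20)),
                          list(np.linspace(0, 5, 20))],
                         index=["keep_na", "drop_na", "keep1", "keep2"])
        out = preprocess_matrix(m, min_var_pct=0)
        assert "keep_na" in out.index
        assert "drop_na" not in out.index

    def test_constant_row_removed(self):
        m = pd.DataFrame([[1.0] * 10, list(range(10)),
                          list(np.linspace(3, 9, 10))],
                         index=["const", "a", "b"])
        out = preprocess_matrix(m, min_var_pct=0)
        assert "const" not in out.index

    def test_winsorization_matches_percentile_oracle(self):
        row = np.r_[np.zeros(19), 100.0]
        m = pd.DataFrame([row, np.linspace(0, 1, 20)], index=["spiky", "r"])
        out = preprocess_matrix(m, min_var_pct=0)
        want_hi = np.percentile(row, 95)       # linear interpolation rule
        assert out.loc["spiky"].max() == pytest.approx(want_hi)

    def test_na_imputed_with_row_median(self):
        row = [1.0, 2.0, np.nan, 3.0, 100.0] + [2.0] * 5
        m = pd.DataFrame([row, list(range(10))], index=["g", "r"])
        out = preprocess_matrix(m, winsor=(0, 100), min_var_pct=0)
        assert out.loc["g"].iloc[2] == pytest.approx(2.0)

    def test_empty_after_filtering_rejected(self):
        m = pd.DataFrame([[1.0] * 5, [2.0] * 5])
        with pytest.raises(ValueError):
            preprocess_matrix(m)


class TestStabilityMetrics:
    def test_binary_consensus_gives_one(self):
        c = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                      [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float)
        np.fill_diagonal(c, 1.0)
        m = evaluate_stability(c, [], np.array([1, 1, 2, 2]))
        assert m["one_minus_pac"] == 1.0

    def test_all_ambiguous_gives_zero(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        m = evaluate_stability(c, [], np.array([1, 1, 2, 2]))
        assert m["one_minus_pac"] == 0.0

    def test_handbuilt_matrix_matches_bruteforce(self):
        c = np.array([
            [1.0, 0.95, 0.5, 0.05],
            [0.95, 1.0, 0.12, 0.0],
            [0.5, 0.12, 1.0, 0.88],
            [0.05, 0.0, 0.88, 1.0]])
        labels = np.array([1, 1, 2, 2])
        parts = [(np.array([0, 1, 2]), np.array([0, 0, 1])),
                 (np.array([1, 2, 3]), np.array([0, 1, 1]))]
        m = evaluate_stability(c, parts, labels,
                               prev_labels=np.array([1, 1, 1, 2]))
        # PAC oracle: off-diagonals strictly inside (0.1, 0.9)
        off = [0.95, 0.5, 0.05, 0.12, 0.0, 0.88]
        pac = np.mean([(0.1 < v < 0.9) for v in off])
        assert m["pac"] == pytest.approx(pac)
        # concordance oracle
        conc = np.mean([pair_concordance(lab, labels[idx])
                        for idx, lab in parts])
        assert m["concordance"] == pytest.approx(conc)
        # jaccard oracle by explicit pair sets
        same1 = {(0, 1), (0, 2), (1, 2)}
        same2 = {(0, 1), (2, 3)}
        want = len(same1 & same2) / len(same1 | same2)
        assert m["jaccard_vs_prev"] == pytest.approx(want)

    def test_sharpening_does_not_decrease_one_minus_pac(self, rng):
        c = rng.uniform(0, 1, size=(8, 8))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        sharp = np.where(c >= 0.5, np.minimum(c * 1.3, 1.0), c * 0.5)
        np.fill_diagonal(sharp, 1.0)
        lab = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        m1 = evaluate_stability(c, [], lab)
        m2 = evaluate_stability(sharp, [], lab)
        assert m2["one_minus_pac"] >= m1["one_minus_pac"] - 1e-12


def _planted_matrix(n_per=12, n_genes=150, sep=3.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    blocks = []
    truth = []
    for k in range(3):
        centre = np.zeros(n_genes)
        centre[k * (n_genes // 3):(k + 1) * (n_genes // 3)] = sep
        X = centre[None, :] + rng.normal(0, noise, (n_per, n_genes))
        blocks.append(X)
        truth += [k] * n_per
    M = np.vstack(blocks).T
    cols = [f"s{i}" for i in range(3 * n_per)]
    return pd.DataFrame(M, columns=cols), np.array(truth)


class TestConsensusPartition:
    @pytest.mark.parametrize("base", ["kmeans", "pam", "hclust"])
    def test_planted_three_clusters_recovered(self, base):
        mat, truth = _planted_matrix()
        res = consensus_partition(mat, base_method=base,
                                  k_range=(2, 3, 4), n_resamples=30,
                                  seed=5)
        assert res.best_k == 3
        ari = adjusted_rand_score(truth, res.labels[3])
        assert ari >= 0.9
        assert res.metrics.loc[3, "one_minus_pac"] >= 0.9

    def test_noise_matrix_less_stable_than_planted(self, rng):
        mat, _ = _planted_matrix()
        noise = pd.DataFrame(rng.normal(size=mat.shape),
                             columns=mat.columns)
        res_p = consensus_partition(mat, k_range=(3,), n_resamples=30,
                                    seed=2)
        res_n = consensus_partition(noise, k_range=(3,), n_resamples=30,
                                    seed=2)
        assert res_n.metrics.loc[3, "one_minus_pac"] < \
            res_p.metrics.loc[3, "one_minus_pac"]

    def test_consensus_matrix_is_valid(self):
        mat, _ = _planted_matrix(n_per=8)
        res = consensus_partition(mat, k_range=(2, 3), n_resamples=20,
                                  seed=1)
        for k, c in res.consensus.items():
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert c.min() >= 0 and c.max() <= 1 + 1e-12

    def test_subsample_too_small_rejected(self):
        mat, _ = _planted_matrix(n_per=3)
        with pytest.raises(ValueError):
            consensus_partition(mat, k_range=(8,),
                                subsample_fraction=0.8)

    def test_method_sweep_selects_k3_on_planted_fixture(self):
        from acrotype.cluster import consensus_sweep
        mat, truth = _planted_matrix(n_per=8)
        best, summary = consensus_sweep(mat, k_range=(2, 3, 4),
                                        n_resamples=12, seed=3)
        assert best.best_k == 3
        assert len(summary) == 9          # 3 feature x 3 base methods
        assert adjusted_rand_score(truth, best.best_labels()) >= 0.9

    def test_deterministic_given_seed(self):
        mat, _ = _planted_matrix(n_per=6)
        r1 = consensus_partition(mat, k_range=(2, 3), n_resamples=15, seed=9)
        r2 = consensus_partition(mat, k_range=(2, 3), n_resamples=15, seed=9)
        assert np.array_equal(r1.labels[3], r2.labels[3])
        assert np.allclose(r1.consensus[3], r2.consensus[3])


class TestSignatureGenes:
    def test_constant_gene_not_significant(self):
        m = pd.DataFrame([[5.0] * 9,
                          [1, 1, 1, 5, 5, 5, 9, 9, 9]],
                         index=["flat", "sig"], dtype=float)
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        out = signature_genes(m, labels)
        assert not out.loc["flat", "significant"]
        assert out.loc["flat", "p"] == 1.0

    def test_f_statistic_matches_anova_oracle(self):
        x = [3.1, 2.9, 3.5, 5.0, 5.2, 4.8, 9.1, 8.9, 9.3]
        m = pd.DataFrame([x], index=["g"], dtype=float)
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        out = signature_genes(m, labels)
        F, p = sps.f_oneway(x[:3], x[3:6], x[6:])
        assert out.loc["g", "F"] == pytest.approx(F, abs=1e-9)
        assert out.loc["g", "p"] == pytest.approx(p, abs=1e-12)

    def test_assigned_to_argmax_cluster(self):
        m = pd.DataFrame([[1, 1, 9, 9, 1, 1]], index=["g"], dtype=float)
        out = signature_genes(m, [1, 1, 2, 2, 3, 3])
        assert out.loc["g", "assigned_cluster"] == 2

    def test_planted_signature_recall(self, cohort):
        """>= 95% of planted module genes recovered at q < 0.05."""
        cfg = cohort.config
        log_expr = np.log2(cohort.expression + 1.0)
        labels = cohort.labels.set_index("sample").loc[
            log_expr.columns, "cluster"].to_numpy()
        out = signature_genes(log_expr, labels)
        planted = [g for mod in cfg.genes.modules for g in mod]
        recall = out.loc[planted, "significant"].mean()
        assert recall >= 0.95

    def test_small_cluster_rejected(self):
        m = pd.DataFrame([[1.0, 2, 3]])
        with pytest.raises(ValueError):
            signature_genes(m, [1, 2, 2])


class TestGeneModules:
    def _profiles(self):
        # three shapes: up in cluster 1 / 2 / 3
        rows = []
        idx = []
        for k in range(3):
            for i in range(3):
                base = np.ones(6)
                base[2 * k:2 * k + 2] = 5 + 0.1 * i
                rows.append(base)
                idx.append(f"g{k}_{i}")
        return pd.DataFrame(rows, index=idx, dtype=float), \
            [1, 1, 2, 2, 3, 3]

    def test_planted_shapes_recovered_exactly(self):
        m, labels = self._profiles()
        res = gene_modules(m, labels, k=3, seed=0)
        for k in range(3):
            mods = {res.assignments[f"g{k}_{i}"] for i in range(3)}
            assert len(mods) == 1
        assert set(res.modules) == {"M1", "M2", "M3"}

    def test_gene_order_invariance(self):
        m, labels = self._profiles()
        res1 = gene_modules(m, labels, k=3, seed=0)
        perm = m.sample(frac=1, random_state=3)
        res2 = gene_modules(perm, labels, k=3, seed=0)
        for g in m.index:
            assert res1.assignments[g] == res2.assignments[g]

    def test_profiles_row_standardized(self):
        m, labels = self._profiles()
        res = gene_modules(m, labels, k=3, seed=0)
        # module profiles are means of per-gene standardized profiles
        assert res.profiles.mean(axis=1).abs().max() < 1e-9

    def test_wss_not_worse_than_exhaustive_oracle(self):
        """k-means with 25 starts reaches the optimum on 9 genes."""
        m, labels = self._profiles()
        lab = np.asarray(labels)
        levels = np.unique(lab)
        prof = np.column_stack([m.to_numpy()[:, lab == lv].mean(axis=1)
                                for lv in levels])
        z = (prof - prof.mean(1, keepdims=True)) / \
            prof.std(1, keepdims=True)

        def wss(assign):
            tot = 0.0
            for k in set(assign):
                pts = z[[i for i, a in enumerate(assign) if a == k]]
                tot += ((pts - pts.mean(0)) ** 2).sum()
            return tot

        best = min(wss(assign) for assign in
                   itertools.product(range(3), repeat=9)
                   if len(set(assign)) == 3)
        res = gene_modules(m, labels, k=3, seed=0)
        codes = pd.Categorical(res.assignments).codes
        assert wss(list(codes)) <= best + 1e-9

    def test_k_exceeding_genes_rejected(self):
        m, labels = self._profiles()
        with pytest.raises(ValueError):
            gene_modules(m.iloc[:2], labels, k=3)


class TestORA:
    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(50)]
        out = ora_enrichment(uni[:10], {"set": uni[40:]}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_hypergeometric_matches_direct_summation(self):
        from math import comb

        uni = [f"g{i}" for i in range(100)]
        module = uni[:20]
        gset = uni[15:25]          # overlap 5
        out = ora_enrichment(module, {"s": gset}, uni)
        want = sum(comb(10, k) * comb(90, 20 - k) for k in range(5, 11)) \
            / comb(100, 20)
        assert out.loc[0, "p"] == pytest.approx(want, rel=1e-9)

    def test_module_equals_set_is_smallest_p(self):
        uni = [f"g{i}" for i in range(30)]
        module = uni[:6]
        p_exact = ora_enrichment(module, {"s": module}, uni).loc[0, "p"]
        p_partial = ora_enrichment(module, {"s": module[:5] + uni[20:21]},
                                   uni).loc[0, "p"]
        assert p_exact < p_partial

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["a"], {"s": ["a"]}, [])
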