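import math
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats as sps

from scregact import (ExpressionMatrix, NormState, greedy_partial_correlation,
                      infer_network, marginal_screen, moderated_t_test,
                      select_tissue_specific_tfs, simulate_bulk_multitissue)
from scregact.netinfer import (correlation_pvalues,
                               partial_correlations_for_target)


def _mat(values, labels=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(values.shape[0])],
                            [f"s{i}" for i in range(values.shape[1])],
                            column_labels=labels,
                            norm_state=NormState.LOG2_NORMALIZED)


def _data_with_exact_cov(cov, n, rng):
    """Rows with sample covariance exactly ``cov`` (ddof=1)."""
    k = cov.shape[0]
    g = rng.normal(size=(k, n))
    g = g - g.mean(axis=1, keepdims=True)
    c = np.cov(g, ddof=1)
    w = np.linalg.cholesky(np.linalg.inv(c))
    target = np.linalg.cholesky(cov)
    return target @ w.T @ g


class TestCorrelationScreen:
    def test_pvalues_match_pearsonr_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=40)
            y = 0.3 * x + rng.normal(size=40)
            r, p_ref = sps.pearsonr(x, y)
            p = correlation_pvalues(np.array([r]), 40)[0]
            assert p == pytest.approx(p_ref, rel=1e-6)

    def test_gtex_scale_significance_boundary(self):
        # at n = 8555 samples, |r| = 0.06 clears p <= 1e-6 but 0.05 does not
        p_hi = correlation_pvalues(np.array([0.06]), 8555)[0]
        p_lo = correlation_pvalues(np.array([0.05]), 8555)[0]
        assert p_hi <= 1e-6 < p_lo

    def test_no_filter_limit_keeps_all_pairs(self, rng):
        x = _mat(rng.normal(size=(20, 30)))
        cands = marginal_screen(x, ["g0", "g1"], sigth=1.0, spTH=1.0,
                                minNtgts=1)
        assert cands.mask.all()
        assert cands.target_ids.size == 18  # TFs are never targets

    def test_planted_block_recovery(self, rng):
        # 10 TFs each driving 30 disjoint targets; independent noise elsewhere
        n, n_tfs, per = 500, 10, 30
        tfs = rng.normal(size=(n_tfs, n))
        targets = np.repeat(tfs, per, axis=0) + rng.normal(
            0, 0.7, (n_tfs * per, n))
        noise = rng.normal(size=(100, n))
        values = np.vstack([tfs, targets, noise])
        x = _mat(values)
        tf_ids = [f"g{i}" for i in range(n_tfs)]
        cands = marginal_screen(x, tf_ids, sigth=1e-6, spTH=1.0, minNtgts=10)
        planted = np.zeros_like(cands.mask)
        for j in range(n_tfs):
            planted[j * per:(j + 1) * per, j] = True
        assert (cands.mask & planted).sum() == planted.sum()  # full recall
        extra = cands.mask & ~planted
        assert extra.sum() <= 2  # at most a couple of chance edges

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            marginal_screen(_mat(rng.normal(size=(5, 3))), ["g0"])

    def test_empty_tf_list(self, rng):
        with pytest.raises(ValueError, match="empty"):
            marginal_screen(_mat(rng.normal(size=(5, 10))), [])


class TestPartialCorrelation:
    def test_single_regulator_equals_marginal_r(self, rng):
        data = rng.normal(size=(2, 60))
        data[1] += 0.5 * data[0]
        pc = partial_correlations_for_target(data)
        r = np.corrcoef(data)[0, 1]
        assert pc[0] == pytest.approx(r, abs=1e-12)

    def test_three_variable_closed_form(self, rng):
        # order (g, f1, f2): first-order partial corr of g,f2 given f1
        cov = np.array([[1.0, 0.6, 0.5],
                        [0.6, 1.0, 0.7],
                        [0.5, 0.7, 1.0]])
        data = _data_with_exact_cov(cov, 50, rng)
        pc = partial_correlations_for_target(data)
        expected = (0.5 - 0.6 * 0.7) / math.sqrt((1 - 0.6 ** 2)
                                                 * (1 - 0.7 ** 2))
        assert pc[1] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.140, abs=5e-4)

    def test_matches_residual_regression_oracle(self, rng):
        # inverse-covariance identity vs brute-force residual correlation
        for _ in range(30):
            data = rng.normal(size=(6, 80))
            data += 0.4 * rng.normal(size=(6, 1))  # shared component
            pc = partial_correlations_for_target(data)
            for j in range(1, 6):
                others = [i for i in range(1, 6) if i != j]
                z = data[others].T
                z = np.column_stack([np.ones(len(z)), z])
                rg = data[0] - z @ np.linalg.lstsq(z, data[0], rcond=None)[0]
                rf = data[j] - z @ np.linalg.lstsq(z, data[j], rcond=None)[0]
                oracle = np.corrcoef(rg, rf)[0, 1]
                assert pc[j - 1] == pytest.approx(oracle, abs=1e-8)

    def test_chain_pruned_at_partial_correlation(self, rng):
        # regulatory chain TF1 -> TF_mid -> G_far: conditioning on the
        # intermediate regulator removes the indirect TF1 -> G_far edge
        kept_direct = kept_indirect = 0
        for _ in range(20):
            n = 1000
            tf1 = rng.normal(size=n)
            tf_mid = tf1 + 0.5 * rng.normal(size=n)
            g_far = tf_mid + 0.5 * rng.normal(size=n)
            x = _mat(np.vstack([tf1, tf_mid, g_far,
                                rng.normal(size=(5, n))]))
            cands = marginal_screen(x, ["g0", "g1"], sigth=1e-6, spTH=1.0,
                                    minNtgts=1)
            net = greedy_partial_correlation(x, cands, pcorth=0.2,
                                             minNtgts=1)
            gi = list(net.target_ids).index("g2")
            for j, tf in enumerate(net.tf_ids):
                if net.adjacency[gi, j] != 0:
                    if tf == "g1":
                        kept_direct += 1
                    if tf == "g0":
                        kept_indirect += 1
        assert kept_direct == 20
        assert kept_indirect == 0

    def test_singular_covariance_names_target(self, rng):
        n = 30
        tf1 = rng.normal(size=n)
        tf2 = tf1.copy()  # exactly collinear regulators
        g = tf1 + 0.1 * rng.normal(size=n)
        x = _mat(np.vstack([tf1, tf2, g]))
        cands = marginal_screen(x, ["g0", "g1"], sigth=1.0, spTH=1.0,
                                minNtgts=1)
        with pytest.raises(np.linalg.LinAlgError, match="g2"):
            greedy_partial_correlation(x, cands, pcorth=0.2, minNtgts=1)


class TestModeratedT:
    def _groups(self):
        return np.arange(0, 6), np.arange(6, 12)

    def test_no_shrinkage_limit_is_ordinary_t(self, rng):
        x = _mat(rng.normal(size=(100, 12)))
        g1, g2 = self._groups()
        res = moderated_t_test(x, g1, g2, prior_df=0)
        ref = sps.ttest_ind(x.values[:, g1], x.values[:, g2], axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_full_shrinkage_limit_shares_variance(self, rng):
        x = _mat(rng.normal(size=(100, 12)))
        g1, g2 = self._groups()
        res = moderated_t_test(x, g1, g2, prior_df=np.inf)
        dmean = x.values[:, g1].mean(axis=1) - x.values[:, g2].mean(axis=1)
        expected = dmean / (math.sqrt(res.s0sq) * math.sqrt(1 / 6 + 1 / 6))
        np.testing.assert_allclose(res["t"], expected, atol=1e-10)

    def test_null_pvalues_uniform(self, rng):
        x = _mat(rng.normal(size=(2000, 16)))
        res = moderated_t_test(x, np.arange(8), np.arange(8, 16))
        ks = sps.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_adjusted_p_never_below_raw(self, rng):
        x = _mat(rng.normal(size=(200, 12)))
        res = moderated_t_test(x, *self._groups())
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert res["p"].between(0, 1).all()

    def test_matches_limma_oracle(self, rng, tmp_path):
        # independent empirical-Bayes implementation (Bioconductor limma)
        sd = np.exp(rng.normal(0.0, 0.5, (150, 1)))  # gene-wise variances
        x = rng.normal(size=(150, 12)) * sd
        x[:40, :6] += rng.normal(1.0, 0.5, (40, 1))
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("x.tsv", sep="\\t"))
            design <- cbind(Intercept=1, Diff=c(rep(1,6), rep(0,6)))
            fit <- eBayes(lmFit(x, design))
            out <- cbind(fit$t[, "Diff"], fit$p.value[, "Diff"],
                         rep(fit$df.prior, nrow(x)),
                         rep(fit$s2.prior, nrow(x)))
            write.table(out, "limma.tsv", sep="\\t",
                        row.names=FALSE, col.names=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "limma.tsv", delimiter="\t")
        mat = _mat(x)
        res = moderated_t_test(mat, np.arange(6), np.arange(6, 12))
        assert res.d0 == pytest.approx(ref[0, 2], rel=1e-4)
        assert res.s0sq == pytest.approx(ref[0, 3], rel=1e-4)
        np.testing.assert_allclose(res["t"], ref[:, 0], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref[:, 1], rtol=1e-6)

    def test_zero_variance_group_rejected(self):
        x = _mat(np.tile([[1.0], [2.0]], (1, 8)))
        with pytest.raises(ValueError, match="zero variance"):
            moderated_t_test(x, np.arange(4), np.arange(4, 8))


class TestTissueSelection:
    def test_planted_tfs_exactly_selected(self):
        bulk, truth = simulate_bulk_multitissue(seed=5)
        cands = marginal_screen(bulk, truth.tf_ids, sigth=1e-6, spTH=1.0)
        net = greedy_partial_correlation(bulk, cands)
        sel = select_tissue_specific_tfs(bulk, net, "Tissue1")
        expected = {tf for tf, t in truth.tf_tissue.items() if t == "Tissue1"}
        assert set(sel.tf_ids) == expected

    def test_confounder_comparison_rejects_shared_tf(self):
        # a TF equally high in toi and the confounding tissue must fail B
        bulk, truth = simulate_bulk_multitissue(seed=5)
        shift = truth.extras["shift"]
        null_tf = truth.tf_ids[-1]
        i = list(bulk.gene_ids).index(null_tf)
        both = np.isin(bulk.column_labels, ["Tissue1", "Tissue2"])
        bulk.values[i, both] += shift
        cands = marginal_screen(bulk, truth.tf_ids, sigth=1e-6, spTH=1.0)
        net = greedy_partial_correlation(bulk, cands)
        selA = select_tissue_specific_tfs(bulk, net, "Tissue1")
        assert null_tf in set(selA.tf_ids)
        selB = select_tissue_specific_tfs(bulk, net, "Tissue1",
                                          cft=["Tissue2"])
        assert null_tf not in set(selB.tf_ids)

    def test_absent_tissue_errors(self):
        bulk, truth = simulate_bulk_multitissue(seed=5, n_genes=600,
                                                n_specific_tfs=2,
                                                n_null_tfs=2,
                                                targets_per_tf=10)
        cands = marginal_screen(bulk, truth.tf_ids, sigth=1e-6, spTH=1.0)
        net = greedy_partial_correlation(bulk, cands)
        with pytest.raises(ValueError, match="absent"):
            select_tissue_specific_tfs(bulk, net, "Kidney")


@pytest.fixture(scope="module")
def planted():
    bulk, truth = simulate_bulk_multitissue(
        n_tissues=5, n_per_tissue=150, n_genes=1500, targets_per_tf=20,
        seed=11)
    return bulk, truth


class TestInferNetwork:
    def test_planted_regulons_recovered(self, planted):
        bulk, truth = planted
        net = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        inferred = {(tf, g) for j, tf in enumerate(net.tf_ids)
                    for g in net.target_ids[net.adjacency[:, j] != 0]}
        planted_edges = {(tf, g) for tf in net.tf_ids
                         for g in truth.regulons[tf].index}
        tp = len(inferred & planted_edges)
        assert tp / len(inferred) >= 0.9       # precision
        assert tp / len(planted_edges) >= 0.9  # recall

    def test_edge_signs_match_truth(self, planted):
        bulk, truth = planted
        net = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        for j, tf in enumerate(net.tf_ids):
            reg = truth.regulons[tf]
            for gi, g in enumerate(net.target_ids):
                if net.adjacency[gi, j] != 0 and g in reg.index:
                    assert net.adjacency[gi, j] == reg[g]

    def test_lower_pcorth_gives_superset(self, planted):
        bulk, truth = planted
        hi = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05,
                           pcorth=0.2)
        lo = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05,
                           pcorth=0.1)
        hi_edges = {(tf, g) for j, tf in enumerate(hi.tf_ids)
                    for g in hi.target_ids[hi.adjacency[:, j] != 0]}
        lo_edges = {(tf, g) for j, tf in enumerate(lo.tf_ids)
                    for g in lo.target_ids[lo.adjacency[:, j] != 0]}
        assert hi_edges <= lo_edges

    def test_sample_permutation_invariance(self, planted, rng):
        bulk, truth = planted
        perm = rng.permutation(bulk.n_columns)
        shuffled = bulk.subset_columns(perm)
        a = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        b = infer_network(shuffled, truth.tf_ids, "Tissue1", spTH=0.05)
        assert list(a.tf_ids) == list(b.tf_ids)
        assert list(a.target_ids) == list(b.target_ids)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-9)

    def test_deterministic(self, planted):
        bulk, truth = planted
        a = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        b = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_network_invariants(self, planted):
        bulk, truth = planted
        net = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        nz = net.adjacency != 0
        assert set(np.unique(net.adjacency)) <= {-1, 0, 1}
        assert (np.abs(net.weights) <= 1).all()
        assert (np.abs(net.weights[nz]) >= 0.2).all()
        assert (np.sign(net.weights[nz]) == net.adjacency[nz]).all()
        assert (nz.sum(axis=0) >= 10).all()

    def test_recovery_degrades_with_noise(self):
        recalls = []
        for noise in (1.0, 3.0, 6.0):
            bulk, truth = simulate_bulk_multitissue(
                n_tissues=3, n_per_tissue=50, n_genes=800,
                n_specific_tfs=4, n_null_tfs=0, targets_per_tf=15,
                noise_sd=noise, seed=13)
            cands = marginal_screen(bulk, truth.tf_ids, sigth=1e-6,
                                    spTH=1.0, minNtgts=1)
            net = greedy_partial_correlation(bulk, cands, minNtgts=1)
            inferred = {(tf, g) for j, tf in enumerate(net.tf_ids)
                        for g in net.target_ids[net.adjacency[:, j] != 0]}
            planted_edges = truth.edge_set()
            recalls.append(len(inferred & planted_edges)
                           / len(planted_edges))
        assert recalls[0] > recalls[1] > recalls[2]

    def test_round_trip_save_load(self, planted, tmp_path):
        bulk, truth = planted
        net = infer_network(bulk, truth.tf_ids, "Tissue1", spTH=0.05)
        from scregact import RegulatoryNetwork
        net.save(str(tmp_path / "net"))
        back = RegulatoryNetwork.load(str(tmp_path / "net"))
        np.testing.assert_array_equal(back.adjacency, net.adjacency)
        np.testing.assert_allclose(back.weights, net.weights, atol=1e-12)
        assert list(back.tf_ids) == list(net.tf_ids)
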