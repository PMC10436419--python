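"""Co-expression: soft threshold, TOM, module detection, eigengenes,
module-trait correlation."""

import numpy as np
import pandas as pd
import pytest

from lncmast import coexpression as cx


def _planted_expr(seed=0, n_modules=3, size=50, n_noise=40, n_samples=12,
                  cor=0.9):
    """Genes sharing a latent factor per module (pairwise r ~ cor) plus
    unstructured noise genes."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(cor)
    rows, names, labels = [], [], []
    for m in range(n_modules):
        f = rng.standard_normal(n_samples)
        for g in range(size):
            rows.append(lam * f + np.sqrt(1 - lam**2)
                        * rng.standard_normal(n_samples))
            names.append(f"m{m}_g{g}")
            labels.append(m)
    for g in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        names.append(f"noise_{g}")
        labels.append(-1)
    expr = pd.DataFrame(rows, index=names,
                        columns=[f"s{i}" for i in range(n_samples)])
    return expr, np.array(labels)


class TestAdjacencyAndTom:
    def test_beta_one_equals_absolute_correlation(self):
        expr, _ = _planted_expr(1, n_modules=1, size=10, n_noise=5)
        adj = cx.adjacency_matrix(expr, beta=1)
        cor = np.abs(np.corrcoef(expr.values))
        np.fill_diagonal(cor, 1.0)
        assert np.allclose(adj, cor)

    def test_adjacency_symmetric_unit_diagonal(self):
        expr, _ = _planted_expr(2, n_modules=1, size=12, n_noise=0)
        adj = cx.adjacency_matrix(expr, beta=6)
        assert np.allclose(adj, adj.T)
        assert np.allclose(np.diag(adj), 1.0)

    def test_tom_unit_diagonal_and_bounded(self):
        expr, _ = _planted_expr(3, n_modules=2, size=15, n_noise=10)
        tom = cx.tom_similarity(cx.adjacency_matrix(expr, beta=6))
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestSoftThreshold:
    def test_scale_free_hub_network_crosses_target(self):
        """Genes loading on one factor with heterogeneous weights produce a
        heavy-tailed connectivity distribution; the fit must cross the R^2
        target at a moderate power (equal-size blocks are deliberately not
        used here — their connectivity is constant, not scale-free)."""
        rng = np.random.default_rng(4)
        ns, n = 40, 400
        f = rng.standard_normal(ns)
        w = 0.98 * rng.random(n) ** 0.75
        expr = pd.DataFrame(
            [wi * f + np.sqrt(1 - wi**2) * rng.standard_normal(ns)
             for wi in w],
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(ns)])
        res = cx.pick_soft_threshold(expr, betas=range(1, 13))
        assert res.r2 > 0.9
        assert res.beta <= 10
        # the chosen beta is the smallest candidate crossing the target
        cand = res.candidates
        earlier = cand[(cand["beta"] < res.beta)]
        assert not ((earlier["r2"] > 0.9) & (earlier["slope"] < 0)).any()

    def test_degenerate_equal_correlations_warns(self, caplog):
        # two samples of a pure latent factor: all |cor| = 1, connectivity
        # constant -> scale-free fit undefined
        rng = np.random.default_rng(5)
        f = rng.standard_normal(6)
        expr = pd.DataFrame([f * s for s in (1, 2, 3, -1, -2, 2, 1.5, 0.5)],
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"s{i}" for i in range(6)])
        with caplog.at_level("WARNING", logger="lncmast"):
            res = cx.pick_soft_threshold(expr)
        assert "pick_soft_threshold" in caplog.text
        assert res.beta >= 1

    def test_requires_four_samples(self):
        expr = pd.DataFrame(np.ones((5, 3)),
                            columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="4 samples"):
            cx.pick_soft_threshold(expr)


class TestDetectModules:
    def test_planted_modules_recovered(self):
        """Three planted 50-gene modules: adjusted Rand index vs the
        planted labels must be >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        expr, labels = _planted_expr(6, cor=0.8)
        modules = cx.detect_modules(expr, beta=6, min_module_size=30)
        assign = {g: m.module_id for m in modules for g in m.members}
        planted = labels >= 0
        pred = [assign[g] for g, p in zip(expr.index, planted) if p]
        true = [l for l, p in zip(labels, planted) if p]
        assert adjusted_rand_score(true, pred) >= 0.8

    def test_single_tight_cluster_is_one_module(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal(10)
        expr = pd.DataFrame(
            [base + 0.05 * rng.standard_normal(10) for _ in range(60)],
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(10)])
        modules = cx.detect_modules(expr, beta=6, min_module_size=30)
        real = [m for m in modules if m.module_id != "grey"]
        assert len(real) == 1
        # a boundary gene may land in grey; the cluster itself is one module
        assert len(real[0].members) >= 55

    def test_membership_invariant_to_gene_order(self):
        expr, _ = _planted_expr(8, n_modules=2, size=40, n_noise=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr))
        m1 = cx.detect_modules(expr, beta=6)
        m2 = cx.detect_modules(expr.iloc[perm], beta=6)
        sets1 = sorted(frozenset(m.members) for m in m1 if m.module_id != "grey")
        sets2 = sorted(frozenset(m.members) for m in m2 if m.module_id != "grey")
        assert sets1 == sets2


class TestModuleTrait:
    def _world(self):
        expr, labels = _planted_expr(9, n_modules=1, size=40, n_noise=20,
                                     n_samples=12, cor=0.85)
        return expr, labels

    def test_eigengene_orientation_and_pc1_optimality(self):
        expr, labels = self._world()
        members = [g for g, l in zip(expr.index, labels) if l == 0]
        me = cx.eigengene(expr, members)
        cors = [np.corrcoef(expr.loc[g], me)[0, 1] for g in members]
        assert np.mean(cors) > 0
        # PC1 explains at least as much member variance as the profile of
        # any single member: compare projection power onto unit vectors
        z = ((expr.loc[members].T - expr.loc[members].mean(axis=1))
             / expr.loc[members].std(axis=1)).T.values

        def proj_power(u):
            u = np.asarray(u, float)
            u = u / np.linalg.norm(u)
            return float(np.mean((z @ u) ** 2))

        best = proj_power(me.values)
        for g in range(len(members)):
            assert best >= proj_power(z[g]) - 1e-9

    def test_me_equal_to_trait_gives_r_one(self):
        expr, labels = self._world()
        members = [g for g, l in zip(expr.index, labels) if l == 0]
        mod = cx.GeneNetworkModule("turquoise", members)
        me = cx.eigengene(expr, members)
        traits = pd.DataFrame({"t": me.values}, index=me.index)
        table = cx.module_trait([mod], expr, traits)
        assert table["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert table["pvalue"].iloc[0] < 1e-12

    def test_trait_sign_flip_negates_r_keeps_p(self):
        expr, labels = self._world()
        members = [g for g, l in zip(expr.index, labels) if l == 0]
        rng = np.random.default_rng(1)
        tv = rng.standard_normal(expr.shape[1])
        t1 = pd.DataFrame({"t": tv}, index=expr.columns)
        t2 = pd.DataFrame({"t": -tv}, index=expr.columns)
        r1 = cx.module_trait([cx.GeneNetworkModule("blue", members)], expr, t1)
        r2 = cx.module_trait([cx.GeneNetworkModule("blue", members)], expr, t2)
        assert r1["r"].iloc[0] == pytest.approx(-r2["r"].iloc[0])
        assert r1["pvalue"].iloc[0] == pytest.approx(r2["pvalue"].iloc[0])

    def test_constant_trait_reported_na(self):
        expr, labels = self._world()
        members = [g for g, l in zip(expr.index, labels) if l == 0]
        traits = pd.DataFrame({"t": np.ones(expr.shape[1])}, index=expr.columns)
        table = cx.module_trait([cx.GeneNetworkModule("red", members)],
                                expr, traits)
        assert np.isnan(table["r"].iloc[0])

    def test_planted_group_module_significant_on_synthetic(self, synth_world):
        """A module planted on group membership must correlate with its
        group indicator at P < 0.05."""
        from lncmast import diff_expr
        counts = diff_expr.prefilter_counts(synth_world["counts"])
        expr = diff_expr.normalized_log(counts)
        truth = synth_world["truth"]
        mod_info = truth.planted_modules["M1"]
        members = [g for g in mod_info["genes"] if g in expr.index]
        groups = pd.Series({s.sample_id: s.group
                            for s in synth_world["samples"]})
        indicator = groups.isin(["SF", "SC"]).astype(float)  # S_status
        traits = pd.DataFrame({"S": indicator})
        mod = cx.GeneNetworkModule("turquoise", members)
        table = cx.module_trait([mod], expr[groups.index], traits)
        assert abs(table["r"].iloc[0]) > 0.5
        assert table["pvalue"].iloc[0] < 0.05
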