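"""Gene significance, module-trait relations, hubs and network export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from comodule import network
from comodule.simulate import SyntheticConfig, generate_dataset
from comodule.trait import (
    export_edge_list,
    gene_network_stats,
    gene_significance,
    gs_mm_kin_correlations,
    hub_genes,
    intramodular_connectivity,
    meta_modules,
    module_significance,
    module_trait_correlation,
)
from conftest import random_expr


def trait_series(n0, n1):
    return pd.Series([0] * n0 + [1] * n1,
                     index=[f"s{j:02d}" for j in range(n0 + n1)])


class TestGeneSignificance:
    def test_gene_equal_to_trait_code(self):
        t = trait_series(5, 5)
        expr = pd.DataFrame([t.to_numpy(float), -t.to_numpy(float)],
                            index=["pos", "neg"], columns=t.index)
        gs = gene_significance(expr, t)
        assert gs["pos"] == pytest.approx(1.0)
        assert gs["neg"] == pytest.approx(-1.0)

    def test_planted_module_mean_gs_matches_loading_times_rho(self):
        """Generative model: E[GS_i] = a_i * rho; with a ~ U(0.85,0.95)
        and rho = 0.6 the module mean GS sits near 0.54."""
        cfg = SyntheticConfig(
            n_samples_group0=400, n_samples_group1=400,
            module_sizes=(80,), module_trait_cor=(0.6,),
            loading_range=(0.85, 0.95), n_background=0, n_deg=0, seed=3,
        )
        ds = generate_dataset(cfg)
        gs = gene_significance(ds.expr, ds.trait)
        assert abs(gs.mean() - 0.9 * 0.6) < 0.05


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_trait(self):
        t = trait_series(6, 6)
        tz = (t - t.mean()) / t.std(ddof=1)
        me = pd.DataFrame([tz.to_numpy()], index=["m"], columns=t.index)
        out = module_trait_correlation(me, t)
        assert out.at["m", "correlation"] == pytest.approx(1.0)
        assert out.at["m", "p_value"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_t_transform(self):
        """r = 0.5 at n = 71: t = r*sqrt((n-2)/(1-r^2)) = 4.796, p = 9.0e-6."""
        rng = np.random.default_rng(0)
        # construct an eigengene with exact r = 0.5 against the trait
        n = 71
        t = pd.Series([0] * 40 + [1] * 31, index=[f"s{j}" for j in range(n)])
        tz = ((t - t.mean()) / t.std(ddof=1)).to_numpy()
        e = rng.standard_normal(n)
        e -= e.mean()
        # orthogonalize then mix to hit r = 0.5 exactly
        e -= tz * (e @ tz) / (tz @ tz)
        e /= e.std(ddof=1)
        r_target = 0.5
        me_vec = r_target * tz + np.sqrt(1 - r_target**2) * e
        me = pd.DataFrame([me_vec], index=["m"], columns=t.index)
        out = module_trait_correlation(me, t)
        assert out.at["m", "correlation"] == pytest.approx(0.5, abs=1e-10)
        t_stat = 0.5 * np.sqrt((n - 2) / (1 - 0.25))
        assert t_stat == pytest.approx(4.796, abs=1e-3)  # 0.5 * sqrt(92)
        expect_p = 2 * sps.t.sf(t_stat, n - 2)
        assert out.at["m", "p_value"] == pytest.approx(expect_p, rel=1e-9)
        assert expect_p == pytest.approx(9.01e-6, rel=0.01)

    def test_orthogonal_eigengene_uncorrelated(self, rng):
        n = 2000
        t = pd.Series([0, 1] * (n // 2), index=[f"s{j}" for j in range(n)])
        me = pd.DataFrame([rng.standard_normal(n)], index=["m"],
                          columns=t.index)
        out = module_trait_correlation(me, t)
        assert abs(out.at["m", "correlation"]) < 3 / np.sqrt(n)


class TestModuleSignificance:
    def test_absolute_value_and_grey_row(self):
        gs = pd.Series([-0.4, -0.4, 0.1], index=["a", "b", "c"])
        assignment = pd.Series(["m", "m", "grey"], index=gs.index)
        ms = module_significance(gs, assignment)
        assert ms["m"] == pytest.approx(0.4)
        assert ms["grey"] == pytest.approx(0.1)


class TestMetaModules:
    def make_me(self, rows, labels, samples=12):
        return pd.DataFrame(rows, index=labels,
                            columns=[f"s{j}" for j in range(samples)])

    def test_correlated_pair_groups(self, rng):
        base = rng.standard_normal(400)
        e1 = base + 0.3 * rng.standard_normal(400)
        e2 = base + 0.3 * rng.standard_normal(400)
        e3 = rng.standard_normal(400)
        me = self.make_me([e1, e2, e3], ["m1", "m2", "m3"], samples=400)
        grouping, merges, cor = meta_modules(me, trait=None, cor_cut=0.5)
        assert grouping["m1"] == grouping["m2"]
        assert grouping["m3"] != grouping["m1"]

    def test_all_uncorrelated_become_singletons(self, rng):
        me = self.make_me(rng.standard_normal((4, 500)),
                          ["m1", "m2", "m3", "m4"], samples=500)
        grouping, _, _ = meta_modules(me, trait=None, cor_cut=0.5)
        assert grouping.nunique() == 4

    def test_trait_joins_its_associated_modules(self):
        cfg = SyntheticConfig(
            module_sizes=(60, 60, 60), module_trait_cor=(0.7, 0.7, 0.0),
            loading_range=(0.7, 0.95), n_background=0, n_deg=0, seed=8,
        )
        ds = generate_dataset(cfg)
        from comodule.modules import module_eigengene

        egs = module_eigengene(ds.expr, ds.truth)
        grouping, _, _ = meta_modules(egs.values, ds.trait, cor_cut=0.5)
        assert grouping["turquoise"] == grouping["blue"] == grouping["trait"]

    def test_single_module_rejected(self, rng):
        me = self.make_me(rng.standard_normal((1, 10)), ["m1"], samples=10)
        with pytest.raises(ValueError):
            meta_modules(me, trait=None)


class TestIntramodularConnectivity:
    def test_full_module_and_singleton(self):
        labels = ["a", "b", "c", "d"]
        adj = pd.DataFrame(np.ones((4, 4)), index=labels, columns=labels)
        assignment = pd.Series(["m", "m", "m", "solo"], index=labels)
        kin = intramodular_connectivity(adj, assignment)
        assert kin[["a", "b", "c"]].tolist() == [2.0, 2.0, 2.0]
        assert kin["d"] == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        expr = random_expr(rng, n_genes=10, n_samples=9)
        adj = network.adjacency(network.correlation_matrix(expr), 3)
        assignment = pd.Series(["m"] * 10, index=expr.index)
        kin = intramodular_connectivity(adj, assignment)
        a = adj.to_numpy()
        for i, g in enumerate(expr.index):
            expect = sum(a[i, j] for j in range(10) if j != i)
            assert abs(kin[g] - expect) < 1e-12


class TestGsMmKin:
    def test_perfect_agreement(self):
        stats_table = pd.DataFrame(
            {
                "module": ["m"] * 5,
                "GS": [0.1, 0.2, 0.3, 0.4, 0.5],
                "MM": [0.1, 0.2, 0.3, 0.4, 0.5],
                "K.in": [1.0, 2.0, 3.0, 4.0, 5.0],
            },
            index=[f"g{i}" for i in range(5)],
        )
        out = gs_mm_kin_correlations(stats_table, "m")
        assert out["r_GS_MM"] == pytest.approx(1.0)
        assert out["r_GS_Kin"] == pytest.approx(1.0)

    def test_hub_gradient_module(self):
        """A wide hub-to-periphery gradient (a in 0.4-0.95) with rho = 0.6
        makes GS track MM strongly across the module."""
        cfg = SyntheticConfig(
            module_sizes=(100,), module_trait_cor=(0.6,),
            loading_range=(0.4, 0.95), n_background=50, n_deg=0, seed=15,
        )
        ds = generate_dataset(cfg)
        from comodule.modules import kme, module_eigengene

        cor = network.correlation_matrix(ds.expr)
        adj = network.adjacency(cor, 6)
        egs = module_eigengene(ds.expr, ds.truth)
        km = kme(ds.expr, egs)
        stats_table = gene_network_stats(ds.expr, ds.trait, adj, ds.truth, km)
        out = gs_mm_kin_correlations(stats_table, "turquoise")
        assert out["r_GS_MM"] >= 0.6
        assert out["r_GS_Kin"] >= 0.4

    def test_zero_variance_rejected(self):
        stats_table = pd.DataFrame(
            {"module": ["m"] * 3, "GS": [0.1, 0.2, 0.3],
             "MM": [0.5, 0.5, 0.5], "K.in": [1, 2, 3]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="zero variance"):
            gs_mm_kin_correlations(stats_table, "m")


class TestHubGenes:
    def base_table(self):
        return pd.DataFrame(
            {
                "module": ["m"] * 4,
                "GS": [0.9, 0.5, 0.4, 0.3],
                "MM": [0.95, 0.6, 0.5, 0.4],
                "K.in": [10.0, 5.0, 5.0, 1.0],
                "GS_rank": [1, 2, 3, 4],
                "K.in_rank": [1, 2, 2, 3],
            },
            index=["hub", "b", "a", "d"],
        )

    def test_dominant_gene_is_sole_consensus_at_top1(self):
        out = hub_genes(self.base_table(), "m", top_n=1)
        assert out[out["consensus_hub"]].index.tolist() == ["hub"]

    def test_kin_ties_break_by_gs_then_id(self):
        t = self.base_table()
        out = hub_genes(t, "m", top_n=4)
        # order of the K.in ranking: hub (10), then b vs a tie at 5 ->
        # b wins on GS, then d
        kin_order = out[out["in_top_kin"]].index.tolist()
        assert kin_order[:3] == ["hub", "b", "a"]

    def test_top_loadings_dominate_kin_ranking(self, planted_dataset, fitted_planted):
        """Planted hubs (top-decile loadings) should fill the K.in top-10."""
        ds = planted_dataset
        res = fitted_planted
        stats_table = res.gene_stats
        module = "turquoise"
        genes = stats_table.index[stats_table["module"] == module]
        truth_genes = [g for g in genes if g.startswith("turquoise_")]
        # recover each gene's planted loading via its correlation with the
        # planted eigengene (E[cor] = a_i)
        e = ds.eigengene_truth.loc["turquoise"]
        loadings = {
            g: abs(np.corrcoef(ds.expr.loc[g], e)[0, 1]) for g in truth_genes
        }
        top = hub_genes(stats_table, module, top_n=10)
        kin_top = top[top["in_top_kin"]].index
        decile = np.quantile(list(loadings.values()), 0.8)
        frac_hubby = np.mean([loadings.get(g, 0) >= decile for g in kin_top])
        assert frac_hubby >= 0.8


class TestEdgeExport:
    def test_threshold_above_one_empty(self, rng):
        expr = random_expr(rng, n_genes=5, n_samples=8)
        t = network.tom(network.adjacency(network.correlation_matrix(expr), 2))
        assignment = pd.Series(["m"] * 5, index=expr.index)
        edges, _ = export_edge_list(t, assignment, "m", tom_cut=1.1)
        assert edges.empty

    def test_hand_enumerated_pairs_and_roundtrip(self, rng):
        expr = random_expr(rng, n_genes=4, n_samples=10)
        t = network.tom(network.adjacency(network.correlation_matrix(expr), 1))
        assignment = pd.Series(["m"] * 4, index=expr.index)
        cut = float(np.median(t.to_numpy()[np.triu_indices(4, 1)]))
        edges, _ = export_edge_list(t, assignment, "m", tom_cut=cut)
        genes = sorted(expr.index)
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                w = t.at[genes[i], genes[j]]
                if w >= cut:
                    expected.append((genes[i], genes[j], w))
        assert len(edges) == len(expected)
        for (g1, g2, w), (_, row) in zip(expected, edges.iterrows()):
            assert (row["source"], row["target"]) == (g1, g2)
            assert row["weight"] == pytest.approx(w)
            assert row["source"] < row["target"]
            assert row["weight"] >= cut
        # re-import reproduces the thresholded submatrix
        rebuilt = np.zeros((4, 4))
        pos = {g: i for i, g in enumerate(genes)}
        for _, row in edges.iterrows():
            rebuilt[pos[row["source"]], pos[row["target"]]] = row["weight"]
            rebuilt[pos[row["target"]], pos[row["source"]]] = row["weight"]
        ref = t.loc[genes, genes].to_numpy().copy()
        ref[ref < cut] = 0.0
        np.fill_diagonal(ref, 0.0)
        np.testing.assert_allclose(rebuilt, ref, atol=1e-12)


def test_gene_stats_invariants(fitted_planted):
    df = fitted_planted.gene_stats
    assert df["GS"].between(-1, 1).all()
    for m, sub in df.groupby("module"):
        assert (sub["K.in"] <= len(sub) - 1 + 1e-9).all()
        assert (sub["K.in"] >= 0).all()
        assert sub["GS_rank"].min() == 1
        assert sub["K.in_rank"].min() == 1
    # within planted modules, K.in and kME rise and fall together
    from scipy.stats import spearmanr

    for m in ("turquoise", "blue"):
        sub = df[df["module"] == m]
        rho = spearmanr(sub["K.in"], sub["MM"].abs()).statistic
        assert rho > 0.5
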