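"""Coexpression network: adjacency, TOM oracle, clustering, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from tnftime.network import (
    average_linkage_cluster,
    cut_tree_dynamic,
    detect_modules,
    featured_flags,
    filter_network_genes,
    hub_gene,
    module_eigengene,
    module_membership,
    pick_soft_threshold,
    signed_hybrid_adjacency,
    topological_overlap,
)


def tom_oracle(a):
    """Triple-loop evaluation of the TOM formula, independent of the
    matrix-product implementation."""
    n = a.shape[0]
    k = a.sum(axis=0) - np.diag(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def _expr(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestNetworkFilter:
    def _sheet(self, n):
        return None

    def test_constant_gene_removed(self):
        counts = pd.DataFrame(
            [[50] * 6, [10, 60, 20, 80, 30, 90]], index=["flat", "var"],
            columns=[f"s{j}" for j in range(6)],
        )
        mask = filter_network_genes(counts, counts.astype(float))
        assert not mask["flat"] and mask["var"]

    @pytest.mark.parametrize("total,kept", [(9, False), (10, True)])
    def test_total_count_boundary(self, total, kept):
        row = np.zeros(6)
        row[0] = total  # single spike: huge CV, boundary on totals
        counts = pd.DataFrame([row], index=["g"], columns=[f"s{j}" for j in range(6)])
        mask = filter_network_genes(counts, counts.astype(float))
        assert bool(mask["g"]) is kept


class TestAdjacency:
    def test_negative_correlation_truncated_to_zero(self):
        x = np.arange(10.0)
        expr = _expr([x, -x + np.linspace(0, 0.1, 10)])
        adj = signed_hybrid_adjacency(expr, beta=6).to_numpy()
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correlation_stays_one(self):
        x = np.arange(10.0)
        expr = _expr([x, 2 * x + 3])
        adj = signed_hybrid_adjacency(expr, beta=7).to_numpy()
        assert adj[0, 1] == pytest.approx(1.0)

    def test_power_applied_to_positive_correlation(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(size=(4, 50)))
        cor = np.corrcoef(expr.to_numpy())
        adj = signed_hybrid_adjacency(expr, beta=2).to_numpy()
        i, j = 0, 1
        expected = max(cor[i, j], 0.0) ** 2
        assert adj[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named(self):
        expr = _expr([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]], genes=["flatg", "ok"])
        with pytest.raises(ValueError, match="flatg"):
            signed_hybrid_adjacency(expr, beta=2)


class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_beta(self):
        import warnings as _warnings

        rng = np.random.default_rng(6)
        z = rng.normal(size=50)
        expr = _expr(
            [0.7 * z + 0.3 * rng.normal(size=50) for _ in range(40)]
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            _, table = pick_soft_threshold(expr, candidate_betas=(1, 2, 4, 6, 8))
        assert (np.diff(table["mean_k"].to_numpy()) < 0).all()

    def test_latent_factor_expression_reaches_fit_target(self):
        # few latent factors with a heavy-tailed loading profile (many weak
        # genes, few hubs) gives an approximately scale-free connectivity
        rng = np.random.default_rng(7)
        n_genes, n_samp = 300, 100
        factors = rng.normal(size=(3, n_samp))
        f_idx = rng.integers(0, 3, size=n_genes)
        load = np.clip(0.08 * np.exp(0.6 * rng.exponential(size=n_genes)), 0.05, 0.98)
        rows = load[:, None] * factors[f_idx] + np.sqrt(1 - load**2)[
            :, None
        ] * rng.normal(size=(n_genes, n_samp))
        beta, table = pick_soft_threshold(_expr(rows))
        assert beta <= 12
        assert table.loc[table["beta"] == beta, "fit_r2"].iloc[0] >= 0.8

    def test_fallback_to_default_when_no_fit(self):
        rng = np.random.default_rng(8)
        expr = _expr(rng.normal(size=(30, 8)))
        with pytest.warns(RuntimeWarning, match="falling back"):
            beta, _ = pick_soft_threshold(
                expr, candidate_betas=(1,), r2_target=0.999999
            )
        assert beta == 12


class TestTopologicalOverlap:
    def test_complete_graph_has_unit_tom(self):
        a = np.ones((3, 3))
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_empty_graph_has_zero_offdiagonal(self):
        a = np.eye(4)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_matches_triple_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.uniform(size=(20, 20))
            a = 0.5 * (a + a.T)
            np.fill_diagonal(a, 1.0)
            tom = topological_overlap(pd.DataFrame(a)).to_numpy()
            assert np.abs(tom - tom_oracle(a)).max() < 1e-10
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestClusteringAndCut:
    def _blocky_diss(self, rng):
        # two planted blocks with low within-block dissimilarity; unrelated
        # genes sit near 1, as TOM dissimilarity does for uncorrelated genes
        n1, n2, noise = 40, 35, 15
        n = n1 + n2 + noise
        d = rng.uniform(0.995, 1.0, size=(n, n))
        d[:n1, :n1] = rng.uniform(0.1, 0.3, size=(n1, n1))
        d[n1 : n1 + n2, n1 : n1 + n2] = rng.uniform(0.1, 0.3, size=(n2, n2))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d), n1, n2

    def test_final_merge_joins_planted_blocks(self):
        diss, n1, n2 = self._blocky_diss(np.random.default_rng(10))
        z = average_linkage_cluster(diss)
        assert (np.diff(z[:, 2]) >= -1e-12).all()  # monotone heights
        labels = cut_tree_dynamic(z, min_size=30)
        assert set(labels[:n1]) == {1} or set(labels[:n1]) == {2}
        assert len(set(labels[:n1])) == 1 and len(set(labels[n1 : n1 + n2])) == 1
        assert labels[:n1][0] != labels[n1 : n1 + n2][0]

    def test_identical_rows_merge_at_height_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        z = average_linkage_cluster(pd.DataFrame(d))
        assert z[0, 2] == pytest.approx(0.0)

    def test_single_gene_yields_empty_dendrogram(self):
        z = average_linkage_cluster(pd.DataFrame([[0.0]]))
        assert z.shape == (0, 4)

    def test_small_blocks_stay_unassigned(self):
        rng = np.random.default_rng(11)
        n = 50
        d = rng.uniform(0.995, 1.0, size=(n, n))
        d[:10, :10] = rng.uniform(0.05, 0.15, size=(10, 10))  # tight block of 10
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        labels = cut_tree_dynamic(average_linkage_cluster(pd.DataFrame(d)), min_size=30)
        assert set(labels[:10]) == {0}

    def test_uncorrelated_genes_give_zero_modules(self):
        rng = np.random.default_rng(12)
        expr = _expr(rng.normal(size=(80, 40)))
        mods = detect_modules(expr, beta=6)
        assert len(mods.eigengenes) == 0
        assert (mods.labels == 0).all()

    def test_min_size_validation(self):
        with pytest.raises(ValueError, match="min_size"):
            cut_tree_dynamic(np.empty((3, 4)), min_size=1)


class TestEigengeneAndMembership:
    def test_identical_profiles_rank_one(self):
        base = np.sin(np.linspace(0, 3, 12))
        expr = _expr([base * 2 + 1, base * 5 - 2, base + 0.5])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig, varex = module_eigengene(expr, labels)
        assert varex[1] == pytest.approx(1.0)
        kme, pvals = module_membership(expr, eig)
        assert np.allclose(kme[1].to_numpy(), 1.0)
        assert (pvals[1] < 1e-6).all()

    def test_orientation_invariant_to_latent_sign_flip(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=30)
        expr = _expr([z + 0.2 * rng.normal(size=30) for _ in range(10)])
        labels = pd.Series(1, index=expr.index)
        eig1, _ = module_eigengene(expr, labels)
        eig2, _ = module_eigengene(-expr, labels)
        # both orient positively with their own members
        assert np.corrcoef(eig1.loc[1], expr.iloc[0])[0, 1] > 0
        assert np.corrcoef(eig2.loc[1], -expr.iloc[0])[0, 1] > 0

    def test_noisy_module_eigengene_tracks_latent(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=40)
        expr = _expr([z + 0.5 * rng.normal(size=40) for _ in range(30)])
        labels = pd.Series(1, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        assert abs(np.corrcoef(eig.loc[1], z)[0, 1]) >= 0.9

    def test_white_noise_gene_has_low_kme(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=44)
        members = [z + 0.3 * rng.normal(size=44) for _ in range(20)]
        noise = rng.normal(size=(30, 44))
        expr = _expr(members + list(noise))
        labels = pd.Series([1] * 20 + [0] * 30, index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        kme, _ = module_membership(expr, eig)
        assert (kme[1].iloc[20:].abs() < 0.5).mean() >= 0.96

    def test_featured_requires_both_kme_and_pvalue(self):
        kme = pd.DataFrame({1: [0.85, 0.85]}, index=["a", "b"])
        pvals = pd.DataFrame({1: [0.2, 0.001]}, index=["a", "b"])
        labels = pd.Series([1, 1], index=["a", "b"])
        out = featured_flags(kme, pvals, labels)
        assert not out["a"] and out["b"]

    def test_constant_gene_inside_module_errors(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        labels = pd.Series([1, 1], index=expr.index)
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(expr, labels)


def test_adjusted_rand_index_matches_sklearn():
    from sklearn.metrics import adjusted_rand_score

    from tnftime.evaluation import adjusted_rand_index

    rng = np.random.default_rng(18)
    for _ in range(10):
        a = rng.integers(0, 5, size=120)
        b = rng.integers(0, 4, size=120)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )
    assert adjusted_rand_index([0, 0, 1, 1], [2, 2, 3, 3]) == 1.0


class TestHubGene:
    def test_star_center_is_hub(self):
        n = 6
        a = np.full((n, n), 0.05)
        a[0, :] = a[:, 0] = 0.9
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)], columns=[f"g{i}" for i in range(n)])
        labels = pd.Series(1, index=adj.index)
        assert hub_gene(adj, labels) == {1: "g0"}

    def test_tie_breaks_lexicographically(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 1.0)
        ids = ["zeta", "alpha", "mid", "beta"]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        labels = pd.Series(1, index=adj.index)
        assert hub_gene(adj, labels) == {1: "alpha"}

    def test_planted_hub_recovered(self):
        rng = np.random.default_rng(16)
        hits = 0
        for trial in range(20):
            z = rng.normal(size=30)
            rows = [2.0 * z + 0.1 * rng.normal(size=30)]  # inflated loading
            rows += [z + 0.8 * rng.normal(size=30) for _ in range(19)]
            expr = _expr(rows)
            adj = signed_hybrid_adjacency(expr, beta=6)
            labels = pd.Series(1, index=expr.index)
            if hub_gene(adj, labels)[1] == "g0":
                hits += 1
        assert hits >= 19
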