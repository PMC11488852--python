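"""Co-expression network: adjacency, TOM, soft threshold, modules,
eigengenes, trait association and intramodular connectivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protoy.de import filter_low_expression, normalize_vst
from protoy.network import (
    adjacency,
    correlation_matrix,
    detect_modules,
    intramodular_connectivity,
    module_eigengenes,
    module_trait_association,
    pick_soft_threshold,
    topological_overlap,
)
from protoy.simulate import SimConfig, simulate_counts


class TestCorrelation:
    def test_identical_and_negated_genes(self):
        x = np.random.default_rng(0).normal(size=12)
        expr = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        r = correlation_matrix(expr)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_formula(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)))
        r = correlation_matrix(expr).to_numpy()
        x = expr.to_numpy()
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                naive = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert r[i, j] == pytest.approx(naive, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]]))

    def test_zero_variance_genes_dropped_with_warning(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4], [5, 5, 5, 5]], index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlation_matrix(expr)
        assert list(r.index) == ["a"]


class TestAdjacency:
    def test_direct_power_both_signs(self):
        corr = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]])
        a = adjacency(corr, 7)
        assert a.iloc[0, 1] == pytest.approx(0.4783, abs=1e-4)
        neg = pd.DataFrame([[1.0, -0.9], [-0.9, 1.0]])
        assert adjacency(neg, 7).iloc[0, 1] == pytest.approx(0.4783, abs=1e-4)

    def test_unsigned_symmetry_under_negation(self, small_corr):
        pd.testing.assert_frame_equal(adjacency(small_corr, 6), adjacency(-small_corr, 6))

    def test_matches_naive_loop(self, small_corr):
        a = adjacency(small_corr, 5).to_numpy()
        r = small_corr.to_numpy()
        n = len(r)
        for i in range(n):
            for j in range(n):
                expect = 1.0 if i == j else abs(r[i, j]) ** 5
                assert a[i, j] == pytest.approx(expect, abs=1e-12)

    def test_permutation_equivariance(self, small_corr, rng):
        perm = list(rng.permutation(small_corr.index))
        direct = adjacency(small_corr, 4).loc[perm, perm]
        permuted = adjacency(small_corr.loc[perm, perm], 4)
        pd.testing.assert_frame_equal(direct, permuted)

    def test_invalid_beta_rejected(self, small_corr):
        with pytest.raises(ValueError):
            adjacency(small_corr, 0)


def brute_force_tom(a):
    n = len(a)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            w[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return w


class TestTopologicalOverlap:
    def test_complete_triangle_saturates(self):
        a = pd.DataFrame(np.ones((3, 3)))
        w = topological_overlap(a)
        assert np.allclose(w.to_numpy(), 1.0)

    def test_isolated_gene_has_zero_overlap(self):
        a = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.0], [0.0, 0.0, 1.0]])
        w = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert w[2, 0] == 0 and w[2, 1] == 0

    def test_matches_triple_loop_brute_force(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        w = topological_overlap(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(w, brute_force_tom(a), atol=1e-12)

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            topological_overlap(pd.DataFrame([[1.0, 1.5], [1.5, 1.0]]))


class TestSoftThreshold:
    def test_beta_one_is_absolute_correlation(self, small_corr):
        fit = pick_soft_threshold(small_corr, candidate_betas=[1], rsq_cut=0.0,
                                  mean_k_min=0.0)
        assert fit.beta == 1
        np.testing.assert_allclose(
            adjacency(small_corr, 1).to_numpy(), np.abs(small_corr.to_numpy())
        )

    def test_scale_free_fixture_reaches_rsq_cut(self):
        # hub-and-spoke-ish correlation structure gives a heavy-tailed degree
        # distribution after soft thresholding
        rng = np.random.default_rng(1)
        n, m = 300, 20
        loadings = rng.uniform(0.2, 1.0, size=n) ** 3  # few strong hubs
        z = rng.normal(size=(1, m))
        x = loadings[:, None] * z + rng.normal(size=(n, m)) * 0.8
        corr = correlation_matrix(pd.DataFrame(x))
        fit = pick_soft_threshold(corr, candidate_betas=list(range(1, 13)))
        assert (fit.table["rsq"].dropna() >= 0.8).any()

    def test_default_candidates_include_conventional_beta(self, small_corr):
        fit = pick_soft_threshold(small_corr)
        assert 7 in fit.table["beta"].tolist()
        assert {"beta", "rsq", "mean_k"} <= set(fit.table.columns)

    def test_no_satisfying_beta_returns_argmax_with_flag(self, small_corr):
        with pytest.warns(UserWarning, match="scale-free"):
            fit = pick_soft_threshold(small_corr, rsq_cut=1.01)
        assert not fit.satisfied


class TestDetectModules:
    def test_planted_partition_recovered(self, two_block_dataset):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            counts, meta, truth = simulate_counts(
                SimConfig(n_genes=300, n_samples=24, seed=seed,
                          module_spec=[(50, 0.8), (50, 0.8)])
            )
            expr = normalize_vst(filter_low_expression(counts))
            corr = correlation_matrix(expr)
            mods = detect_modules(topological_overlap(adjacency(corr, 6)), expr)
            t = pd.Series(truth.module_membership, index=counts.index).reindex(expr.index)
            aris.append(adjusted_rand_score(t, mods.to_numpy()))
        assert np.mean(aris) > 0.9

    def test_small_block_below_min_size_unassigned(self):
        counts, _, truth = simulate_counts(
            SimConfig(n_genes=80, n_samples=20, seed=4, module_spec=[(10, 0.9)])
        )
        expr = normalize_vst(counts)
        corr = correlation_matrix(expr)
        mods = detect_modules(topological_overlap(adjacency(corr, 6)), expr, min_size=30)
        block = np.array(truth.module_membership) == 1
        assert (mods.to_numpy()[block] == 0).all()

    def test_blocks_sharing_a_latent_factor_merge(self):
        # one latent driver split into two nominal blocks: eigengene r ~ 1
        rng = np.random.default_rng(8)
        z = rng.normal(size=24)
        x = 2.0 * z[None, :] + rng.normal(size=(80, 24)) * 0.8
        x = np.vstack([x, rng.normal(size=(60, 24))])
        expr = pd.DataFrame(x, index=[f"g{i:03d}" for i in range(140)])
        corr = correlation_matrix(expr)
        mods = detect_modules(topological_overlap(adjacency(corr, 6)), expr,
                              min_size=20, merge_threshold=0.2)
        driven = mods.to_numpy()[:80]
        assigned = driven[driven != 0]
        assert len(assigned) > 0 and len(set(assigned)) == 1

    def test_min_size_above_gene_count_leaves_all_unassigned(self, small_corr):
        tom = topological_overlap(adjacency(small_corr, 2))
        with pytest.warns(UserWarning, match="min_size"):
            mods = detect_modules(tom, min_size=50)
        assert (mods == 0).all()

    def test_deterministic_given_tom(self, two_block_dataset):
        _, _, _, expr = two_block_dataset
        tom = topological_overlap(adjacency(correlation_matrix(expr), 6))
        m1 = detect_modules(tom, expr)
        m2 = detect_modules(tom, expr)
        pd.testing.assert_series_equal(m1, m2)


class TestEigengenes:
    def test_identical_genes_give_their_standardized_profile(self):
        x = np.random.default_rng(2).normal(size=12)
        expr = pd.DataFrame([x, x, x], index=["a", "b", "c"])
        mods = pd.Series([1, 1, 1], index=expr.index)
        eig = module_eigengenes(expr, mods).loc[1].to_numpy()
        z = (x - x.mean()) / x.std()
        expected = z / np.linalg.norm(z)
        assert np.allclose(eig, expected) or np.allclose(eig, -expected)
        assert np.corrcoef(eig, x)[0, 1] > 0  # sign rule

    def test_pc1_beats_random_unit_vectors(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 10)))
        mods = pd.Series(1, index=expr.index)
        eig = module_eigengenes(expr, mods).loc[1].to_numpy()
        z = stats.zscore(expr.to_numpy(), axis=1)
        var_eig = ((z @ eig) ** 2).sum()
        for _ in range(100):
            v = rng.normal(size=10)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() <= var_eig + 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 9)))
        mods = pd.Series(1, index=expr.index)
        eig = module_eigengenes(expr, mods).loc[1].to_numpy()
        z = stats.zscore(expr.to_numpy(), axis=1)
        vals, vecs = np.linalg.eigh(z.T @ z)
        top = vecs[:, -1]
        assert np.allclose(np.abs(eig @ top), 1.0, atol=1e-8)

    def test_zero_variance_module_rejected(self):
        expr = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["a"])
        with pytest.raises(ValueError, match="zero-variance"):
            module_eigengenes(expr, pd.Series([1], index=["a"]))


class TestTraitAssociation:
    def test_eigengene_equal_to_trait_is_perfect(self):
        trait = np.array([0.0, 1, 0, 1, 0, 1])
        eig = pd.DataFrame([trait], index=[1])
        out = module_trait_association(eig, trait)
        assert out.loc[1, "r"] == pytest.approx(1.0)
        assert out.loc[1, "p"] < 1e-6

    def test_trait_driven_module_has_smallest_p(self):
        hits = 0
        for seed in range(20):
            # module 1 genes also carry a genotype effect
            de_spec = [(i, 1.5) for i in range(40)]
            counts, meta, _ = simulate_counts(
                SimConfig(n_genes=220, n_samples=24, seed=seed,
                          module_spec=[(40, 0.6), (40, 0.6)], de_spec=de_spec)
            )
            expr = normalize_vst(filter_low_expression(counts))
            corr = correlation_matrix(expr)
            mods = detect_modules(topological_overlap(adjacency(corr, 6)), expr,
                                  min_size=20)
            if not (mods != 0).any():
                continue
            eig = module_eigengenes(expr, mods)
            trait = (meta["genotype"] == "IIIM").astype(float)
            assoc = module_trait_association(eig, trait)
            best = assoc["p_adj"].idxmin()
            members = mods[mods == best].index
            planted = [f"gene{i + 1:05d}" for i in range(40)]
            hits += len(set(members) & set(planted)) > len(members) / 2
        assert hits / 20 >= 0.9

    def test_permuted_trait_false_positive_rate(self):
        rng = np.random.default_rng(5)
        sig = 0
        n_mod, n_rep = 20, 25
        for _ in range(n_rep):
            eig = pd.DataFrame(rng.normal(size=(n_mod, 24)))
            trait = rng.permutation([0.0] * 12 + [1.0] * 12)
            out = module_trait_association(eig, trait)
            sig += (out["p"] < 0.05).sum()
        rate = sig / (n_mod * n_rep)
        assert 0.0 <= rate <= 0.15

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)))
        with pytest.raises(ValueError, match="constant"):
            module_trait_association(eig, np.ones(6))


class TestIntramodularConnectivity:
    def test_complete_module_of_three(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        mods = pd.Series([1, 1, 1], index=list("abc"))
        assert (intramodular_connectivity(a, mods) == 2.0).all()

    def test_singleton_module_and_unassigned_get_zero(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        mods = pd.Series([1, 0, 0], index=list("abc"))
        k = intramodular_connectivity(a, mods)
        assert (k == 0).all()

    def test_matches_double_loop_brute_force(self, small_corr, rng):
        a = adjacency(small_corr, 3)
        mods = pd.Series(rng.integers(0, 3, size=len(a)), index=a.index)
        k = intramodular_connectivity(a, mods)
        for i, gi in enumerate(a.index):
            expect = sum(
                a.iloc[i, j]
                for j, gj in enumerate(a.index)
                if gi != gj and mods[gj] == mods[gi] and mods[gi] != 0
            )
            assert k[gi] == pytest.approx(expect, abs=1e-12)

    def test_hub_ranking_unaffected_by_unassigned_genes(self, small_corr):
        a = adjacency(small_corr, 3)
        mods = pd.Series(1, index=a.index)
        k_full = intramodular_connectivity(a, mods)
        mods2 = mods.copy()
        mods2.iloc[-3:] = 0
        k_sub = intramodular_connectivity(a.iloc[:-3, :-3], mods2.iloc[:-3])
        k_ref = intramodular_connectivity(a, mods2)
        ranked_sub = k_sub.sort_values(ascending=False).index
        ranked_ref = k_ref.iloc[:-3].sort_values(ascending=False).index
        assert list(ranked_sub) == list(ranked_ref)
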