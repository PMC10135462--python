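import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna_forge.coexpr import (
    GREY,
    _cor_test_p,
    adjacency_matrix,
    compute_tom,
    detect_modules,
    detect_outlier_samples,
    disease_specific_genes,
    gene_stats,
    module_trait,
    pick_soft_threshold,
    select_top_variance,
    tom_from_adjacency,
)
from cerna_forge.io_prep import make_sample_table


def _expr(vals, prefix="G"):
    vals = np.asarray(vals, dtype=float)
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(vals.shape[0])],
        columns=[f"s{i}" for i in range(vals.shape[1])],
    )


def _block_matrix(rng, blocks, n_samples, noise=0.0, factor_cor=0.0):
    """Stack latent-factor blocks; optional correlation between factors."""
    cov = np.full((len(blocks), len(blocks)), factor_cor)
    np.fill_diagonal(cov, 1.0)
    factors = rng.multivariate_normal(np.zeros(len(blocks)), cov, size=n_samples).T
    rows = []
    for b, size in enumerate(blocks):
        load = rng.uniform(0.8, 1.0, size=size)
        rows.append(load[:, None] * factors[b][None, :]
                    + rng.normal(0, noise, size=(size, n_samples)))
    return _expr(np.vstack(rows))


class TestSelectTopVariance:
    def test_keeps_highest_variance_feature(self):
        x = _expr([[0, 0, 0], [0, 1, 2], [0, 2, 4], [0, 3, 6]])
        out = select_top_variance(x, 0.25)
        assert list(out.index) == ["G3"]

    def test_fraction_one_is_identity(self, rng):
        x = _expr(rng.normal(size=(10, 5)))
        pd.testing.assert_frame_equal(select_top_variance(x, 1.0), x)

    def test_tie_broken_by_feature_id(self):
        x = _expr([[0, 2], [0, 2], [0, 1]])  # G0, G1 tied at the cut
        out = select_top_variance(x, 1 / 3)
        assert list(out.index) == ["G0"]


class TestOutlierDetection:
    def test_identical_samples_unflagged(self):
        x = _expr(np.ones((5, 6)))
        assert detect_outlier_samples(x, cut_height=10.0) == []

    def test_offset_sample_flagged(self, rng):
        x = _expr(rng.normal(size=(20, 5)))
        x["s4"] += 100.0
        flagged = detect_outlier_samples(x, cut_height=50.0)
        assert flagged == ["s4"]

    def test_infinite_cut_flags_nothing(self, rng):
        x = _expr(rng.normal(size=(20, 5)))
        x["s4"] += 100.0
        assert detect_outlier_samples(x, cut_height=np.inf) == []


class TestSoftThreshold:
    def test_single_candidate_power_always_selected(self, rng):
        x = _expr(rng.normal(size=(30, 10)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pick_soft_threshold(x, powers=[1], r2_target=0.99)
        assert rep.selected == 1

    def test_hub_connectivity_two_bin_fit_is_exact(self):
        from cerna_forge.coexpr import _scale_free_fit

        # one hub with high connectivity, many leaves at low connectivity:
        # two occupied bins -> the log-log fit passes through both points
        k = np.array([20.0] * 3 + [1.0] * 47)
        assert _scale_free_fit(k) == pytest.approx(1.0)

    def test_noise_matrix_falls_back_with_warning(self, rng):
        x = _expr(rng.normal(size=(60, 12)))
        with pytest.warns(UserWarning, match="falling back"):
            rep = pick_soft_threshold(x, powers=[1, 2, 3], r2_target=0.999)
        assert not rep.target_met
        best = rep.table.loc[rep.table["r2_signed"].idxmax(), "power"]
        assert rep.selected == best

    def test_selection_rule_smallest_power_reaching_target(self, rng):
        x = _block_matrix(rng, [30, 30], 25, noise=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe = pick_soft_threshold(x, powers=range(1, 9), r2_target=2.0)
        r2 = probe.table["r2_signed"]
        target = float((r2.min() + r2.max()) / 2)
        rep = pick_soft_threshold(x, powers=range(1, 9), r2_target=target)
        reached = rep.table[rep.table["r2_signed"] >= target]
        assert rep.selected == int(reached["power"].iloc[0])


class TestTOM:
    def test_complete_graph_gives_ones(self):
        a = np.ones((6, 6)) - np.eye(6)
        tom = tom_from_adjacency(a).to_numpy()
        assert tom == pytest.approx(np.ones((6, 6)))

    def test_isolated_pair_gives_zero(self):
        a = np.zeros((4, 4))
        tom = tom_from_adjacency(a).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        assert off == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 21))
            x = _expr(rng.normal(size=(n, 12)))
            beta = int(rng.integers(1, 7))
            tom = compute_tom(x, beta).to_numpy()
            a = adjacency_matrix(x, beta)
            k = a.sum(axis=0)
            brute = np.ones((n, n))
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
                    den = min(k[i], k[j]) + 1.0 - a[i, j]
                    brute[i, j] = num / den
            assert np.abs(tom - brute).max() < 1e-12

    def test_zero_variance_gene_rejected(self, rng):
        x = _expr(rng.normal(size=(5, 8)))
        x.loc["G2"] = 3.0
        with pytest.raises(ValueError, match="G2"):
            compute_tom(x, 6)


class TestDetectModules:
    def test_two_pure_blocks_recovered(self, rng):
        x = _block_matrix(rng, [60, 60], 30, noise=0.0)
        tom = compute_tom(x, 6)
        assign = detect_modules(tom, x, min_module_size=50)
        labels = assign.modules
        assert set(labels[:60]) == {labels.iloc[0]} and labels.iloc[0] != GREY
        assert set(labels[60:]) == {labels.iloc[60]} and labels.iloc[60] != GREY
        assert labels.iloc[0] != labels.iloc[60]

    def test_undersized_blocks_all_grey(self, rng):
        x = _block_matrix(rng, [30, 30], 25, noise=0.1)
        tom = compute_tom(x, 6)
        with pytest.warns(UserWarning, match="grey"):
            assign = detect_modules(tom, x, min_module_size=50)
        assert set(assign.modules) == {GREY}

    def test_correlated_modules_merged_by_eigengene_rule(self, rng):
        x = _block_matrix(rng, [60, 60], 40, noise=0.05, factor_cor=0.97)
        tom = compute_tom(x, 6)
        assign = detect_modules(tom, x, min_module_size=50, merge_cut_height=0.15)
        non_grey = set(assign.modules) - {GREY}
        assert len(non_grey) == 1

    def test_uncorrelated_modules_not_merged(self, rng):
        x = _block_matrix(rng, [60, 60], 40, noise=0.05, factor_cor=0.0)
        tom = compute_tom(x, 6)
        assign = detect_modules(tom, x, min_module_size=50, merge_cut_height=0.15)
        assert len(set(assign.modules) - {GREY}) == 2

    def test_eigengenes_unit_norm_and_first_pc_optimal(self, rng):
        block = _block_matrix(rng, [60], 30, noise=0.4)
        background = _expr(rng.normal(size=(30, 30)), prefix="BG")
        background.columns = block.columns
        x = pd.concat([block, background])
        tom = compute_tom(x, 6)
        assign = detect_modules(tom, x, min_module_size=50)
        assert len(assign.eigengenes) == 1
        me = assign.eigengenes.iloc[0].to_numpy()
        assert np.linalg.norm(me) == pytest.approx(1.0)
        # first-PC optimality: variance explained >= any random direction
        mod_genes = assign.modules[assign.modules != GREY].index
        z = x.loc[mod_genes].to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        var_me = ((z @ me) ** 2).sum()
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        assert var_me == pytest.approx(s[0] ** 2, rel=1e-9)
        for _ in range(20):
            d = rng.normal(size=me.size)
            d /= np.linalg.norm(d)
            assert ((z @ d) ** 2).sum() <= var_me + 1e-9


class TestModuleTraitAndGeneStats:
    def _assign_with_me(self, me_vals, samples):
        from cerna_forge.coexpr import ModuleAssignment

        genes = [f"G{i}" for i in range(3)]
        return ModuleAssignment(
            modules=pd.Series(["turquoise"] * 3, index=genes),
            eigengenes=pd.DataFrame([me_vals], index=["turquoise"],
                                    columns=samples["sample_id"]),
        )

    def test_eigengene_equal_to_trait_gives_r_one(self, two_group_table):
        t = two_group_table(3, 3)
        assign = self._assign_with_me([0, 0, 0, 1, 1, 1], t)
        mt = module_trait(assign, t)
        assert mt.loc["turquoise", "r"] == pytest.approx(1.0)

    def test_orthogonal_eigengene_gives_zero_r(self, two_group_table):
        t = two_group_table(2, 2)
        assign = self._assign_with_me([1, -1, 1, -1], t)
        mt = module_trait(assign, t)
        assert mt.loc["turquoise", "r"] == pytest.approx(0.0, abs=1e-12)
        assert mt.loc["turquoise", "p"] == pytest.approx(1.0)

    def test_p_formula_matches_reported_magnitude_at_n59(self):
        # a module-trait correlation of 0.53 over 59 samples is reported
        # alongside p = 2e-5; the t-based formula must reproduce that scale
        p = _cor_test_p(0.53, 59)
        t = 0.53 * np.sqrt(57 / (1 - 0.53**2))
        assert p == pytest.approx(2 * stats.t.sf(t, 57), rel=1e-12)
        assert 1e-5 < p < 3e-5

    def test_mm_gs_match_direct_correlations(self, rng, two_group_table):
        t = two_group_table(6, 6)
        x = _expr(rng.normal(size=(20, 12)))
        x.columns = t["sample_id"]
        tom = compute_tom(x, 2)
        assign = detect_modules(tom, x, min_module_size=3, min_persistence_frac=0.0)
        if assign.eigengenes.empty:
            pytest.skip("no modules in noise draw")
        assign = gene_stats(assign, x, t)
        trait = (t["group"] == "case").to_numpy(dtype=float)
        for g in x.index[:5]:
            for mod in assign.eigengenes.index:
                expect = np.corrcoef(x.loc[g], assign.eigengenes.loc[mod])[0, 1]
                assert assign.mm.loc[g, mod] == pytest.approx(expect, abs=1e-12)
            expect_gs = np.corrcoef(x.loc[g], trait)[0, 1]
            assert assign.gs[g] == pytest.approx(expect_gs, abs=1e-12)

    def test_gene_identical_to_trait_gives_gs_one(self, two_group_table, rng):
        t = two_group_table(5, 5)
        x = _expr(rng.normal(size=(10, 10)))
        x.columns = t["sample_id"]
        x.loc["G0"] = (t["group"] == "case").to_numpy(dtype=float)
        tom = compute_tom(x, 2)
        assign = detect_modules(tom, x, min_module_size=2, min_persistence_frac=0.0)
        if assign.eigengenes.empty:
            pytest.skip("no modules in noise draw")
        assign = gene_stats(assign, x, t)
        assert assign.gs["G0"] == pytest.approx(1.0)


class TestDiseaseSpecificGenes:
    def _assign(self, mapping):
        from cerna_forge.coexpr import ModuleAssignment

        return ModuleAssignment(modules=pd.Series(mapping))

    def test_set_intersection(self):
        de = pd.DataFrame(
            {"direction": ["up", "down", "up", "ns"]}, index=["A", "B", "C", "D"]
        )
        assign = self._assign({"A": "grey", "B": "blue", "C": "blue", "D": "blue"})
        assert disease_specific_genes(de, assign, ["blue"]) == ["B", "C"]

    def test_empty_de_set(self):
        de = pd.DataFrame({"direction": ["ns", "ns"]}, index=["A", "B"])
        assign = self._assign({"A": "blue", "B": "blue"})
        assert disease_specific_genes(de, assign, ["blue"]) == []

    def test_unknown_module_raises(self):
        de = pd.DataFrame({"direction": ["up"]}, index=["A"])
        assign = self._assign({"A": "blue"})
        with pytest.raises(ValueError, match="magenta"):
            disease_specific_genes(de, assign, ["magenta"])
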