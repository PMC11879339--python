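import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from seepecol.diversity import bray_curtis
from seepecol.simulate import (
    ActivityModel,
    AssemblyScenario,
    NicheModel,
    clade_taxonomy,
    evolve_optima,
    lognormal_pool,
    simulate_metacommunity,
    simulate_paired_rna,
    simulate_survey,
    simulate_tree,
)


class TestSimulateTree:
    def test_three_tips_is_rooted_binary(self):
        t = simulate_tree(3, seed=0)
        assert t.n_tips == 3
        n_edges = sum(1 for _ in t.tree.traverse(include_self=False))
        assert n_edges == 4  # rooted binary: 2n - 2

    def test_deterministic_given_seed(self):
        assert simulate_tree(20, seed=5).to_newick() == simulate_tree(20, seed=5).to_newick()
        assert simulate_tree(20, seed=5).to_newick() != simulate_tree(20, seed=6).to_newick()

    def test_patristic_positive_finite(self):
        t = simulate_tree(200, seed=1)
        d = t.patristic_matrix().data
        off = d[np.triu_indices(200, 1)]
        assert np.isfinite(off).all() and off.mean() > 0

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=0)


class TestEvolveOptima:
    def test_zero_rate_degenerates_to_root_value(self):
        t = simulate_tree(10, seed=2)
        n = evolve_optima(t, 0.0, seed=3, root_value=1.5)
        assert np.allclose(n.optima, 1.5)

    def test_deterministic(self):
        t = simulate_tree(10, seed=2)
        a = evolve_optima(t, 1.0, seed=7).optima
        b = evolve_optima(t, 1.0, seed=7).optima
        pd.testing.assert_series_equal(a, b)

    def test_brownian_variance_identity(self, three_tip_tree):
        # Var(opt_A - opt_B) over replicate evolutions equals rate * d(A, B)
        rate, n_rep = 2.0, 1000
        d_ab = three_tip_tree.patristic_matrix()["A", "B"]
        diffs = np.array(
            [
                (lambda o: o["A"] - o["B"])(
                    evolve_optima(three_tip_tree, rate, seed=s).optima
                )
                for s in range(n_rep)
            ]
        )
        assert diffs.var() == pytest.approx(rate * d_ab, rel=0.15)


class TestSimulateMetacommunity:
    def _tree_niche(self, sigma=0.5):
        t = simulate_tree(40, seed=11)
        return t, evolve_optima(t, 1.0, seed=12, sigma_niche=sigma)

    def test_column_sums_equal_read_depth(self):
        t, n = self._tree_niche()
        sc = AssemblyScenario("selection", env_values=[0.0, 0.5, 1.0], read_depth=2500)
        tbl, meta = simulate_metacommunity(t, n, sc, seed=13)
        assert (tbl.sample_sums() == 2500).all()
        assert list(meta["env"]) == [0.0, 0.5, 1.0]

    def test_flat_gaussian_reduces_to_neutral(self):
        t, _ = self._tree_niche()
        wide = evolve_optima(t, 1.0, seed=12, sigma_niche=1e9)
        pool = lognormal_pool(t.tip_names, seed=5).to_numpy()
        sel = AssemblyScenario("selection", env_values=[0.3] * 4, pool=pool)
        neu = AssemblyScenario("neutral", env_values=[0.3] * 4, pool=pool)
        a, _ = simulate_metacommunity(t, wide, sel, seed=21)
        b, _ = simulate_metacommunity(t, wide, neu, seed=21)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_identical_env_identical_expectation(self):
        # two samples, same env, pure selection, huge depth: compositions converge
        t, n = self._tree_niche(sigma=0.4)
        sc = AssemblyScenario("selection", env_values=[0.2, 0.2], read_depth=1_000_000)
        tbl, _ = simulate_metacommunity(t, n, sc, seed=31)
        rel = tbl.relative_abundance()
        assert np.abs(rel.iloc[:, 0] - rel.iloc[:, 1]).max() < 0.01

    def test_env_outside_all_niches_errors(self):
        t, n = self._tree_niche(sigma=0.05)
        sc = AssemblyScenario("selection", env_values=[1e6])
        with pytest.raises(ValueError, match="sigma_niche"):
            simulate_metacommunity(t, n, sc, seed=1)

    def test_distance_decay_under_selection(self):
        # |env_i - env_k| correlates positively with Bray-Curtis(i, k)
        rhos = []
        for seed in range(5):
            t = simulate_tree(60, seed=100 + seed)
            n = evolve_optima(t, 1.0, seed=200 + seed, sigma_niche=0.5)
            env = np.linspace(n.optima.min(), n.optima.max(), 12)
            sc = AssemblyScenario("selection", env_values=env, read_depth=2000)
            tbl, _ = simulate_metacommunity(t, n, sc, seed=300 + seed)
            bc = bray_curtis(tbl)
            ii, jj = np.triu_indices(12, 1)
            rhos.append(spearmanr(np.abs(env[ii] - env[jj]), bc.data[ii, jj])[0])
        assert all(r > 0 for r in rhos)

    def test_neutral_bray_curtis_independent_of_env(self):
        rhos = []
        for seed in range(5):
            t = simulate_tree(60, seed=400 + seed)
            n = evolve_optima(t, 1.0, seed=500 + seed)
            env = np.linspace(-2, 2, 12)
            sc = AssemblyScenario("neutral", env_values=env, read_depth=2000)
            tbl, _ = simulate_metacommunity(t, n, sc, seed=600 + seed)
            bc = bray_curtis(tbl)
            ii, jj = np.triu_indices(12, 1)
            rhos.append(spearmanr(np.abs(env[ii] - env[jj]), bc.data[ii, jj])[0])
        # no systematic distance-decay in the neutral regime
        assert abs(np.mean(rhos)) < 0.2


class TestSimulatePairedRNA:
    def _dna(self, depth=100_000, n_tips=60):
        t = simulate_tree(n_tips, seed=42)
        n = evolve_optima(t, 1.0, seed=43)
        sc = AssemblyScenario("neutral", env_values=[0.0] * 4, read_depth=depth)
        tbl, _ = simulate_metacommunity(t, n, sc, seed=44)
        return tbl

    def test_identity_activity_gives_ra_one(self):
        dna = self._dna()
        am = ActivityModel(inactive_fraction=0.0, phantom_fraction=0.0, multiplier_sigma=0.0)
        paired, truth = simulate_paired_rna(dna, am, seed=7)
        dna_rel = paired.dna.relative_abundance()
        rna_rel = paired.rna.relative_abundance()
        common = dna_rel.loc[dna_rel.iloc[:, 0] > 1e-3].index
        ra = (rna_rel.loc[common] / dna_rel.loc[common]).to_numpy()
        assert np.abs(ra - 1.0).mean() < 0.2
        assert (truth["status"] == "active").all()

    def test_phantoms_absent_from_dna(self):
        dna = self._dna(depth=5000)
        am = ActivityModel(phantom_fraction=0.1)
        paired, truth = simulate_paired_rna(dna, am, seed=8)
        phantoms = truth.index[truth["status"] == "phantom"]
        assert len(phantoms) == round(0.1 * dna.n_asvs)
        assert set(phantoms).isdisjoint(paired.dna.asv_ids)
        assert set(phantoms) <= set(paired.rna.asv_ids)

    def test_rna_depth_preserved_with_phantoms(self):
        dna = self._dna(depth=5000)
        am = ActivityModel(phantom_fraction=0.1, inactive_fraction=0.2)
        paired, _ = simulate_paired_rna(dna, am, seed=9, read_depth=5000)
        assert (paired.rna.sample_sums() == 5000).all()

    def test_fraction_overflow_rejected(self):
        with pytest.raises(ValueError):
            ActivityModel(inactive_fraction=0.7, phantom_fraction=0.4)


class TestCladeTaxonomyAndSurvey:
    def test_groups_are_clades(self):
        t = simulate_tree(50, seed=3)
        tax = clade_taxonomy(t, 5)
        groups = {tax.group(tip) for tip in t.tip_names}
        assert len(groups) == 5
        # each group's tips form a connected clade: the group of the MRCA's
        # tips equals the group itself
        for g in groups:
            tips = [tip for tip in t.tip_names if tax.group(tip) == g]
            mrca = t.tree.lowest_common_ancestor(tips)
            assert {tax.group(x.name) for x in mrca.tips()} == {g}

    def test_survey_structure(self, survey):
        meta = survey["metadata"]
        assert set(meta["region"]) == {"seep", "non-seep"}
        assert survey["paired"].n_pairs == len(meta)
        # planted truth covers every RNA ASV
        assert set(survey["paired"].rna.asv_ids) <= set(survey["truth"].index)

    def test_survey_deterministic(self):
        a = simulate_survey(n_tips=60, seed=77, read_depth=1000)
        b = simulate_survey(n_tips=60, seed=77, read_depth=1000)
        pd.testing.assert_frame_equal(a["dna"].counts, b["dna"].counts)
        pd.testing.assert_frame_equal(a["paired"].rna.counts, b["paired"].rna.counts)
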