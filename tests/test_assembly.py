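import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepecol.assembly import (
    bmntd,
    bnti_for_table,
    classify_process,
    niche_values_from_env,
    null_bnti,
    patristic_distances,
    phylo_signal,
)
from seepecol.io import CommunityTable, read_newick
from seepecol.simulate import AssemblyScenario, evolve_optima, simulate_metacommunity, simulate_tree


def brute_force_bmntd(comm_k: dict, comm_m: dict, dist) -> float:
    """Independent oracle: literal double-loop over the printed equation."""
    def side(a, b):
        total_a = sum(a.values())
        acc = 0.0
        for i, ni in a.items():
            if ni <= 0:
                continue
            dmin = min(dist[i, j] for j, nj in b.items() if nj > 0)
            acc += (ni / total_a) * dmin
        return acc

    return 0.5 * (side(comm_k, comm_m) + side(comm_m, comm_k))


class TestPatristic:
    def test_example_tree(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree)
        assert dm["A", "B"] == 2 and dm["A", "C"] == 4 and dm["B", "C"] == 4

    def test_symmetric_zero_diagonal(self):
        t = simulate_tree(50, seed=0)
        d = patristic_distances(t).data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_matches_pathwalk_oracle(self):
        t = simulate_tree(50, seed=1)
        dm = patristic_distances(t)
        rng = np.random.default_rng(2)
        tips = {x.name: x for x in t.tree.tips()}
        names = list(tips)
        for _ in range(100):
            a, b = rng.choice(names, 2, replace=False)
            # independent traversal: sum branch lengths via the LCA
            lca = t.tree.lowest_common_ancestor([a, b])

            def up(node):
                acc = 0.0
                while node is not lca:
                    acc += node.length
                    node = node.parent
                return acc

            assert dm[a, b] == pytest.approx(up(tips[a]) + up(tips[b]), abs=1e-9)


class TestBmntd:
    def test_identical_communities_zero(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree)
        assert bmntd({"A": 3, "B": 1}, {"A": 3, "B": 1}, dm) == pytest.approx(0.0)

    def test_singletons_collapse_to_pairwise_distance(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree)
        assert bmntd({"A": 1}, {"B": 1}, dm) == pytest.approx(2.0)

    def test_hand_worked_example(self, three_tip_tree):
        # k={A:.5, C:.5}, m={B:1}: 0.5*[(0.5*2 + 0.5*4) + 1*2] = 2.5
        dm = patristic_distances(three_tip_tree)
        assert bmntd({"A": 0.5, "C": 0.5}, {"B": 1.0}, dm) == pytest.approx(2.5)

    def test_empty_community_rejected(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree)
        with pytest.raises(ValueError):
            bmntd({"A": 0}, {"B": 1}, dm)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_bruteforce_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        tree = simulate_tree(n, seed=int(rng.integers(2**31 - 1)))
        dm = patristic_distances(tree)
        tips = tree.tip_names
        k = {t: int(rng.integers(0, 5)) for t in tips}
        m = {t: int(rng.integers(0, 5)) for t in tips}
        if sum(k.values()) == 0:
            k[tips[0]] = 1
        if sum(m.values()) == 0:
            m[tips[-1]] = 1
        val = bmntd(k, m, dm)
        assert val == pytest.approx(brute_force_bmntd(k, m, dm), abs=1e-10)
        assert val == pytest.approx(bmntd(m, k, dm), abs=1e-12)
        # invariant to rescaling all counts of one community
        k10 = {t: 10 * v for t, v in k.items()}
        assert bmntd(k10, m, dm) == pytest.approx(val, abs=1e-12)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti,label",
        [
            (-3.1, "homogeneous_selection"),
            (0.0, "stochastic"),
            (2.5, "heterogeneous_selection"),
            (-2.0, "stochastic"),
            (2.0, "stochastic"),
        ],
    )
    def test_thresholds(self, bnti, label):
        assert classify_process(bnti) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_process(float("nan"))


class TestNullModel:
    def test_star_phylogeny_degenerate(self):
        star = read_newick("(A:1,B:1,C:1,D:1);")
        res = null_bnti({"A": 1, "B": 1}, {"C": 1, "D": 1}, star,
                        n_randomizations=99, seed=0)
        assert res.flagged_degenerate

    def test_identical_communities_centered(self):
        t = simulate_tree(20, seed=3)
        comm = {x: 1 for x in t.tip_names[:8]}
        res = null_bnti(comm, comm, t, n_randomizations=99, seed=1)
        assert res.bnti == 0.0 and res.process == "stochastic"

    def test_neutral_pair_is_stochastic(self):
        t = simulate_tree(80, seed=4)
        n = evolve_optima(t, 1.0, seed=5)
        sc = AssemblyScenario("neutral", env_values=[0.0] * 2, read_depth=1000)
        tbl, _ = simulate_metacommunity(t, n, sc, seed=6)
        res = null_bnti(tbl.counts.iloc[:, 0], tbl.counts.iloc[:, 1], t,
                        n_randomizations=199, seed=7)
        assert abs(res.bnti) < 3  # calibrated null: no strong deviation

    def test_table_runner_matches_single_pair_convention(self):
        t = simulate_tree(40, seed=8)
        n = evolve_optima(t, 1.0, seed=9)
        sc = AssemblyScenario("neutral", env_values=[0.0] * 4, read_depth=800,
                              drift_sigma=1.0)
        tbl, _ = simulate_metacommunity(t, n, sc, seed=10)
        res = bnti_for_table(tbl, t, n_randomizations=99, seed=11)
        assert len(res) == 6
        assert set(res["process"]) <= {
            "stochastic", "homogeneous_selection", "heterogeneous_selection",
            "undetermined",
        }
        # observed bmntd agrees with the direct per-pair implementation
        row = res.iloc[0]
        direct = bmntd(tbl.counts[row.sample_k], tbl.counts[row.sample_m],
                       patristic_distances(t))
        assert row.bmntd_obs == pytest.approx(direct, abs=1e-12)

    def test_observed_rank_uniform_under_neutrality(self):
        # exchangeability: the rank of the observed bmntd among its null draws
        # is uniform when communities carry no phylogenetic structure
        ranks = []
        for seed in range(30):
            t = simulate_tree(30, seed=700 + seed)
            rng = np.random.default_rng(800 + seed)
            k = pd.Series(rng.integers(0, 3, 30), index=t.tip_names)
            m = pd.Series(rng.integers(0, 3, 30), index=t.tip_names)
            if k.sum() == 0 or m.sum() == 0:
                continue
            res = null_bnti(k, m, t, n_randomizations=99, seed=900 + seed)
            if res.flagged_degenerate:
                continue
            ranks.append(res.bnti)
        frac_extreme = np.mean(np.abs(ranks) > 2)
        assert frac_extreme <= 0.2


class TestPhyloSignal:
    def test_brownian_optima_detected(self):
        t = simulate_tree(150, seed=20)
        n = evolve_optima(t, 1.0, seed=21)
        corr = phylo_signal(n.optima, patristic_distances(t),
                            n_permutations=199, seed=22)
        assert corr.signal_present and corr.r[0] > 0

    def test_constant_niche_flagged(self):
        t = simulate_tree(40, seed=23)
        vals = pd.Series(1.0, index=t.tip_names)
        corr = phylo_signal(vals, patristic_distances(t), n_permutations=99, seed=24)
        assert corr.flagged and not corr.signal_present

    def test_niche_values_abundance_weighted(self):
        counts = pd.DataFrame(
            {"s1": [4, 0], "s2": [4, 2]}, index=["x", "y"]
        )
        tbl = CommunityTable(counts)
        env = pd.Series({"s1": 1.0, "s2": 3.0})
        nv = niche_values_from_env(tbl, env)
        assert nv["x"] == pytest.approx(2.0)  # (4*1 + 4*3) / 8
        assert nv["y"] == pytest.approx(3.0)
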