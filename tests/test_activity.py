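import numpy as np
import pandas as pd
import pytest

from seepecol.activity import (
    abundant_groups,
    levins_breadth,
    relative_activity,
    seep_active_groups,
)
from seepecol.io import CommunityTable, PairedCommunity, TaxonomyMap, validate_metadata


def _paired(dna_counts, rna_counts, ids):
    samples = [f"s{i}" for i in range(dna_counts.shape[1])]
    dna = CommunityTable(pd.DataFrame(dna_counts, index=ids, columns=samples))
    rna = CommunityTable(pd.DataFrame(rna_counts, index=ids, columns=samples))
    return PairedCommunity(dna, rna, [(s, s) for s in samples])


class TestRelativeActivity:
    def test_ratio_definition(self):
        # DNA rel 0.01 vs RNA rel 0.02 -> RA = 2 (exact at matched depth)
        dna = np.array([[1], [99]])
        rna = np.array([[2], [98]])
        paired = _paired(dna * 100, rna * 100, ["a", "b"])
        act = relative_activity(paired, rarefaction_depth=10_000, seed=0)
        row = act[(act.asv_id == "a")].iloc[0]
        assert row.ra == pytest.approx(2.0)
        assert row.status == "active"

    def test_dna_only_kept_as_inactive(self):
        paired = _paired(np.array([[50], [50]]), np.array([[0], [100]]), ["a", "b"])
        act = relative_activity(paired, rarefaction_depth=100, seed=0)
        row = act[act.asv_id == "a"].iloc[0]
        assert row.ra == 0.0 and row.status == "inactive"

    def test_rna_only_is_phantom_and_excluded_from_ra(self):
        paired = _paired(np.array([[0], [100]]), np.array([[40], [60]]), ["a", "b"])
        act = relative_activity(paired, rarefaction_depth=100, seed=0)
        assert (act.loc[act.asv_id == "a", "status"] == "phantom").all()
        assert act.loc[act.asv_id == "a", "ra"].isna().all()

    def test_no_surviving_pairs_errors(self):
        paired = _paired(np.array([[5], [5]]), np.array([[5], [5]]), ["a", "b"])
        with pytest.raises(ValueError):
            relative_activity(paired, rarefaction_depth=1000, seed=0)


class TestAbundantGroups:
    def _tax(self):
        return TaxonomyMap(
            {
                "a": ("D", "P1", "G1"),
                "b": ("D", "P1", "G1"),
                "c": ("D", "P2", "G2"),
            },
            group_rank="class",
        )

    def test_threshold_rule(self):
        # G2 mean relabund 0.0015 > 0.1%; with a stricter threshold it drops out
        counts = pd.DataFrame(
            {"s1": [600, 397, 3], "s2": [499, 501, 0]}, index=["a", "b", "c"]
        )
        t = CommunityTable(counts)
        ab = abundant_groups(t, self._tax(), threshold=0.001)
        assert bool(ab.loc["G2", "abundant"]) is True
        ab2 = abundant_groups(t, self._tax(), threshold=0.01)
        assert bool(ab2.loc["G2", "abundant"]) is False

    def test_single_group_always_abundant(self):
        counts = pd.DataFrame({"s1": [10, 1]}, index=["a", "b"])
        tax = TaxonomyMap({"a": ("D", "P", "G"), "b": ("D", "P", "G")})
        ab = abundant_groups(CommunityTable(counts), tax, threshold=0.9)
        assert bool(ab.loc["G", "abundant"]) is True
        assert ab.loc["G", "mean_relabund"] == pytest.approx(1.0)


class TestLevinsBreadth:
    def test_uniform_profile_maximal(self):
        counts = pd.DataFrame(
            {f"s{i}": [10, 1] for i in range(4)}, index=["a", "b"]
        )
        res = levins_breadth(CommunityTable(counts))
        assert res.breadth["a"] == pytest.approx(4.0)
        assert res.n_communities == 4

    def test_single_sample_specialist(self):
        counts = pd.DataFrame(
            {"s0": [10, 5], "s1": [0, 5], "s2": [0, 5]}, index=["a", "b"]
        )
        res = levins_breadth(CommunityTable(counts))
        assert res.breadth["a"] == pytest.approx(1.0)

    def test_hand_worked_profile(self):
        # P = (0.5, 0.3, 0.2) -> B = 1/(0.25+0.09+0.04) = 2.6316
        counts = pd.DataFrame(
            {"s0": [50, 50], "s1": [30, 70], "s2": [20, 80]}, index=["a", "b"]
        )
        res = levins_breadth(CommunityTable(counts))
        assert res.breadth["a"] == pytest.approx(1 / 0.38, abs=1e-4)

    def test_bounds_and_scale_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(15, 6)),
            index=[f"t{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(6)],
        )
        counts.iloc[0] += 1
        t = CommunityTable(counts)
        res = levins_breadth(t)
        assert ((res.breadth >= 1 - 1e-9) & (res.breadth <= 6 + 1e-9)).all()
        # rescaling one taxon's counts across all samples leaves its B unchanged
        scaled = counts.copy()
        scaled.iloc[0] *= 7
        res2 = levins_breadth(CommunityTable(scaled))
        assert res2.breadth.iloc[0] == pytest.approx(res.breadth.iloc[0])

    def test_needs_two_communities(self):
        counts = pd.DataFrame({"s0": [1]}, index=["a"])
        with pytest.raises(ValueError):
            levins_breadth(CommunityTable(counts))


class TestSeepActiveGroups:
    def _setup(self, seep_ra, non_ra):
        """Build an activity frame with one group whose RA differs by region."""
        rows = []
        meta_rows = []
        for i, ra_vals in enumerate(seep_ra):
            pair = f"seep{i}"
            meta_rows.append((pair, "ROV1", 5.0))
            for j, v in enumerate(ra_vals):
                rows.append((f"asv{j}", pair, v, "active" if v > 0 else "inactive"))
        for i, ra_vals in enumerate(non_ra):
            pair = f"non{i}"
            meta_rows.append((pair, "ROV4", 5.0))
            for j, v in enumerate(ra_vals):
                rows.append((f"asv{j}", pair, v, "active" if v > 0 else "inactive"))
        act = pd.DataFrame(rows, columns=["asv_id", "pair", "ra", "status"])
        tax = TaxonomyMap({f"asv{j}": ("D", "P", "G1") for j in range(8)})
        meta = validate_metadata(
            pd.DataFrame(meta_rows, columns=["sample_id", "habitat", "depth_cmbs"])
        )
        return act, tax, meta

    def test_direction_rule_blocks_nonseep_winner(self):
        # strongly HIGHER RA in the non-seep region: significant but never flagged
        non = [[10 + j for j in range(8)] for _ in range(6)]
        seep = [[0.1] * 8 for _ in range(6)]
        act, tax, meta = self._setup(seep, non)
        out = seep_active_groups(act, tax, meta, ["G1"], aggregate="pool")
        assert out.loc["G1", "p"] < 0.05
        assert bool(out.loc["G1", "seep_active"]) is False

    def test_seep_winner_flagged(self):
        seep = [[5 + j * 0.1 for j in range(8)] for _ in range(6)]
        non = [[0.1 * (j + 1) for j in range(8)] for _ in range(6)]
        act, tax, meta = self._setup(seep, non)
        out = seep_active_groups(act, tax, meta, ["G1"])
        assert bool(out.loc["G1", "seep_active"]) is True

    def test_manual_include_is_flagged_as_override(self):
        seep = [[1.0] * 8 for _ in range(4)]
        non = [[1.0] * 8 for _ in range(4)]
        act, tax, meta = self._setup(seep, non)
        out = seep_active_groups(act, tax, meta, ["G1"], manual_include=("G1",))
        assert bool(out.loc["G1", "seep_active"]) is True
        assert bool(out.loc["G1", "manually_included"]) is True

    def test_phantoms_never_enter_pools(self):
        seep = [[1.0] * 8 for _ in range(4)]
        non = [[1.0] * 8 for _ in range(4)]
        act, tax, meta = self._setup(seep, non)
        phantom = pd.DataFrame(
            [("asv0", "seep0", np.nan, "phantom")],
            columns=["asv_id", "pair", "ra", "status"],
        )
        out = seep_active_groups(
            pd.concat([act, phantom]), tax, meta, ["G1"], aggregate="pool"
        )
        assert out.loc["G1", "n_seep"] == 32  # 4 pairs x 8 ASVs, phantom excluded
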