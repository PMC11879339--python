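"""Relative activity (RNA:DNA), seep-active groups and Levins' niche breadth.

The relative activity (RA) of an ASV in a sample pair is its relative
abundance in the RNA (cDNA) library divided by its relative abundance in the
DNA library, both computed on tables rarefied to a common depth.  RA is a
proxy of relative metabolic activity, not of growth rate.  ASVs detected
only in the DNA library keep RA = 0 (dead/dormant signal is informative);
"phantom" ASVs detected only in RNA are excluded from every RA summary.

A group (class, or phylum for microeukaryotes) is *abundant* when its mean
summed relative abundance across the regional community exceeds a threshold
(default 0.1%), and *seep-active* when its ASV-level RA values are
significantly higher (Wilcoxon rank-sum, Bonferroni-corrected) in seep than
in non-seep sample pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import rarefy
from .io import CommunityTable, PairedCommunity, TaxonomyMap
from .stats import bonferroni, wilcoxon_rank_sum

__all__ = [
    "relative_activity",
    "abundant_groups",
    "seep_active_groups",
    "levins_breadth",
    "GroupActivitySummary",
    "NicheBreadthResult",
]

logger = logging.getLogger(__name__)


def relative_activity(
    paired: PairedCommunity,
    rarefaction_depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(ASV, sample-pair) relative activity on rarefied tables.

    Both tables are rarefied to the same depth (default: 90% of the smallest
    sample total across both libraries).  Pairs in which either library
    falls below the depth are dropped; zero surviving pairs is an error.

    Returns a long DataFrame with columns ``asv_id``, ``pair`` (physical
    sample key = DNA sample id), ``ra`` and ``status``
    (``active``/``inactive``/``phantom``).  Phantom rows carry ``ra = NaN``
    and must be excluded from every summary (they are kept in the frame only
    so callers can report how many were removed).
    """
    if rarefaction_depth is None:
        rarefaction_depth = max(
            1,
            int(
                np.floor(
                    0.9
                    * min(
                        paired.dna.sample_sums().min(),
                        paired.rna.sample_sums().min(),
                    )
                )
            ),
        )
    rng = np.random.default_rng(seed)
    dna_r = rarefy(paired.dna, rarefaction_depth, seed=int(rng.integers(2**31 - 1)))
    rna_r = rarefy(paired.rna, rarefaction_depth, seed=int(rng.integers(2**31 - 1)))

    surviving = [
        (d, r)
        for d, r in paired.pairs
        if d in set(dna_r.sample_ids) and r in set(rna_r.sample_ids)
    ]
    if not surviving:
        raise ValueError("no sample pairs survive rarefaction")
    dropped = len(paired.pairs) - len(surviving)
    if dropped:
        logger.info("relative_activity: %d pairs dropped at depth %d",
                    dropped, rarefaction_depth)

    dna_rel = dna_r.relative_abundance()
    rna_rel = rna_r.relative_abundance()
    rows = []
    for d_id, r_id in surviving:
        d_col = dna_rel[d_id]
        r_col = rna_rel[r_id]
        for asv in dna_r.asv_ids:
            dv = d_col.get(asv, 0.0)
            rv = r_col.get(asv, 0.0) if asv in rna_rel.index else 0.0
            if dv > 0:
                ra = rv / dv
                rows.append(
                    (asv, d_id, ra, "active" if ra > 0 else "inactive")
                )
        # RNA-only detections in this pair: phantoms
        rna_only = set(rna_r.asv_ids) - set(dna_r.asv_ids)
        for asv in sorted(rna_only):
            if r_col.get(asv, 0.0) > 0:
                rows.append((asv, d_id, np.nan, "phantom"))
        for asv in dna_r.asv_ids:
            if d_col.get(asv, 0.0) == 0 and asv in rna_rel.index and r_col.get(asv, 0.0) > 0:
                rows.append((asv, d_id, np.nan, "phantom"))
    return pd.DataFrame(rows, columns=["asv_id", "pair", "ra", "status"])


def abundant_groups(
    table: CommunityTable,
    taxonomy: TaxonomyMap,
    threshold: float = 0.001,
) -> pd.DataFrame:
    """Groups whose mean relative abundance across samples exceeds
    ``threshold`` (default 0.1%).

    Returns a DataFrame indexed by group with columns ``mean_relabund`` and
    ``abundant`` (strictly above threshold).
    """
    rel = table.relative_abundance()
    groups = taxonomy.groups(table.asv_ids)
    by_group = rel.groupby(groups).sum()  # group x sample summed relabund
    mean_rel = by_group.mean(axis=1).sort_values(ascending=False)
    return pd.DataFrame(
        {"mean_relabund": mean_rel, "abundant": mean_rel > threshold}
    )


@dataclass
class GroupActivitySummary:
    """Region contrast of one group's ASV-level RA distribution."""

    group: str
    n_seep: int
    n_nonseep: int
    seep_median: float
    nonseep_median: float
    statistic: float
    p: float
    adjusted_p: float
    seep_active: bool
    manually_included: bool = False

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def seep_active_groups(
    activity: pd.DataFrame,
    taxonomy: TaxonomyMap,
    metadata: pd.DataFrame,
    abundant: pd.DataFrame | list[str],
    alpha: float = 0.05,
    manual_include: tuple[str, ...] = (),
    aggregate: str = "pair_median",
) -> pd.DataFrame:
    """Identify groups with significantly higher RA in seep samples.

    Per abundant group, RA observations (phantoms excluded, RA = 0
    retained) are contrasted between regions with a two-sided Wilcoxon
    rank-sum test; p-values are Bonferroni-corrected across the groups
    tested.  A group is seep-active when its adjusted p < ``alpha`` AND its
    seep median RA exceeds the non-seep median.

    ``aggregate`` controls the observational unit of the test:

    ``"pair_median"`` (default)
        one observation per sample pair — the median RA over the group's
        ASVs in that pair.  Sample pairs are the exchangeable units, so the
        test's size is honest; RA values of different ASVs within one
        sample share library-level effects and are not independent.
    ``"pool"``
        every (ASV, pair) RA value enters individually.  Maximises power
        but pseudo-replicates the per-sample correlation structure.
    ``"asv_mean"``
        one observation per ASV per region (mean over the region's pairs).

    ``manual_include`` forces named groups into the seep-active set; the
    flag ``manually_included`` records that the call was an override, never
    silent.
    """
    if aggregate not in ("pair_median", "pool", "asv_mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if isinstance(abundant, pd.DataFrame):
        group_list = list(abundant.index[abundant["abundant"]])
    else:
        group_list = list(abundant)
    obs = activity[activity["status"] != "phantom"].copy()
    obs["group"] = [taxonomy.group(a) for a in obs["asv_id"]]
    region_of = metadata["region"]

    rows = []
    raw_ps = []
    for g in group_list:
        sub = obs[obs["group"] == g].copy()
        sub["region"] = sub["pair"].map(region_of)
        if aggregate == "pool":
            seep_ra = sub.loc[sub["region"] == "seep", "ra"].to_numpy()
            non_ra = sub.loc[sub["region"] == "non-seep", "ra"].to_numpy()
        elif aggregate == "asv_mean":
            m = sub.groupby(["asv_id", "region"], observed=True)["ra"].mean().reset_index()
            seep_ra = m.loc[m["region"] == "seep", "ra"].to_numpy()
            non_ra = m.loc[m["region"] == "non-seep", "ra"].to_numpy()
        else:  # pair_median
            m = sub.groupby("pair", observed=True)["ra"].median().reset_index()
            m["region"] = m["pair"].map(region_of)
            seep_ra = m.loc[m["region"] == "seep", "ra"].to_numpy()
            non_ra = m.loc[m["region"] == "non-seep", "ra"].to_numpy()
        if seep_ra.size == 0 or non_ra.size == 0:
            logger.info("seep_active_groups: group %s lacks a region; skipped", g)
            continue
        res = wilcoxon_rank_sum(seep_ra, non_ra)
        rows.append(
            {
                "group": g,
                "n_seep": int(seep_ra.size),
                "n_nonseep": int(non_ra.size),
                "seep_median": float(np.median(seep_ra)),
                "nonseep_median": float(np.median(non_ra)),
                "statistic": res.statistic,
                "p": res.p,
            }
        )
        raw_ps.append(res.p)

    adj = bonferroni(raw_ps)
    out = []
    for row, ap in zip(rows, adj):
        row["adjusted_p"] = ap
        row["seep_active"] = bool(
            ap < alpha and row["seep_median"] > row["nonseep_median"]
        )
        row["manually_included"] = False
        if row["group"] in manual_include and not row["seep_active"]:
            row["seep_active"] = True
            row["manually_included"] = True
            logger.warning(
                "seep_active_groups: %s included by manual override (p=%.3g)",
                row["group"], row["p"],
            )
        out.append(row)
    return pd.DataFrame(out).set_index("group", drop=False)


@dataclass
class NicheBreadthResult:
    """Levins' niche breadth per taxon plus per-sample community summary."""

    breadth: pd.Series  # B_j per taxon, in [1, N]
    n_communities: int
    community_level: pd.Series  # abundance-weighted mean B per sample

    def as_frame(self) -> pd.DataFrame:
        return self.breadth.rename("levins_b").to_frame()


def levins_breadth(
    table: CommunityTable,
    scope: list[str] | None = None,
) -> NicheBreadthResult:
    """Levins' niche breadth B_j = 1 / sum_i P_ij^2 within a sample scope.

    ``P_ij`` is taxon *j*'s occupancy profile across the N local communities
    of the scope — its relative abundances renormalised per taxon so that
    ``sum_i P_ij = 1``.  B ranges from 1 (present in a single community:
    specialist) to N (uniform across all communities: generalist).  Taxa
    absent from every scope sample are excluded.  The community-level value
    of a sample is the abundance-weighted mean of B over the taxa present in
    it.
    """
    sub = table if scope is None else table.subset_samples(scope)
    if sub.n_samples < 2:
        raise ValueError("niche breadth needs >= 2 local communities")
    counts = sub.counts.astype(float)
    totals = counts.sum(axis=1)
    present = totals > 0
    counts = counts.loc[present]
    # per-taxon occupancy profile over the N local communities; normalising
    # the taxon's own counts makes B invariant to rescaling that taxon
    P = counts.div(counts.sum(axis=1), axis=0)
    b = 1.0 / (P**2).sum(axis=1)
    b.name = "levins_b"

    rel = sub.relative_abundance().loc[present]
    weights = rel.div(rel.sum(axis=0), axis=1)  # per-sample weights over present taxa
    community = (weights.mul(b, axis=0)).sum(axis=0)
    community.name = "community_levins_b"
    return NicheBreadthResult(b, sub.n_samples, community)
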