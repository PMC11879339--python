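"""Alpha, beta and gamma diversity for ASV count tables.

Alpha indices follow the survey's reporting set: observed richness, Chao1,
Faith's phylogenetic diversity (rooted convention — the path to the root is
included, so PD is monotone under ASV addition and a single-ASV sample gets
its root-to-tip distance), and Pielou's evenness.  Beta diversity is
Bray–Curtis on relative abundances; gamma diversity is the total ASV
richness of a habitat, compared at equal sample numbers via random species
accumulation curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import faith_pd
from skbio.stats.distance import anosim as _skbio_anosim

from .io import CommunityTable, Phylogeny

__all__ = [
    "rarefy",
    "alpha_diversity",
    "chao1",
    "pielou_evenness",
    "bray_curtis",
    "gamma_diversity",
    "accumulation_curve",
    "AccumulationCurve",
    "anosim",
]

logger = logging.getLogger(__name__)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged).  Subsampling
    is multivariate hypergeometric, i.e. drawing reads without replacement,
    so a sample already at ``depth`` keeps a valid (possibly re-ordered but
    numerically identical) composition only in distribution; a sample whose
    total equals ``depth`` is returned unchanged.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums.index[sums >= depth].tolist()
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not keep:
        raise ValueError(f"no samples reach rarefaction depth {depth}")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    return CommunityTable(pd.DataFrame(out, index=table.asv_ids))


def default_rarefaction_depth(table: CommunityTable, fraction: float = 0.9) -> int:
    """Default depth: 90% of the smallest sample total."""
    return max(1, int(np.floor(fraction * table.sample_sums().min())))


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S + F1^2/(2 F2), with the bias-corrected denominator
    S + F1(F1-1)/(2(F2+1)) when no doubletons exist."""
    counts = np.asarray(counts)
    s = int(np.count_nonzero(counts))
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    if f2 == 0:
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def pielou_evenness(counts: np.ndarray) -> float:
    """Pielou's J = H'/ln S; undefined (NaN) for single-taxon samples."""
    counts = np.asarray(counts, float)
    counts = counts[counts > 0]
    s = counts.size
    if s < 2:
        return float("nan")
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(s))


def alpha_diversity(table: CommunityTable, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity (richness, chao1, faith_pd, pielou).

    ``faith_pd`` requires every ASV present in the table to be a tip of the
    tree; pass ``tree=None`` to skip the phylogenetic index.
    """
    if tree is not None:
        missing = set(a for a in table.asv_ids
                      if (table.counts.loc[a] > 0).any()) - set(tree.tip_names)
        if missing:
            raise ValueError(
                f"{len(missing)} ASVs with reads are missing from the tree, "
                f"e.g. {sorted(missing)[:3]}"
            )
    records = []
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        if col.sum() == 0:
            raise ValueError(f"empty sample {s!r}")
        rec = {
            "sample_id": s,
            "richness": int(np.count_nonzero(col)),
            "chao1": chao1(col),
            "pielou": pielou_evenness(col),
        }
        if tree is not None:
            rec["faith_pd"] = float(
                faith_pd(col, taxa=table.asv_ids, tree=tree.tree)
            )
        records.append(rec)
    return pd.DataFrame(records).set_index("sample_id", drop=False)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples, on relative abundances."""
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples for beta diversity")
    rel = table.relative_abundance().to_numpy().T  # samples x ASVs
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def gamma_diversity(table: CommunityTable, grouping: pd.Series) -> pd.Series:
    """Total ASV richness per habitat (group of samples)."""
    out = {}
    for hab, samples in grouping.groupby(grouping).groups.items():
        sub = table.counts.loc[:, list(samples)]
        out[hab] = int((sub.sum(axis=1) > 0).sum())
    return pd.Series(out, name="gamma_richness")


@dataclass
class AccumulationCurve:
    """Random species accumulation curve for one habitat."""

    habitat: str
    n_sites: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int
    flagged: bool = False  # habitat had < 2 samples

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "habitat": self.habitat,
                "n_sites": self.n_sites,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def accumulation_curve(
    table: CommunityTable,
    grouping: pd.Series,
    n_permutations: int = 1000,
    n_sites_cap: int | None = None,
    seed: int = 0,
) -> dict[str, AccumulationCurve]:
    """Random-order ASV accumulation curve per habitat.

    Site order is permuted uniformly ``n_permutations`` times; the mean and
    SD of the cumulative unique-ASV count are reported for 1..cap sites,
    where cap defaults to the smallest habitat size so habitats are compared
    at an equal number of samples.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    groups = {h: list(idx) for h, idx in grouping.groupby(grouping).groups.items()}
    min_size = min(len(v) for v in groups.values())
    cap = min(n_sites_cap, min_size) if n_sites_cap else min_size

    curves: dict[str, AccumulationCurve] = {}
    for hab, samples in groups.items():
        presence = (table.counts.loc[:, samples].to_numpy() > 0)
        n = len(samples)
        k = min(cap, n)
        if n < 2:
            rich = int(presence.any(axis=1).sum())
            curves[hab] = AccumulationCurve(
                hab, np.array([1]), np.array([float(rich)]), np.array([0.0]),
                n_permutations, flagged=True,
            )
            continue
        acc = np.empty((n_permutations, k))
        for p in range(n_permutations):
            order = rng.permutation(n)
            seen = np.zeros(presence.shape[0], dtype=bool)
            for j in range(k):
                seen |= presence[:, order[j]]
                acc[p, j] = seen.sum()
        curves[hab] = AccumulationCurve(
            hab,
            np.arange(1, k + 1),
            acc.mean(axis=0),
            acc.std(axis=0, ddof=1),
            n_permutations,
        )
    return curves


def expected_accumulation(presence: np.ndarray, n: int) -> float:
    """Closed-form expected richness after drawing ``n`` of the N sites
    uniformly without replacement: sum_j [1 - C(N-m_j, n)/C(N, n)]."""
    from scipy.special import comb

    N = presence.shape[1]
    m = presence.sum(axis=1)
    return float(np.sum(1.0 - comb(N - m, n) / comb(N, n)))


def anosim(
    dist: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities (rank-based R statistic, permutation p).

    R contrasts the mean rank of between-group distances against
    within-group distances; p counts permutations with R at least as large
    as observed (the observed labelling included).  Every group must have
    >= 2 members.
    """
    labels = pd.Series(list(grouping))
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if (sizes < 2).any():
        raise ValueError("every ANOSIM group needs >= 2 members")
    # skbio's anosim permutes via the numpy global RNG; seed it locally for
    # the package-wide explicit-seed contract
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**32))
        res = _skbio_anosim(dist, list(grouping), permutations=n_permutations)
    finally:
        np.random.set_state(state)
    return float(res["test statistic"]), float(res["p-value"])
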