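"""Phylogenetic-turnover null models for community-assembly inference.

The central statistic is the abundance-weighted beta mean nearest taxon
distance between two local communities *k* and *m*:

    betaMNTD = 0.5 * [ sum_i f_ik * min_j Delta_ij  +  sum_i f_im * min_j Delta_ij ]

where ``f_ik`` is the relative abundance of ASV *i* in community *k*, the
minimum runs over the ASVs *j* present in the *other* community, and
``Delta`` is the patristic (branch-length path) distance.  A taxon present
in both communities matches itself at distance 0, so identical communities
have betaMNTD = 0.

The null model shuffles tip labels across the metacommunity taxon pool
(holding abundances and occupancy fixed) and recomputes betaMNTD; the
standardised deviation of the observation from the null is the beta nearest
taxon index (betaNTI).  betaNTI < -2 indicates homogeneous selection
(less turnover than expected), betaNTI > 2 heterogeneous selection,
|betaNTI| <= 2 stochastic assembly (dispersal, drift).

Inference from phylogenetic turnover presupposes a phylogenetic signal in
the taxa's environmental niches at short phylogenetic distances; the
Mantel-correlogram check for that prerequisite lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import CommunityTable, Phylogeny

__all__ = [
    "patristic_distances",
    "bmntd",
    "null_bnti",
    "bnti_for_table",
    "classify_process",
    "phylo_signal",
    "niche_values_from_env",
    "AssemblyResult",
    "SignalCorrelogram",
    "STOCHASTIC_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: |betaNTI| beyond this indicates dominance of deterministic selection
STOCHASTIC_THRESHOLD = 2.0


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all tips."""
    return tree.patristic_matrix()


def _as_relabund(comm, ids: list[str]) -> np.ndarray:
    """Align a community vector (mapping or Series) to ``ids`` and normalise
    to relative abundances over its present taxa."""
    if isinstance(comm, pd.Series):
        vec = comm.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    else:
        vec = np.array([float(comm.get(a, 0.0)) for a in ids])
    if np.any(vec < 0):
        raise ValueError("negative abundance in community vector")
    total = vec.sum()
    if total <= 0:
        raise ValueError("empty community")
    return vec / total


def bmntd(comm_k, comm_m, dist: DistanceMatrix) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two
    communities.

    ``comm_k``/``comm_m`` map ASV id -> abundance (counts or proportions;
    normalised internally, so the statistic depends only on relative
    abundances).  Minimum distances run over taxa with abundance > 0 in the
    other community; self-matching is allowed, so ``bmntd(c, c) == 0``.
    """
    ids = list(dist.ids)
    f_k = _as_relabund(comm_k, ids)
    f_m = _as_relabund(comm_m, ids)
    d = dist.data
    k_idx = np.flatnonzero(f_k > 0)
    m_idx = np.flatnonzero(f_m > 0)
    term_k = f_k[k_idx] @ d[np.ix_(k_idx, m_idx)].min(axis=1)
    term_m = f_m[m_idx] @ d[np.ix_(m_idx, k_idx)].min(axis=1)
    return float(0.5 * (term_k + term_m))


def _bmntd_matrix(F: np.ndarray, present: list[np.ndarray], d: np.ndarray,
                  pair_index: np.ndarray | None = None) -> np.ndarray:
    """betaMNTD for many samples at once.

    ``F`` is samples x taxa relative abundances, ``present[s]`` the index
    array of taxa present in sample ``s``, ``d`` the taxa x taxa distance
    matrix.  Computes, per sample ``m``, the profile
    ``min_{j in m} d[:, j]`` once and reuses it for every partner, so a full
    randomization costs O(S * T * avg_occupancy) instead of
    O(S^2 * T^2).
    """
    n = F.shape[0]
    colmin = np.empty((n, d.shape[0]))
    for s in range(n):
        colmin[s] = d[:, present[s]].min(axis=1)
    # B[k, m] = sum_i f_ik * min_{j in m} d[i, j]
    B = F @ colmin.T
    return 0.5 * (B + B.T)


@dataclass
class AssemblyResult:
    """betaMNTD, its null summary and the inferred assembly process for one
    sample pair."""

    sample_k: str
    sample_m: str
    bmntd_obs: float
    null_mean: float
    null_sd: float
    n_randomizations: int
    bnti: float
    process: str
    flagged_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "sample_k": self.sample_k,
            "sample_m": self.sample_m,
            "bmntd_obs": self.bmntd_obs,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_randomizations": self.n_randomizations,
            "bnti": self.bnti,
            "process": self.process,
            "flagged_degenerate": self.flagged_degenerate,
        }


def classify_process(bnti: float) -> str:
    """Map a betaNTI value to its assembly-process label."""
    if not np.isfinite(bnti):
        raise ValueError("betaNTI must be finite")
    if bnti < -STOCHASTIC_THRESHOLD:
        return "homogeneous_selection"
    if bnti > STOCHASTIC_THRESHOLD:
        return "heterogeneous_selection"
    return "stochastic"


def _result_from_nulls(sk, sm, obs, nulls, n_rand) -> AssemblyResult:
    null_mean = float(np.mean(nulls))
    null_sd = float(np.std(nulls, ddof=1))
    if null_sd == 0.0:
        # Point-mass null: either the two communities share their full
        # membership (every taxon self-matches under any shuffle) or the
        # tree itself is degenerate (e.g. equidistant star).  When the
        # observation coincides with the null the standardised deviation is
        # zero by the centering rule -> stochastic; otherwise the index is
        # undefined.  Both cases stay flagged.
        if abs(obs - null_mean) <= 1e-12:
            logger.warning(
                "point-mass null (sd=0, obs==mean) for pair (%s, %s); betaNTI=0", sk, sm
            )
            return AssemblyResult(sk, sm, obs, null_mean, 0.0, n_rand,
                                  0.0, "stochastic", flagged_degenerate=True)
        logger.warning("degenerate null distribution (sd=0) for pair (%s, %s)", sk, sm)
        return AssemblyResult(sk, sm, obs, null_mean, 0.0, n_rand,
                              float("nan"), "undetermined", flagged_degenerate=True)
    bnti = (obs - null_mean) / null_sd
    return AssemblyResult(sk, sm, obs, null_mean, null_sd, n_rand,
                          float(bnti), classify_process(bnti))


def null_bnti(
    comm_k,
    comm_m,
    tree: Phylogeny,
    n_randomizations: int = 999,
    seed: int = 0,
    pool: list[str] | None = None,
    sample_names: tuple[str, str] = ("k", "m"),
) -> AssemblyResult:
    """betaNTI for a single community pair.

    The null shuffles tip labels jointly across the taxon ``pool`` (default:
    the union of taxa present in the two communities), holding the abundance
    vectors fixed, and recomputes betaMNTD ``n_randomizations`` times.
    """
    if n_randomizations < 99:
        raise ValueError("n_randomizations must be >= 99")
    dist = tree.patristic_matrix()
    ids = list(dist.ids)
    f_k = _as_relabund(comm_k, ids)
    f_m = _as_relabund(comm_m, ids)
    if pool is None:
        pool_idx = np.flatnonzero((f_k > 0) | (f_m > 0))
    else:
        lookup = {a: i for i, a in enumerate(ids)}
        pool_idx = np.array(sorted(lookup[a] for a in pool))
    d = dist.data
    obs = bmntd(comm_k, comm_m, dist)

    rng = np.random.default_rng(seed)
    F = np.vstack([f_k, f_m])
    present = [np.flatnonzero(f_k > 0), np.flatnonzero(f_m > 0)]
    nulls = np.empty(n_randomizations)
    for r in range(n_randomizations):
        perm = pool_idx[rng.permutation(len(pool_idx))]
        remap = np.arange(len(ids))
        remap[pool_idx] = perm
        d_perm = d[np.ix_(remap, remap)]
        nulls[r] = _bmntd_matrix(F, present, d_perm)[0, 1]
    return _result_from_nulls(sample_names[0], sample_names[1], obs, nulls,
                              n_randomizations)


def bnti_for_table(
    table: CommunityTable,
    tree: Phylogeny,
    n_randomizations: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    metadata: pd.DataFrame | None = None,
    within_habitat_only: bool = False,
) -> pd.DataFrame:
    """betaNTI for many sample pairs of one table, sharing null draws.

    All pairs are evaluated against the same ``n_randomizations`` tip-label
    shuffles over the metacommunity taxon pool (every taxon with a read
    anywhere in the table), which is both the standard scheme and far
    cheaper than shuffling per pair.  ``pairs`` defaults to all unordered
    sample pairs, or all within-habitat pairs when ``within_habitat_only``
    is set (requires ``metadata`` with a ``habitat`` column).

    Returns a DataFrame of :class:`AssemblyResult` rows (plus a ``habitat``
    column when metadata is supplied).
    """
    if n_randomizations < 99:
        raise ValueError("n_randomizations must be >= 99")
    work = table.drop_empty_asvs()
    dist = tree.patristic_matrix()
    ids = list(dist.ids)
    id_pos = {a: i for i, a in enumerate(ids)}
    missing = set(work.asv_ids) - set(ids)
    if missing:
        raise ValueError(f"{len(missing)} table ASVs missing from tree")

    samples = work.sample_ids
    if pairs is None:
        if within_habitat_only:
            if metadata is None:
                raise ValueError("within_habitat_only requires metadata")
            pairs = []
            for _, members in metadata.loc[samples].groupby("habitat")["sample_id"]:
                ms = [m for m in members if m in set(samples)]
                pairs.extend(
                    (ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))
                )
        else:
            pairs = [
                (samples[i], samples[j])
                for i in range(len(samples))
                for j in range(i + 1, len(samples))
            ]
    if not pairs:
        raise ValueError("no sample pairs to evaluate")

    # relative abundances aligned to the tree's id order
    rel = work.relative_abundance()
    T = len(ids)
    S = len(samples)
    F = np.zeros((S, T))
    row_idx = np.array([id_pos[a] for a in work.asv_ids])
    F[:, row_idx] = rel.to_numpy().T
    present = [np.flatnonzero(F[s] > 0) for s in range(S)]
    s_pos = {s: i for i, s in enumerate(samples)}
    pool_idx = np.flatnonzero(F.sum(axis=0) > 0)

    d = dist.data
    obs_mat = _bmntd_matrix(F, present, d)

    rng = np.random.default_rng(seed)
    pair_ij = np.array([(s_pos[a], s_pos[b]) for a, b in pairs])
    nulls = np.empty((n_randomizations, len(pairs)))
    remap = np.arange(T)
    for r in range(n_randomizations):
        perm = pool_idx[rng.permutation(len(pool_idx))]
        remap[pool_idx] = perm
        d_perm = d[np.ix_(remap, remap)]
        null_mat = _bmntd_matrix(F, present, d_perm)
        nulls[r] = null_mat[pair_ij[:, 0], pair_ij[:, 1]]

    rows = []
    for p, (a, b) in enumerate(pairs):
        res = _result_from_nulls(
            a, b, float(obs_mat[s_pos[a], s_pos[b]]), nulls[:, p], n_randomizations
        )
        row = res.as_dict()
        if metadata is not None and a in metadata.index and b in metadata.index:
            ha, hb = metadata.loc[a, "habitat"], metadata.loc[b, "habitat"]
            row["habitat"] = ha if ha == hb else f"{ha}|{hb}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phylogenetic-signal prerequisite
# ---------------------------------------------------------------------------

@dataclass
class SignalCorrelogram:
    """Mantel correlogram of niche distance against phylogenetic distance.

    ``r`` per distance class is signed so that a positive value means taxa
    within the class have *more similar* niche values than average
    (positive phylogenetic autocorrelation); ``p`` is the one-tailed
    permutation probability of an r at least as positive.
    """

    class_bounds: np.ndarray  # length n_classes + 1
    r: np.ndarray
    p: np.ndarray
    n_permutations: int
    signal_present: bool
    flagged: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_low": self.class_bounds[:-1],
                "class_high": self.class_bounds[1:],
                "mantel_r": self.r,
                "p": self.p,
            }
        )


def niche_values_from_env(table: CommunityTable, env: pd.Series) -> pd.Series:
    """Per-ASV niche value: abundance-weighted mean of an environmental
    variable across the samples the ASV occurs in."""
    counts = table.counts
    env = env.reindex(counts.columns)
    if env.isna().any():
        raise ValueError("env values missing for some samples")
    weights = counts.to_numpy(dtype=float)
    totals = weights.sum(axis=1)
    keep = totals > 0
    vals = (weights @ env.to_numpy()) / np.where(totals > 0, totals, 1.0)
    return pd.Series(vals[keep], index=counts.index[keep], name="niche_value")


def phylo_signal(
    niche_values: pd.Series,
    dist: DistanceMatrix,
    n_classes: int = 8,
    n_permutations: int = 499,
    seed: int = 0,
) -> SignalCorrelogram:
    """Test for phylogenetic signal in niche values (Mantel correlogram).

    The phylogenetic-distance range is split into ``n_classes`` equal-width
    classes.  For each class the statistic is the (negated) Pearson
    correlation, over all taxon pairs, between the niche distance
    ``|v_i - v_j|`` and the in-class indicator — positive when close
    relatives share environmental optima.  Significance comes from jointly
    permuting niche values across taxa.  ``signal_present`` is true when the
    shortest class shows a significantly positive correlation, the
    prerequisite for betaNTI-based inference.
    """
    ids = [a for a in dist.ids if a in niche_values.index]
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa with niche values")
    if len(ids) < 30:
        logger.warning("phylo_signal: only %d taxa; results unreliable", len(ids))
    v = niche_values.loc[ids].to_numpy(dtype=float)
    d = dist.filter(ids).data
    iu = np.triu_indices(len(ids), k=1)
    dvec = d[iu]

    bounds = np.linspace(dvec.min(), dvec.max(), n_classes + 1)
    masks = []
    for c in range(n_classes):
        hi_incl = c == n_classes - 1
        m = (dvec >= bounds[c]) & ((dvec <= bounds[c + 1]) if hi_incl else (dvec < bounds[c + 1]))
        masks.append(m)

    P = dvec.size
    w_stats = []
    for m in masks:
        nw = int(m.sum())
        w_stats.append((m, nw, nw / P, np.sqrt(nw / P * (1 - nw / P))))

    def class_r(a: np.ndarray) -> np.ndarray:
        a_mean = a.mean()
        a_sd = a.std()
        out = np.full(n_classes, np.nan)
        if a_sd == 0:
            return out
        for c, (m, nw, w_mean, w_sd) in enumerate(w_stats):
            if nw == 0 or w_sd == 0:
                continue
            cov = a[m].sum() / P - a_mean * w_mean
            # negate: smaller within-class niche distance => positive signal
            out[c] = -cov / (a_sd * w_sd)
        return out

    avec = np.abs(v[iu[0]] - v[iu[1]])
    r_obs = class_r(avec)
    flagged = bool(np.all(np.isnan(r_obs)))

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(n_classes)
    valid = np.zeros(n_classes)
    for _ in range(n_permutations):
        vp = v[rng.permutation(v.size)]
        rp = class_r(np.abs(vp[iu[0]] - vp[iu[1]]))
        ok = ~np.isnan(rp) & ~np.isnan(r_obs)
        count_ge[ok & (rp >= r_obs)] += 1
        valid[ok] += 1
    p = np.where(
        np.isnan(r_obs), np.nan, (count_ge + 1.0) / (valid + 1.0)
    )

    signal = bool(
        not flagged
        and np.isfinite(r_obs[0])
        and r_obs[0] > 0
        and p[0] < 0.05
    )
    return SignalCorrelogram(bounds, r_obs, p, n_permutations, signal, flagged)
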