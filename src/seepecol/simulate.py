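"""Synthetic metacommunity generator.

Generates everything the inference chain consumes — a phylogeny, ASV count
tables for a DNA and a paired RNA library, taxonomy, sample metadata and the
planted ground truth — with the statistical structure the analysis assumes:

* niche optima evolve by Brownian motion on the tree, so a phylogenetic
  signal exists at short phylogenetic distances;
* samples assemble either under Gaussian environmental filtering
  (``selection``), by neutral multinomial sampling from a lognormal regional
  pool (``neutral``), or as a convex mixture (``mixed``);
* RNA libraries re-sample the DNA community through per-ASV activity
  multipliers, with a configurable fraction of fully inactive ASVs (RNA
  expectation zero) and a configurable fraction of "phantom" ASVs present
  only in RNA.

Every generator is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    CommunityTable,
    PairedCommunity,
    Phylogeny,
    TaxonomyMap,
    SEEP_HABITATS,
    NONSEEP_HABITATS,
    region_of_habitat,
)

__all__ = [
    "NicheModel",
    "AssemblyScenario",
    "ActivityModel",
    "simulate_tree",
    "evolve_optima",
    "lognormal_pool",
    "simulate_metacommunity",
    "simulate_paired_rna",
    "clade_taxonomy",
    "simulate_survey",
]


@dataclass
class NicheModel:
    """Per-ASV environmental optima plus the shared niche tolerance.

    ``optima`` is indexed by tree tip name.  ``sigma_niche`` is the standard
    deviation of the Gaussian filter (same units as the environmental axis);
    ``brownian_rate`` is the variance accumulated per unit branch length.
    """

    optima: pd.Series
    sigma_niche: float = 0.5
    brownian_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_niche <= 0:
            raise ValueError("sigma_niche must be positive")
        if self.brownian_rate < 0:
            raise ValueError("brownian_rate must be non-negative")


@dataclass
class AssemblyScenario:
    """Conditions under which a set of local communities assembles.

    ``process`` is one of ``selection``/``neutral``/``mixed``; ``env_values``
    gives one environmental value per sample (ignored by the neutral
    expectation but still recorded in metadata); ``mixture_weight`` is the
    weight on the selection component for ``mixed``.
    """

    process: str
    env_values: Sequence[float]
    read_depth: int = 10_000
    habitats: Sequence[str] | None = None
    depths_cmbs: Sequence[float] | None = None
    pool: np.ndarray | None = None
    pool_sigma: float = 1.5
    mixture_weight: float = 0.5
    #: lognormal sigma of per-sample, per-taxon abundance multipliers
    #: (ecological drift / priority effects between replicate communities);
    #: 0 recovers pure multinomial sampling of the expectation
    drift_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.process not in ("selection", "neutral", "mixed"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.read_depth < 100:
            raise ValueError("read_depth must be >= 100")
        env = np.asarray(self.env_values, float)
        if not np.all(np.isfinite(env)):
            raise ValueError("env_values must be finite")
        if not (0.0 <= self.mixture_weight <= 1.0):
            raise ValueError("mixture_weight must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.env_values)


@dataclass
class ActivityModel:
    """Planted RNA activity structure.

    ``inactive_fraction`` of DNA ASVs get RNA expectation 0;
    ``phantom_fraction`` (of the DNA ASV count) phantom ASVs are injected
    into RNA only; the remainder are active with lognormal multipliers.
    A group of ASVs can additionally be boosted by ``boost_factor`` in
    ``boost_samples`` to plant a region-specific activity contrast.
    """

    inactive_fraction: float = 0.0
    phantom_fraction: float = 0.0
    multiplier_sigma: float = 1.0
    phantom_lambda: float = 5.0
    boost_asvs: frozenset[str] = frozenset()
    boost_samples: frozenset[str] = frozenset()
    boost_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("inactive_fraction", "phantom_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.inactive_fraction + self.phantom_fraction > 1.0:
            raise ValueError("inactive_fraction + phantom_fraction exceeds 1")
        if self.boost_factor <= 0:
            raise ValueError("boost_factor must be positive")
        self.boost_asvs = frozenset(self.boost_asvs)
        self.boost_samples = frozenset(self.boost_samples)


# ---------------------------------------------------------------------------
# tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Simulate a rooted binary pure-birth (Yule) tree.

    Lineages split at rate ``birth_rate`` each; the simulation runs until
    ``n_tips`` lineages exist plus one final waiting interval, so terminal
    branches have positive length.  Tips are labelled ``ASV0001``… in
    left-to-right order.  Deterministic given the seed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    active: list[TreeNode] = [root]
    pending = {id(root): 0.0}
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            pending[id(node)] += wait
        idx = rng.integers(k)
        parent = active.pop(idx)
        parent.length = pending.pop(id(parent))
        children = [TreeNode(), TreeNode()]
        parent.extend(children)
        for ch in children:
            pending[id(ch)] = 0.0
        active.extend(children)
    final = rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.length = pending.pop(id(node)) + final

    root.length = None
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"ASV{i:04d}"
    return Phylogeny(root)


def evolve_optima(tree: Phylogeny, brownian_rate: float, seed: int,
                  sigma_niche: float = 0.5, root_value: float = 0.0) -> NicheModel:
    """Evolve environmental optima by Brownian motion root-to-tip.

    Each branch of length :math:`\\ell` adds an independent
    :math:`\\mathcal{N}(0, \\mathrm{rate} \\cdot \\ell)` increment, so the
    variance of the difference between two tips equals rate × their
    patristic distance.
    """
    if brownian_rate < 0:
        raise ValueError("brownian_rate must be non-negative")
    if tree.total_branch_length() == 0:
        raise ValueError("tree has zero total branch length")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): root_value}
    optima: dict[str, float] = {}
    for node in tree.tree.preorder(include_self=False):
        step_sd = np.sqrt(brownian_rate * (node.length or 0.0))
        val = values[id(node.parent)] + rng.normal(0.0, step_sd)
        values[id(node)] = val
        if node.is_tip():
            optima[node.name] = val
    series = pd.Series(optima, name="optimum").loc[tree.tip_names]
    return NicheModel(series, sigma_niche=sigma_niche, brownian_rate=brownian_rate)


def lognormal_pool(asv_ids: Sequence[str], seed: int, sigma: float = 1.5) -> pd.Series:
    """Lognormal(0, sigma) regional-pool abundances — a realistic
    abundant/rare split with a long tail of rare taxa."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.lognormal(0.0, sigma, len(asv_ids)), index=list(asv_ids))


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _expected_relabund(process, pool, optima, sigma, env_i, mixture_weight):
    neutral = pool / pool.sum()
    if process == "neutral":
        return neutral
    gauss = pool * np.exp(-((env_i - optima) ** 2) / (2.0 * sigma ** 2))
    total = gauss.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(
            "all expected abundances are 0 (env far outside all niches); "
            "widen sigma_niche or move env_values"
        )
    sel = gauss / total
    if process == "selection":
        return sel
    return mixture_weight * sel + (1.0 - mixture_weight) * neutral


def simulate_metacommunity(
    tree: Phylogeny,
    niche: NicheModel,
    scenario: AssemblyScenario,
    seed: int,
    sample_prefix: str = "S",
) -> tuple[CommunityTable, pd.DataFrame]:
    """Assemble local communities on an environmental gradient.

    Under ``selection`` the expected relative abundance of ASV *j* in sample
    *i* is proportional to ``pool_j * exp(-(env_i - opt_j)^2 / (2 sigma^2))``;
    under ``neutral`` it is proportional to ``pool_j`` alone; ``mixed``
    blends the two normalised expectations by ``mixture_weight``.  Reads are
    drawn multinomially at ``read_depth``, so every column sums exactly to
    the configured depth.

    Returns the count table and a metadata frame (sample_id, habitat,
    region, depth_cmbs, env).
    """
    rng = np.random.default_rng(seed)
    tips = tree.tip_names
    missing = set(tips) - set(niche.optima.index)
    if missing:
        raise ValueError(f"niche model lacks optima for {len(missing)} tips")
    pool = (
        pd.Series(np.asarray(scenario.pool, float), index=tips)
        if scenario.pool is not None
        else lognormal_pool(tips, seed=int(rng.integers(2**31 - 1)), sigma=scenario.pool_sigma)
    )
    optima = niche.optima.loc[tips].to_numpy()
    pool_arr = pool.loc[tips].to_numpy()

    n = scenario.n_samples
    habitats = list(scenario.habitats) if scenario.habitats is not None else ["ROV1"] * n
    if len(habitats) != n:
        raise ValueError("habitats length must match env_values length")
    depths = (
        list(scenario.depths_cmbs)
        if scenario.depths_cmbs is not None
        else [5.0] * n
    )

    counts = np.empty((len(tips), n), dtype=np.int64)
    for i, env_i in enumerate(np.asarray(scenario.env_values, float)):
        p = _expected_relabund(
            scenario.process, pool_arr, optima, niche.sigma_niche, env_i,
            scenario.mixture_weight,
        )
        if scenario.drift_sigma > 0:
            p = p * rng.lognormal(0.0, scenario.drift_sigma, p.size)
        counts[:, i] = rng.multinomial(scenario.read_depth, p / p.sum())

    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    table = CommunityTable(pd.DataFrame(counts, index=tips, columns=sample_ids))
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "habitat": habitats,
            "region": [region_of_habitat(h) for h in habitats],
            "depth_cmbs": depths,
            "env": np.asarray(scenario.env_values, float),
            "process": scenario.process,
        }
    ).set_index("sample_id", drop=False)
    return table, meta


# ---------------------------------------------------------------------------
# paired RNA libraries
# ---------------------------------------------------------------------------

def simulate_paired_rna(
    dna: CommunityTable,
    activity: ActivityModel,
    seed: int,
    phantom_candidates: Sequence[str] | None = None,
    read_depth: int | None = None,
) -> tuple[PairedCommunity, pd.DataFrame]:
    """Generate an RNA table matched sample-for-sample to a DNA table.

    Each DNA ASV is planted as ``inactive`` (RNA expectation 0) with
    probability ``inactive_fraction`` or ``active`` with a lognormal activity
    multiplier; the RNA expectation of an active ASV in a sample is its DNA
    relative abundance times its multiplier, renormalised.  Phantom ASVs
    (absent from DNA) receive Poisson(``phantom_lambda``) reads per sample,
    carved out of the fixed RNA depth before the active ASVs are sampled
    multinomially, so RNA columns also sum to the configured depth.

    Returns the paired community plus the planted per-ASV truth
    (status ``active``/``inactive``/``phantom`` and multiplier).
    """
    rng = np.random.default_rng(seed)
    asvs = dna.asv_ids
    n_asv = len(asvs)

    n_inactive = int(round(activity.inactive_fraction * n_asv))
    order = rng.permutation(n_asv)
    inactive_idx = set(order[:n_inactive].tolist())
    status = np.array(
        ["inactive" if i in inactive_idx else "active" for i in range(n_asv)]
    )
    multipliers = rng.lognormal(0.0, activity.multiplier_sigma, n_asv)
    multipliers[status == "inactive"] = 0.0

    n_phantom = int(round(activity.phantom_fraction * n_asv))
    if n_phantom:
        if phantom_candidates is not None:
            cand = [c for c in phantom_candidates if c not in set(asvs)]
            if len(cand) < n_phantom:
                raise ValueError(
                    f"need {n_phantom} phantom candidates, got {len(cand)}"
                )
            phantom_ids = list(rng.choice(cand, n_phantom, replace=False))
        else:
            phantom_ids = [f"PHANTOM{i + 1:04d}" for i in range(n_phantom)]
    else:
        phantom_ids = []

    dna_rel = dna.relative_abundance().to_numpy()
    sums = dna.sample_sums().to_numpy()
    n_samples = dna.n_samples
    depths = np.full(n_samples, read_depth, dtype=np.int64) if read_depth else sums

    mult_base = multipliers[:, None] * np.ones((1, n_samples))
    if activity.boost_asvs:
        boost_rows = np.array([a in activity.boost_asvs for a in asvs])
        boost_cols = np.array([s in activity.boost_samples for s in dna.sample_ids])
        mult_base[np.ix_(boost_rows, boost_cols)] *= activity.boost_factor

    rna_counts = np.zeros((n_asv + len(phantom_ids), n_samples), dtype=np.int64)
    for i in range(n_samples):
        phantom_reads = rng.poisson(activity.phantom_lambda, len(phantom_ids))
        phantom_reads = np.minimum(phantom_reads, depths[i])  # degenerate guard
        budget = int(depths[i] - phantom_reads.sum())
        if budget < 0:
            # extreme phantom load: truncate proportionally
            scale = depths[i] / phantom_reads.sum()
            phantom_reads = np.floor(phantom_reads * scale).astype(np.int64)
            budget = int(depths[i] - phantom_reads.sum())
        expected = dna_rel[:, i] * mult_base[:, i]
        total = expected.sum()
        if total > 0 and budget > 0:
            rna_counts[:n_asv, i] = rng.multinomial(budget, expected / total)
        rna_counts[n_asv:, i] = phantom_reads

    all_ids = asvs + phantom_ids
    rna = CommunityTable(
        pd.DataFrame(rna_counts, index=all_ids, columns=dna.sample_ids)
    )
    truth = pd.DataFrame(
        {
            "asv_id": all_ids,
            "status": list(status) + ["phantom"] * len(phantom_ids),
            "multiplier": list(multipliers) + [np.nan] * len(phantom_ids),
        }
    ).set_index("asv_id", drop=False)
    paired = PairedCommunity(dna, rna, [(s, s) for s in dna.sample_ids])
    return paired, truth


# ---------------------------------------------------------------------------
# taxonomy and full-survey convenience
# ---------------------------------------------------------------------------

def clade_taxonomy(tree: Phylogeny, n_groups: int, group_rank: str = "class") -> TaxonomyMap:
    """Assign tips to ``n_groups`` synthetic taxonomic groups by clade.

    The root clade is split repeatedly (largest clade first) until
    ``n_groups`` clades exist; each clade becomes one group, so group
    membership is phylogenetically coherent — as real class/phylum labels
    are.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    clades = [tree.tree]
    while len(clades) < n_groups:
        splittable = [c for c in clades if not c.is_tip()]
        if not splittable:
            break
        largest = max(splittable, key=lambda c: sum(1 for _ in c.tips()))
        clades.remove(largest)
        clades.extend(largest.children)
    lineages = {}
    for gi, clade in enumerate(clades, start=1):
        label = f"Group{gi:02d}"
        tips = [clade.name] if clade.is_tip() else [t.name for t in clade.tips()]
        for tip in tips:
            lineages[tip] = ("Synthetica", label, label, "unclassified",
                             "unclassified", "unclassified")
    return TaxonomyMap(lineages, group_rank=group_rank)


#: per-habitat sample counts of the emulated survey design (three seep ROVs,
#: two smaller non-seep reference ROVs)
DEFAULT_DESIGN: dict[str, int] = {
    "ROV1": 9, "ROV2": 9, "ROV3": 10, "ROV4": 3, "ROV5": 2,
}


def simulate_survey(
    n_tips: int = 200,
    seed: int = 0,
    design: Mapping[str, int] | None = None,
    read_depth: int = 5_000,
    sigma_niche: float = 0.3,
    brownian_rate: float = 1.0,
    inactive_fraction: float = 0.3,
    phantom_fraction: float = 0.05,
    n_groups: int = 8,
    seep_boost_group: str | None = None,
    seep_boost_factor: float = 1.0,
    env_jitter: float = 0.1,
    drift_sigma: float = 2.0,
    seep_env_quantiles: tuple[float, float, float] = (0.02, 0.05, 0.98),
    seep_process: str = "selection",
) -> dict:
    """Generate a complete synthetic survey emulating the seep/non-seep design.

    Seep habitats (ROV1–3) assemble under Gaussian environmental filtering
    at habitat-specific environmental values placed in the *tails* of the
    evolved-optima distribution (``seep_env_quantiles``) — extreme
    environments, like seep chemistry, select the few lineages whose
    conserved optima reach the tail, which is what makes homogeneous
    selection detectable as depressed phylogenetic turnover.  Non-seep
    habitats (ROV4–5) assemble neutrally at the trait-field median.
    ``drift_sigma`` adds lognormal per-sample compositional drift on top of
    the expectation, emulating the strong replicate-to-replicate turnover of
    real sediment communities.  A fraction of tree tips is reserved (zero
    pool abundance) to serve as phantom candidates for the RNA library.

    Returns a dict with keys ``tree``, ``niche``, ``pool``, ``dna``,
    ``metadata``, ``taxonomy``, ``paired``, ``truth``.
    """
    design = dict(design or DEFAULT_DESIGN)
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
    niche = evolve_optima(
        tree, brownian_rate, seed=int(rng.integers(2**31 - 1)), sigma_niche=sigma_niche
    )
    pool = lognormal_pool(tree.tip_names, seed=int(rng.integers(2**31 - 1)))
    # reserve tips for phantom injection so RNA tables stay on the tree
    n_reserve = max(int(round(0.1 * n_tips)), int(np.ceil(phantom_fraction * n_tips)) + 1)
    reserved = list(rng.choice(tree.tip_names, n_reserve, replace=False))
    pool.loc[reserved] = 0.0

    opt = niche.optima
    seep_env = dict(zip(SEEP_HABITATS, np.quantile(opt, list(seep_env_quantiles))))
    habitats, env_values, depths = [], [], []
    for hab, n in design.items():
        for k in range(n):
            habitats.append(hab)
            depths.append(float(5 * (k % 2)))  # alternate 0 / 5 cmbs layers
            if hab in seep_env:
                env_values.append(seep_env[hab] + rng.normal(0.0, env_jitter))
            else:
                env_values.append(float(np.median(opt)))

    # assemble seep (selection) and non-seep (neutral) samples in one pass:
    # per-sample process is selection iff the habitat is a seep habitat
    tips = tree.tip_names
    optima_arr = opt.loc[tips].to_numpy()
    pool_arr = pool.loc[tips].to_numpy()
    if seep_process not in ("selection", "neutral", "mixed"):
        raise ValueError(f"unknown seep_process {seep_process!r}")
    counts = np.empty((len(tips), len(habitats)), dtype=np.int64)
    for i, (hab, env_i) in enumerate(zip(habitats, env_values)):
        process = seep_process if region_of_habitat(hab) == "seep" else "neutral"
        p = _expected_relabund(process, pool_arr, optima_arr, sigma_niche, env_i, 0.5)
        if drift_sigma > 0:
            p = p * rng.lognormal(0.0, drift_sigma, p.size)
        counts[:, i] = rng.multinomial(read_depth, p / p.sum())
    sample_ids = [f"{h}_c{i + 1:02d}" for i, h in enumerate(habitats)]
    dna = CommunityTable(
        pd.DataFrame(counts, index=tips, columns=sample_ids)
    ).drop_empty_asvs()
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "habitat": habitats,
            "region": [region_of_habitat(h) for h in habitats],
            "depth_cmbs": depths,
            "env": env_values,
        }
    ).set_index("sample_id", drop=False)

    taxonomy = clade_taxonomy(tree, n_groups)
    boost_asvs: frozenset[str] = frozenset()
    boost_samples: frozenset[str] = frozenset()
    if seep_boost_group is not None:
        boost_asvs = frozenset(
            a for a in dna.asv_ids if taxonomy.group(a) == seep_boost_group
        )
        boost_samples = frozenset(
            meta.index[meta["region"] == "seep"].tolist()
        )
    activity = ActivityModel(
        inactive_fraction=inactive_fraction,
        phantom_fraction=phantom_fraction,
        boost_asvs=boost_asvs,
        boost_samples=boost_samples,
        boost_factor=seep_boost_factor,
    )
    phantom_cand = [t for t in reserved if t not in set(dna.asv_ids)]
    paired, truth = simulate_paired_rna(
        dna, activity, seed=int(rng.integers(2**31 - 1)),
        phantom_candidates=phantom_cand, read_depth=read_depth,
    )
    return {
        "tree": tree,
        "niche": niche,
        "pool": pool,
        "dna": dna,
        "metadata": meta,
        "taxonomy": taxonomy,
        "paired": paired,
        "truth": truth,
        "activity_model": activity,
    }


def write_survey(survey: Mapping, out_dir, seed: int | None = None) -> dict[str, str]:
    """Write a generated survey to disk as the pipeline's input files.

    Emits ``dna.tsv``, ``rna.tsv``, ``tree.nwk``, ``taxonomy.tsv``,
    ``metadata.tsv`` and ``truth.tsv`` (planted per-ASV activity status and
    niche optima — generator ground truth, not an observable).  Returns the
    path map.
    """
    from pathlib import Path

    from .io import (
        write_community_table,
        write_metadata,
        write_newick,
        write_result_table,
        write_taxonomy,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {"generator": "seepecol.simulate.simulate_survey"}
    if seed is not None:
        params["seed"] = seed
    paths = {
        "dna": out / "dna.tsv",
        "rna": out / "rna.tsv",
        "tree": out / "tree.nwk",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_community_table(survey["dna"], paths["dna"], params)
    write_community_table(survey["paired"].rna, paths["rna"], params)
    write_newick(survey["tree"], paths["tree"])
    write_taxonomy(survey["taxonomy"], paths["taxonomy"])
    write_metadata(survey["metadata"], paths["metadata"], params)
    truth = survey["truth"].copy()
    optima = survey["niche"].optima
    truth["optimum"] = [optima.get(a, float("nan")) for a in truth.index]
    write_result_table(truth, paths["truth"], params, index=False)
    return {k: str(v) for k, v in paths.items()}
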