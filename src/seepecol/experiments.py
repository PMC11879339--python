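"""Validation experiments on synthetic metacommunities.

Each function runs one planted-truth experiment at frozen study conditions
and returns plain numbers, so the same code backs both the test suite and
the reproduction script.  Conditions (tree sizes, read depths, niche widths,
drift) are the package's synthetic study design; the rationale for each
choice is documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from . import activity as act
from . import assembly as asb
from . import diversity as dv
from . import simulate as sim
from . import stats as st

__all__ = [
    "bmntd_oracle_max_error",
    "neutral_null_calibration",
    "process_recovery",
    "signal_gate_experiment",
    "ra_recovery",
    "seep_active_experiment",
    "anosim_type1_error",
    "mantel_type1_error",
]

#: survey design used by the assembly experiments: three seep habitats, two
#: smaller non-seep reference habitats (33 samples)
ASSEMBLY_DESIGN = {"ROV1": 7, "ROV2": 7, "ROV3": 6, "ROV4": 5, "ROV5": 5}

SEEP = ("ROV1", "ROV2", "ROV3")
NONSEEP = ("ROV4", "ROV5")


def _brute_force_bmntd(comm_k: dict, comm_m: dict, dist) -> float:
    def side(a, b):
        total = sum(a.values())
        acc = 0.0
        for i, ni in a.items():
            if ni > 0:
                acc += (ni / total) * min(
                    dist[i, j] for j, nj in b.items() if nj > 0
                )
        return acc

    return 0.5 * (side(comm_k, comm_m) + side(comm_m, comm_k))


def bmntd_oracle_max_error(n_instances: int = 50, seed: int = 0) -> float:
    """Largest |bmntd - exhaustive double-loop| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 13))
        tree = sim.simulate_tree(n, seed=int(rng.integers(2**31 - 1)))
        dm = tree.patristic_matrix()
        tips = tree.tip_names
        k = {t: int(rng.integers(0, 5)) for t in tips}
        m = {t: int(rng.integers(0, 5)) for t in tips}
        if sum(k.values()) == 0:
            k[tips[0]] = 1
        if sum(m.values()) == 0:
            m[tips[-1]] = 1
        worst = max(worst, abs(asb.bmntd(k, m, dm) - _brute_force_bmntd(k, m, dm)))
    return worst


def neutral_null_calibration(
    n_seeds: int = 20,
    seed: int = 0,
    n_tips: int = 100,
    n_samples: int = 20,
    read_depth: int = 10_000,
    n_randomizations: int = 199,
) -> dict:
    """betaNTI calibration under pure neutral assembly.

    All samples draw multinomially from one lognormal pool; betaNTI is
    computed for every sample pair.  A calibrated null gives betaNTI
    centred near zero with almost all pairs classified stochastic.
    """
    rng = np.random.default_rng(seed)
    all_bnti: list[float] = []
    stochastic = 0
    total = 0
    for _ in range(n_seeds):
        tree = sim.simulate_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
        niche = sim.evolve_optima(tree, 1.0, seed=int(rng.integers(2**31 - 1)))
        sc = sim.AssemblyScenario(
            "neutral", env_values=[0.0] * n_samples, read_depth=read_depth
        )
        tbl, _ = sim.simulate_metacommunity(
            tree, niche, sc, seed=int(rng.integers(2**31 - 1))
        )
        res = asb.bnti_for_table(
            tbl, tree, n_randomizations=n_randomizations,
            seed=int(rng.integers(2**31 - 1)),
        )
        all_bnti.extend(res["bnti"].dropna())
        stochastic += int((res["process"] == "stochastic").sum())
        total += len(res)
    return {
        "mean_bnti": float(np.mean(all_bnti)),
        "pct_stochastic": 100.0 * stochastic / total,
        "n_pairs": total,
    }


def _assembly_survey(seed: int, seep_process: str = "selection") -> dict:
    """Survey at the frozen assembly-contrast conditions: a 600-tip pool,
    sparse communities (depth 400), sharp conserved niches and seep
    environments in the tails of the optima distribution."""
    return sim.simulate_survey(
        n_tips=600,
        seed=seed,
        design=ASSEMBLY_DESIGN,
        read_depth=400,
        sigma_niche=0.25,
        env_jitter=0.1,
        drift_sigma=2.5,
        seep_env_quantiles=(0.005, 0.02, 0.98),
        seep_process=seep_process,
        inactive_fraction=0.0,
        phantom_fraction=0.0,
    )


def process_recovery(
    n_seeds: int = 20, seed: int = 0, n_randomizations: int = 199
) -> dict:
    """Selection vs neutral assembly-process recovery.

    Within-habitat betaNTI in seep habitats (Gaussian filtering at
    environmental extremes) is contrasted with non-seep habitats (neutral).
    Reports per-seed fractions of pairs below -2 and the pooled selection
    betaNTI distribution.
    """
    rng = np.random.default_rng(seed)
    sel_frac, neu_frac = [], []
    sel_bnti: list[float] = []
    for _ in range(n_seeds):
        sv = _assembly_survey(int(rng.integers(2**31 - 1)))
        res = asb.bnti_for_table(
            sv["dna"], sv["tree"], n_randomizations=n_randomizations,
            seed=int(rng.integers(2**31 - 1)), metadata=sv["metadata"],
            within_habitat_only=True,
        )
        sel = res[res["habitat"].isin(SEEP)]
        neu = res[res["habitat"].isin(NONSEEP)]
        sel_frac.append(float((sel["bnti"] < -2).mean()))
        neu_frac.append(float((neu["bnti"] < -2).mean()))
        sel_bnti.extend(sel["bnti"].dropna())
    sel_frac_arr, neu_frac_arr = np.array(sel_frac), np.array(neu_frac)
    return {
        "seeds_selection_gt_neutral": int((sel_frac_arr > neu_frac_arr).sum()),
        "n_seeds": n_seeds,
        "selection_median_bnti": float(np.median(sel_bnti)),
        "selection_frac_lt_m2": float(sel_frac_arr.mean()),
        "neutral_frac_lt_m2": float(neu_frac_arr.mean()),
    }


def signal_gate_experiment(
    n_seeds: int = 20, seed: int = 0, n_tips: int = 200,
    n_permutations: int = 199,
) -> dict:
    """Phylogenetic-signal detection and type-I control.

    Brownian optima must light up the shortest distance class; optima
    randomly permuted across tips must not.
    """
    rng = np.random.default_rng(seed)
    detected = 0
    false_pos = 0
    for _ in range(n_seeds):
        tree = sim.simulate_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
        niche = sim.evolve_optima(tree, 1.0, seed=int(rng.integers(2**31 - 1)))
        dm = tree.patristic_matrix()
        corr = asb.phylo_signal(
            niche.optima, dm, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        detected += int(corr.signal_present)
        shuffled = pd.Series(
            np.random.default_rng(int(rng.integers(2**31 - 1)))
            .permutation(niche.optima.to_numpy()),
            index=niche.optima.index,
        )
        corr0 = asb.phylo_signal(
            shuffled, dm, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        false_pos += int(corr0.signal_present)
    return {"detected": detected, "false_positives": false_pos, "n_seeds": n_seeds}


def ra_recovery(
    seed: int = 0,
    n_tips: int = 300,
    n_samples: int = 10,
    read_depth: int = 100_000,
    inactive_fraction: float = 0.5,
    phantom_fraction: float = 0.1,
) -> dict:
    """Recovery of planted RNA activity structure at high depth.

    Checks that planted inactive ASVs (with enough DNA signal) are called
    RA = 0, phantoms never reach RA summaries, and active-ASV RA tracks the
    planted multipliers.
    """
    rng = np.random.default_rng(seed)
    tree = sim.simulate_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
    niche = sim.evolve_optima(tree, 1.0, seed=int(rng.integers(2**31 - 1)))
    sc = sim.AssemblyScenario(
        "neutral", env_values=[0.0] * n_samples, read_depth=read_depth
    )
    dna, _ = sim.simulate_metacommunity(
        tree, niche, sc, seed=int(rng.integers(2**31 - 1))
    )
    am = sim.ActivityModel(
        inactive_fraction=inactive_fraction, phantom_fraction=phantom_fraction
    )
    paired, truth = sim.simulate_paired_rna(
        dna, am, seed=int(rng.integers(2**31 - 1)), read_depth=read_depth
    )
    ra = act.relative_activity(paired, seed=int(rng.integers(2**31 - 1)))
    obs = ra[ra["status"] != "phantom"]
    per_asv = obs.groupby("asv_id")["ra"].mean()

    inactive = [
        a
        for a in truth.index[truth["status"] == "inactive"]
        if (dna.counts.loc[a] >= 10).any()
    ]
    called_zero = [a for a in inactive if per_asv.get(a, np.nan) == 0.0]
    phantoms = set(truth.index[truth["status"] == "phantom"])
    leaked = phantoms & set(obs["asv_id"])

    active = [
        a
        for a in truth.index[truth["status"] == "active"]
        if a in per_asv.index and dna.counts.loc[a].sum() >= 100
    ]
    rho = st.spearman(
        truth.loc[active, "multiplier"], per_asv.loc[active]
    ).statistic
    return {
        "pct_inactive_recovered": 100.0 * len(called_zero) / len(inactive),
        "n_inactive_eligible": len(inactive),
        "pct_phantoms_excluded": 100.0 * (1 - len(leaked) / max(len(phantoms), 1)),
        "active_multiplier_spearman": float(rho),
    }


def seep_active_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    n_tips: int = 200,
    read_depth: int = 10_000,
    boost_factor: float = 10.0,
    drift_sigma: float = 1.5,
) -> dict:
    """Seep-active group recovery and null false-flag rate.

    Both regions assemble neutrally so the planted x``boost_factor``
    activity multiplier in seep samples is the only region difference;
    the paired null surveys plant nothing.  Compositional drift is nuisance
    variance for this question and is held at a moderate level.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    null_flags = 0
    for _ in range(n_seeds):
        sv = sim.simulate_survey(
            n_tips=n_tips, seed=int(rng.integers(2**31 - 1)),
            design=ASSEMBLY_DESIGN, read_depth=read_depth,
            seep_process="neutral", drift_sigma=drift_sigma,
            seep_boost_group="Group03", seep_boost_factor=boost_factor,
        )
        ra = act.relative_activity(sv["paired"], seed=int(rng.integers(2**31 - 1)))
        ab = act.abundant_groups(sv["dna"], sv["taxonomy"])
        sa = act.seep_active_groups(ra, sv["taxonomy"], sv["metadata"], ab)
        hits += int(
            "Group03" in sa.index and bool(sa.loc["Group03", "seep_active"])
        )
        sv0 = sim.simulate_survey(
            n_tips=n_tips, seed=int(rng.integers(2**31 - 1)),
            design=ASSEMBLY_DESIGN, read_depth=read_depth,
            seep_process="neutral", drift_sigma=drift_sigma,
        )
        ra0 = act.relative_activity(sv0["paired"], seed=int(rng.integers(2**31 - 1)))
        ab0 = act.abundant_groups(sv0["dna"], sv0["taxonomy"])
        sa0 = act.seep_active_groups(ra0, sv0["taxonomy"], sv0["metadata"], ab0)
        null_flags += int(bool(sa0["seep_active"].any()))
    return {"detected": hits, "null_false_flags": null_flags, "n_seeds": n_seeds}


def anosim_type1_error(
    n_reps: int = 200, seed: int = 0, n_samples: int = 12,
    n_permutations: int = 99,
) -> float:
    """Empirical ANOSIM rejection rate at alpha=0.05 under shuffled labels."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        pts = rng.normal(size=(n_samples, 3))
        dm = DistanceMatrix(
            squareform(pdist(pts)), [f"s{i}" for i in range(n_samples)]
        )
        labels = ["g1"] * (n_samples // 2) + ["g2"] * (n_samples - n_samples // 2)
        labels = list(rng.permutation(labels))
        _, p = dv.anosim(dm, labels, n_permutations=n_permutations,
                         seed=int(rng.integers(2**31 - 1)))
        rejections += int(p <= 0.05)
    return rejections / n_reps


def mantel_type1_error(
    n_reps: int = 200, seed: int = 0, n_samples: int = 10,
    n_permutations: int = 99,
) -> float:
    """Empirical Mantel rejection rate at alpha=0.05 for independent
    random Euclidean distance matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    ids = [f"s{i}" for i in range(n_samples)]
    for _ in range(n_reps):
        d1 = DistanceMatrix(squareform(pdist(rng.normal(size=(n_samples, 3)))), ids)
        d2 = DistanceMatrix(squareform(pdist(rng.normal(size=(n_samples, 3)))), ids)
        res = st.mantel(d1, d2, n_permutations=n_permutations,
                        seed=int(rng.integers(2**31 - 1)))
        rejections += int(res.p <= 0.05)
    return rejections / n_reps
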