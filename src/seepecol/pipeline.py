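"""End-to-end orchestration of the inference chain.

``run_pipeline`` executes, in order: load → DNA/RNA pairing → rarefaction →
alpha/beta/gamma diversity → ANOSIM (region, habitat, depth-bin factors) →
phylogenetic-signal check → betaNTI within habitats → Levins' niche breadth
per habitat → relative activity → abundant groups → seep-active groups →
seep/non-seep contrasts.  Every stage writes one TSV into the output
directory, and a JSON manifest records the seed, package version and a hash
of the configuration, so identical config + seed reproduce byte-identical
outputs.

The phylogenetic-signal gate is advisory by default: when the check fails,
the betaNTI stage still runs but is marked in the manifest; under
``strict_signal_gate`` it is skipped with a logged notice (the same
conditional-inference rule that excludes community types without signal).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import abundant_groups, levins_breadth, relative_activity, seep_active_groups
from .assembly import bnti_for_table, niche_values_from_env, phylo_signal
from .diversity import (
    accumulation_curve,
    alpha_diversity,
    anosim,
    bray_curtis,
    default_rarefaction_depth,
    gamma_diversity,
    rarefy,
)
from .io import (
    CommunityTable,
    pair_samples,
    read_community_table,
    read_metadata,
    read_newick,
    read_taxonomy,
    write_result_table,
)
from .stats import wilcoxon_rank_sum

__all__ = ["PipelineConfig", "run_pipeline", "PipelineStageError"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage.  Outputs of
    earlier stages remain on disk."""


@dataclass
class PipelineConfig:
    """All inputs and tunables of a pipeline run.  ``seed`` is mandatory."""

    dna_path: str
    rna_path: str
    tree_path: str
    taxonomy_path: str
    metadata_path: str
    out_dir: str
    seed: int
    rarefaction_depth: int | None = None  # None: 90% of smallest sample
    n_randomizations: int = 199
    n_permutations: int = 499
    n_accum_permutations: int = 200
    alpha: float = 0.05
    abundance_threshold: float = 0.001
    group_rank: str = "class"
    max_depth_cmbs: float = 10.0
    depth_bin_cmbs: float = 5.0
    signal_env_var: str = "env"
    strict_signal_gate: bool = False
    ra_aggregate: str = "pair_median"
    manual_include: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_randomizations", "n_permutations", "n_accum_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "manual_include" in data:
            data["manual_include"] = tuple(data["manual_include"])
        return cls(**data)

    #: fields that identify file locations, not the analysis itself; kept out
    #: of the config hash so identical analyses hash identically wherever the
    #: inputs and outputs live
    _PATH_FIELDS = ("dna_path", "rna_path", "tree_path", "taxonomy_path",
                    "metadata_path", "out_dir")

    def config_hash(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _params(cfg: PipelineConfig, **extra) -> dict:
    base = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    base.update(extra)
    return base


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the result bundle (dict of DataFrames).

    Raises :class:`PipelineStageError` naming the failing stage; outputs of
    completed stages are preserved in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in (
            "rarefy_dna", "rarefy_rna", "accumulation", "anosim", "signal",
            "bnti", "activity",
        )
    }
    bundle: dict = {}
    manifest = {
        "seepecol_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": [],
        "notes": [],
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
        return deco

    @stage("load")
    def _load():
        bundle["dna_raw"] = read_community_table(cfg.dna_path)
        bundle["rna_raw"] = read_community_table(cfg.rna_path)
        bundle["tree"] = read_newick(cfg.tree_path)
        bundle["taxonomy"] = read_taxonomy(cfg.taxonomy_path, group_rank=cfg.group_rank)
        bundle["metadata"] = read_metadata(cfg.metadata_path)

    @stage("pair")
    def _pair():
        bundle["paired"] = pair_samples(
            bundle["dna_raw"], bundle["rna_raw"], bundle["metadata"],
            max_depth_cmbs=cfg.max_depth_cmbs,
        )

    @stage("rarefy")
    def _rarefy():
        paired = bundle["paired"]
        depth = cfg.rarefaction_depth or min(
            default_rarefaction_depth(paired.dna),
            default_rarefaction_depth(paired.rna),
        )
        bundle["rarefaction_depth"] = depth
        bundle["dna"] = rarefy(paired.dna, depth, stage_seeds["rarefy_dna"]).drop_empty_asvs()

    @stage("alpha")
    def _alpha():
        alpha = alpha_diversity(bundle["dna"], bundle["tree"])
        meta = bundle["metadata"]
        alpha["habitat"] = meta.loc[alpha.index, "habitat"]
        alpha["region"] = meta.loc[alpha.index, "region"]
        bundle["alpha"] = alpha
        write_result_table(alpha, out / "alpha.tsv",
                           _params(cfg, depth=bundle["rarefaction_depth"]), index=False)

    @stage("beta")
    def _beta():
        dm = bray_curtis(bundle["dna"])
        bundle["beta"] = dm
        write_result_table(dm.to_data_frame(), out / "beta_braycurtis.tsv", _params(cfg))

    @stage("gamma")
    def _gamma():
        grouping = bundle["metadata"].loc[bundle["dna"].sample_ids, "habitat"]
        gamma = gamma_diversity(bundle["dna"], grouping)
        bundle["gamma"] = gamma
        curves = accumulation_curve(
            bundle["dna"], grouping,
            n_permutations=cfg.n_accum_permutations,
            seed=stage_seeds["accumulation"],
        )
        bundle["accumulation"] = curves
        frames = pd.concat([c.as_frame() for c in curves.values()], ignore_index=True)
        write_result_table(gamma.to_frame(), out / "gamma.tsv", _params(cfg),
                           index_label="habitat")
        write_result_table(frames, out / "accumulation.tsv",
                           _params(cfg, n_permutations=cfg.n_accum_permutations),
                           index=False)

    @stage("anosim")
    def _anosim():
        meta = bundle["metadata"].loc[bundle["dna"].sample_ids]
        dm = bundle["beta"]
        factors = {
            "region": meta["region"],
            "habitat": meta["habitat"],
            "depth_bin": (meta["depth_cmbs"] // cfg.depth_bin_cmbs).astype(int).astype(str),
        }
        rows = []
        for name, labels in factors.items():
            try:
                r, p = anosim(dm, labels.tolist(),
                              n_permutations=cfg.n_permutations,
                              seed=stage_seeds["anosim"])
                rows.append({"factor": name, "anosim_r": r, "p": p, "note": ""})
            except ValueError as exc:
                rows.append({"factor": name, "anosim_r": np.nan, "p": np.nan,
                             "note": str(exc)})
        bundle["anosim"] = pd.DataFrame(rows)
        write_result_table(bundle["anosim"], out / "anosim.tsv",
                           _params(cfg, n_permutations=cfg.n_permutations), index=False)

    @stage("signal")
    def _signal():
        meta = bundle["metadata"]
        env = meta.loc[bundle["dna"].sample_ids, cfg.signal_env_var].astype(float)
        niche_vals = niche_values_from_env(bundle["dna"], env)
        corr = phylo_signal(
            niche_vals, bundle["tree"].patristic_matrix(),
            n_permutations=cfg.n_permutations, seed=stage_seeds["signal"],
        )
        bundle["signal"] = corr
        write_result_table(corr.as_frame(), out / "signal.tsv",
                           _params(cfg, signal_present=corr.signal_present),
                           index=False)
        if not corr.signal_present:
            manifest["notes"].append("phylogenetic signal absent in shortest class")

    @stage("bnti")
    def _bnti():
        corr = bundle["signal"]
        if not corr.signal_present and cfg.strict_signal_gate:
            logger.warning("bnti: skipped — phylogenetic-signal gate failed (strict)")
            manifest["notes"].append("bnti skipped: signal gate (strict)")
            bundle["bnti"] = pd.DataFrame()
            return
        if not corr.signal_present:
            logger.warning("bnti: phylogenetic-signal check failed; "
                           "interpret betaNTI with caution")
        res = bnti_for_table(
            bundle["dna"], bundle["tree"],
            n_randomizations=cfg.n_randomizations,
            seed=stage_seeds["bnti"],
            metadata=bundle["metadata"],
            within_habitat_only=True,
        )
        bundle["bnti"] = res
        write_result_table(res, out / "bnti.tsv",
                           _params(cfg, n_randomizations=cfg.n_randomizations,
                                   null_model="tip-shuffle over metacommunity pool",
                                   pairs="within-habitat"),
                           index=False)
        frac = (
            res.groupby("habitat")["process"]
            .value_counts(normalize=True)
            .rename("fraction")
            .reset_index()
        )
        bundle["process_fractions"] = frac
        write_result_table(frac, out / "process_fractions.tsv", _params(cfg), index=False)

    @stage("niche_breadth")
    def _niche():
        meta = bundle["metadata"].loc[bundle["dna"].sample_ids]
        rows = []
        comm_rows = []
        for hab, members in meta.groupby("habitat")["sample_id"]:
            ms = list(members)
            if len(ms) < 2:
                logger.info("niche_breadth: habitat %s has <2 samples; skipped", hab)
                continue
            res = levins_breadth(bundle["dna"], scope=ms)
            df = res.as_frame()
            df["habitat"] = hab
            df["n_communities"] = res.n_communities
            rows.append(df.reset_index(names="asv_id"))
            cl = res.community_level.rename("community_levins_b").to_frame()
            cl["habitat"] = hab
            comm_rows.append(cl.reset_index(names="sample_id"))
        bundle["niche_breadth"] = pd.concat(rows, ignore_index=True)
        bundle["niche_breadth_community"] = pd.concat(comm_rows, ignore_index=True)
        write_result_table(bundle["niche_breadth"], out / "niche_breadth.tsv",
                           _params(cfg), index=False)
        write_result_table(bundle["niche_breadth_community"],
                           out / "niche_breadth_community.tsv", _params(cfg),
                           index=False)

    @stage("activity")
    def _activity():
        act = relative_activity(
            bundle["paired"], rarefaction_depth=bundle["rarefaction_depth"],
            seed=stage_seeds["activity"],
        )
        bundle["activity"] = act
        write_result_table(act, out / "activity.tsv",
                           _params(cfg, depth=bundle["rarefaction_depth"]), index=False)

    @stage("groups")
    def _groups():
        ab = abundant_groups(bundle["dna"], bundle["taxonomy"],
                             threshold=cfg.abundance_threshold)
        bundle["abundant_groups"] = ab
        write_result_table(ab, out / "abundant_groups.tsv",
                           _params(cfg, threshold=cfg.abundance_threshold),
                           index_label="group")
        summary = seep_active_groups(
            bundle["activity"], bundle["taxonomy"], bundle["metadata"], ab,
            alpha=cfg.alpha, manual_include=cfg.manual_include,
            aggregate=cfg.ra_aggregate,
        )
        bundle["seep_active"] = summary
        write_result_table(summary, out / "seep_active.tsv",
                           _params(cfg, alpha=cfg.alpha), index=False)

    @stage("region_contrasts")
    def _contrasts():
        alpha = bundle["alpha"]
        rows = []
        for index_name in ("richness", "chao1", "faith_pd", "pielou"):
            if index_name not in alpha.columns:
                continue
            seep = alpha.loc[alpha["region"] == "seep", index_name].dropna()
            non = alpha.loc[alpha["region"] == "non-seep", index_name].dropna()
            if seep.empty or non.empty:
                continue
            res = wilcoxon_rank_sum(seep, non)
            rows.append({
                "quantity": index_name,
                "seep_median": float(seep.median()),
                "nonseep_median": float(non.median()),
                "statistic": res.statistic,
                "p": res.p,
            })
        # beta diversity: within-region Bray-Curtis values
        meta = bundle["metadata"].loc[bundle["dna"].sample_ids]
        dm = bundle["beta"]
        vals = {"seep": [], "non-seep": []}
        ids = list(dm.ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ri, rj = meta.loc[ids[i], "region"], meta.loc[ids[j], "region"]
                if ri == rj:
                    vals[ri].append(dm[ids[i], ids[j]])
        if vals["seep"] and vals["non-seep"]:
            res = wilcoxon_rank_sum(vals["seep"], vals["non-seep"])
            rows.append({
                "quantity": "braycurtis_within_region",
                "seep_median": float(np.median(vals["seep"])),
                "nonseep_median": float(np.median(vals["non-seep"])),
                "statistic": res.statistic,
                "p": res.p,
            })
        bundle["region_contrasts"] = pd.DataFrame(rows)
        write_result_table(bundle["region_contrasts"], out / "region_contrasts.tsv",
                           _params(cfg), index=False)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle
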