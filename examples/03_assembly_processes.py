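"""Infer community-assembly processes from phylogenetic turnover.

Checks the phylogenetic-signal prerequisite, then computes betaMNTD and its
tip-shuffle null for every within-habitat sample pair and classifies each
pair: betaNTI < -2 homogeneous selection, > +2 heterogeneous selection,
in between stochastic (dispersal/drift).
"""

from seepecol.assembly import bnti_for_table, niche_values_from_env, phylo_signal
from seepecol.simulate import simulate_survey

survey = simulate_survey(
    n_tips=600, seed=7, read_depth=400, sigma_niche=0.25,
    drift_sigma=2.5, seep_env_quantiles=(0.005, 0.02, 0.98),
    design={"ROV1": 7, "ROV2": 7, "ROV3": 6, "ROV4": 5, "ROV5": 5},
)
table, tree, meta = survey["dna"], survey["tree"], survey["metadata"]

# prerequisite: niche values must carry signal at short phylogenetic distance
niche_vals = niche_values_from_env(table, meta.loc[table.sample_ids, "env"])
corr = phylo_signal(niche_vals, tree.patristic_matrix(),
                    n_permutations=199, seed=8)
print(f"phylogenetic signal, shortest distance class: "
      f"r = {corr.r[0]:.3f}, p = {corr.p[0]:.3f} "
      f"({'present' if corr.signal_present else 'ABSENT - do not infer'})")

res = bnti_for_table(table, tree, n_randomizations=199, seed=9,
                     metadata=meta, within_habitat_only=True)
res["region"] = [
    "seep" if h in ("ROV1", "ROV2", "ROV3") else "non-seep"
    for h in res["habitat"]
]
print("\nbetaNTI by region (within-habitat pairs):")
print(res.groupby("region")["bnti"].median().round(2).to_string())
print("\nprocess fractions:")
print(res.groupby("region")["process"].value_counts(normalize=True)
      .round(2).to_string())
print("\nSeep habitats filter for the few lineages adapted to extreme "
      "conditions, so their\npairs show less phylogenetic turnover than the "
      "null (betaNTI < -2 = homogeneous\nselection); neutral non-seep pairs "
      "sit inside the +/-2 stochastic band.")
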