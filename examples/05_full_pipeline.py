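"""Run the complete inference chain on generated input files.

Generates a survey, writes its six input files, then executes every stage —
load, DNA/RNA pairing, rarefaction, alpha/beta/gamma diversity, ANOSIM,
phylogenetic-signal check, betaNTI, niche breadth, relative activity,
abundant and seep-active groups, region contrasts — writing one TSV per
stage plus a JSON manifest. Re-running with the same seed reproduces every
TSV byte for byte.
"""

from seepecol.pipeline import PipelineConfig, run_pipeline
from seepecol.simulate import simulate_survey, write_survey

survey = simulate_survey(n_tips=150, seed=42, read_depth=4000, n_groups=6)
paths = write_survey(survey, "example_survey", seed=42)

cfg = PipelineConfig(
    dna_path=paths["dna"], rna_path=paths["rna"], tree_path=paths["tree"],
    taxonomy_path=paths["taxonomy"], metadata_path=paths["metadata"],
    out_dir="example_results", seed=7,
    n_randomizations=199, n_permutations=499, n_accum_permutations=200,
)
bundle = run_pipeline(cfg)

print("stages completed:", ", ".join(bundle["manifest"]["stages"]))
print(f"rarefaction depth: {bundle['rarefaction_depth']} reads/sample")
print("\nANOSIM effects on composition (R near 1 = strong separation):")
print(bundle["anosim"][["factor", "anosim_r", "p"]].round(3).to_string(index=False))
print("\nassembly-process fractions per habitat:")
print(bundle["process_fractions"].round(2).to_string(index=False))
print("\nseep/non-seep diversity contrasts (Wilcoxon):")
print(bundle["region_contrasts"].round(4).to_string(index=False))
print("\nall stage tables + manifest written to example_results/")
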