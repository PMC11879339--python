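# Methods

This note records the models the package implements, the conventions and
defaults it chooses where several are defensible, what the synthetic-data
generator does and does not emulate, and the known limitations. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

All analyses run on an integer ASV × sample count matrix with per-sample
metadata (habitat ROV1–ROV5, region derived as ROV1–3 = seep, ROV4–5 =
non-seep, sediment depth in cm below surface, environmental variables), a
rooted phylogeny whose tips are the ASVs, a taxonomy map with a designated
group rank (class, or phylum for microeukaryotes), and — for activity
analyses — a second count matrix from RNA (cDNA) libraries paired sample
by sample with the DNA matrix. Pairing strips a library suffix
(`_DNA`/`_RNA`/`_cDNA`, configurable) and keeps pairs at most 10 cmbs deep
by default, since RNA libraries are only informative in the surface layers
where both libraries exist. Tables are validated on construction:
non-negative integer counts, unique identifiers, no all-zero samples.

## Diversity layer

* **Rarefaction** draws without replacement (multivariate hypergeometric)
  to an exact common depth; samples below depth are dropped and logged.
  The default depth is 90% of the smallest retained sample total — high
  enough to keep most reads, low enough to retain most samples. DNA and
  RNA tables are rarefied to one common depth before RA so the ratio's
  numerator and denominator have equal sampling variance.
* **Chao1** uses S + F₁²/(2F₂), switching to the bias-corrected
  denominator S + F₁(F₁−1)/(2(F₂+1)) only when no doubletons exist, which
  avoids division by zero while reproducing the classical value elsewhere.
* **Faith's PD** follows the rooted convention (path to the root included),
  so PD is monotone under ASV addition and a single-ASV sample receives its
  root-to-tip distance rather than zero.
* **Pielou's evenness** is reported as missing for single-taxon samples
  (0/0, not 0).
* **Accumulation curves** permute site order uniformly; habitats are
  compared at the smallest habitat's sample count. The permutation mean is
  validated against the closed-form hypergeometric expectation
  S(n) = Σⱼ [1 − C(N−mⱼ, n)/C(N, n)].
* **ANOSIM and Mantel** are delegated to scikit-bio behind seeded wrappers
  (the library uses the global numpy RNG; the wrappers scope it so that the
  package-wide explicit-seed contract holds). Permutation p-values include
  the observed labelling, so p ≥ 1/(n_perm + 1) and p = 0 cannot occur —
  the same convention applies to every permutation test in the package.

## Assembly inference

βMNTD is computed exactly as defined, with minima over taxa *present*
(count > 0) in the other community and relative abundances renormalised
within each community. A taxon present in both communities matches itself
at distance zero, so identical communities have βMNTD = 0; the statistic is
symmetric and invariant to rescaling either community's counts.

The null model shuffles tip labels jointly across the metacommunity taxon
pool (every taxon with a read anywhere in the table), holding abundances
and occupancy fixed, and recomputes βMNTD — the standard "taxa labels"
scheme. All sample pairs share the same shuffle sequence, which is both the
conventional choice and what makes the computation fast: for each shuffle,
a per-sample profile of minimum distances is computed once
(O(samples × taxa × occupancy)) and every pair's βMNTD follows by dot
products. 999 randomizations is the analysis default; experiments use 199.

**Point-mass nulls.** When two communities share their entire membership,
every shared taxon self-matches under any shuffle and the null distribution
collapses onto the observation (sd = 0, obs = mean). The standardised
deviation is then zero by the centering rule, so such pairs are classified
stochastic and flagged `degenerate`. A point-mass null that does *not*
contain the observation (possible only on degenerate trees, e.g. an
equidistant star) leaves βNTI undefined: the pair is flagged and labelled
`undetermined`.

**Phylogenetic-signal gate.** βNTI inference presupposes that niche values
are conserved at short phylogenetic distances. The check is a Mantel
correlogram: the phylogenetic-distance range is cut into equal-width
classes (8 by default) and, per class, the (sign-flipped) Pearson
correlation between |niche_i − niche_j| and the in-class indicator is
tested by permuting niche values across taxa (one-tailed, positive). The
sign convention makes "close relatives have similar niches" positive.
Signal is declared present when the shortest class is significantly
positive. Per-ASV niche values are abundance-weighted means of an
environmental variable; synthetic experiments may use the generating optima
directly. In the pipeline the gate is advisory by default (βNTI still runs,
with a warning and a manifest note) and blocking under
`strict_signal_gate` — community types without signal should not be
interpreted through phylogenetic turnover.

## Activity layer

RA is computed per (ASV, sample pair) on the rarefied tables. Phantom
detections (RNA > 0, DNA = 0) are recorded but excluded from every
summary; DNA-only ASVs are retained with RA = 0, because dead or dormant
organisms are part of the community's story. Abundant groups are those
with mean summed relative abundance strictly above 0.1% across samples.

**Seep-active testing.** The default observational unit is the sample
pair: per group and pair, the median RA over the group's ASVs, compared
between regions by two-sided Wilcoxon rank-sum with Bonferroni correction
across groups and a direction check (seep median > non-seep median).
Sample pairs are the exchangeable units — RA values of different ASVs
within one pair share the library-level renormalisation denominator, so
pooling them as independent observations (available as `aggregate="pool"`)
inflates the false-positive rate several-fold in planted-null experiments
while pair-level aggregation holds the nominal test size. A manual
inclusion override exists for a priori groups but always sets an explicit
`manually_included` flag.

**Levins' niche breadth** uses per-taxon occupancy profiles computed from
counts (P_ij = c_ij/Σᵢc_ij), which bounds B in [1, N] and makes it
invariant to rescaling a taxon's counts. The community-level value is the
abundance-weighted mean of B over the taxa present in a sample.

## Synthetic metacommunity generator

The generator is a pure function of its parameters and an integer seed.

* **Trees** are pure-birth (Yule): exponential waits at rate k·λ with a
  final waiting interval so terminal branches are positive.
* **Optima** evolve by Brownian motion root-to-tip; the variance of the
  difference between two tips equals rate × patristic distance (verified
  by Monte Carlo in the suite).
* **Assembly.** Expected relative abundance under selection is
  pool_j · exp(−(env_i − opt_j)²/(2σ²)); neutral is pool_j alone; `mixed`
  blends the normalised expectations. Reads are multinomial at exact depth.
  The regional pool is lognormal(0, 1.5) — a realistic abundant/rare split.
  An optional lognormal per-sample **drift** multiplier (σ_d, default 0 in
  `AssemblyScenario`, 2.0 in `simulate_survey`) emulates the strong
  replicate-to-replicate compositional turnover of real sediment
  communities. Without it, samples whose depth far exceeds the pool size
  share nearly their full membership, every taxon self-matches in the
  βMNTD null, and no assembly signal of any kind is detectable — pure
  multinomial resampling of one expectation is re-sequencing, not ecology.
* **Survey design.** `simulate_survey` emulates the seep/non-seep contrast:
  ROV1–3 assemble under selection at habitat-specific environments placed
  in the *tails* of the optima distribution (quantiles (0.02, 0.05, 0.98)
  by default), ROV4–5 neutrally at the median. Tail placement is a
  deliberate design choice: a Brownian trait field is self-similar, so a
  *central* trait slice is scattered over many clades and filtering for it
  barely depresses nearest-taxon distances; trait extremes are reached by
  few conserved lineages, so filtering for them selects coherent clades —
  which is also the ecologically faithful picture of seep chemistry as an
  environmental extreme selecting specialist lineages.
* **RNA libraries.** Each DNA ASV is planted inactive (RNA expectation 0)
  with the configured probability, otherwise active with a lognormal
  multiplier; a configurable group of ASVs can be boosted by a factor in
  chosen samples to plant a region-specific activity contrast. Phantom
  ASVs are drawn from reserved tree tips (zero pool abundance) so RNA
  tables stay tree-compatible, and receive Poisson(5) reads carved out of
  the fixed RNA depth before the active ASVs are sampled multinomially —
  column sums stay exact. The planted per-ASV status is returned as ground
  truth.
* **Taxonomy.** Synthetic groups are clades (the root is split, largest
  clade first, until k groups exist), so group labels are phylogenetically
  coherent as real class/phylum labels are.

### What the generator does not emulate

No mechanistic chemistry (methane/sulphide dynamics) — the environment is
one abstract axis. No sequencing error, chimeras or taxonomy
misassignment. No spatial structure within a habitat beyond exchangeable
drift; no dispersal limitation gradient, so the stochastic class is not
partitioned further. Passing tests therefore show that the inference chain
recovers planted structure of these kinds at these sizes — not that real
cold-seep data satisfy the generative assumptions.

## Validation experiment sizes

The planted-truth experiments (in `seepecol.experiments`, run by both the
test suite and `scripts/acceptance.py`) use problem sizes chosen to finish
in seconds to minutes on one CPU while leaving clear recovery margins:

* Null calibration: 20 neutral metacommunities, 100 tips, 20 samples,
  depth 10⁴, 199 randomizations.
* Selection recovery: 20 surveys, 600 tips, depth 400, σ_niche 0.25,
  drift 2.5, seep environments at quantiles (0.005, 0.02, 0.98) — sparse
  communities (richness ≪ pool), which is where nearest-taxon turnover is
  informative, mirroring real tables where per-sample richness is a small
  fraction of the regional ASV pool.
* Signal gate: 200-tip trees, 20 Brownian and 20 permuted trait sets.
* RA recovery: depth 10⁵, planted inactive fraction 0.5, phantom fraction
  0.1.
* Seep-active: 20 boosted and 20 null surveys, 200 tips, depth 10⁴,
  neutral assembly in both regions so the ×10 multiplier boost is the only
  planted region difference; moderate drift (1.5), since compositional
  drift is nuisance variance for the classifier under test.
* Test sizes: 200 replicates each for ANOSIM (shuffled labels) and Mantel
  (independent random point sets).

## Numerical conventions

Explicit integer seeds everywhere; child seeds are spawned from a single
`numpy` Generator so stages are independently reproducible. Wilcoxon uses
the exact distribution for tie-free groups of ≤ 25, otherwise the normal
approximation with continuity correction; Spearman offers a permutation p
for small n. Bonferroni is min(1, p·m). Ties are midranked throughout.
Missing newick branch lengths become 0 with a warning (a warning also
fires when > 1% of branches are zero-length, where nearest-taxon distances
degenerate). Result TSVs carry `#` headers recording the package version,
seed and parameters; the pipeline manifest stores a hash of the analysis
configuration (file paths excluded), and identical configuration + seed
reproduce byte-identical stage outputs.

## Limitations

βNTI's stochastic class is not partitioned into dispersal limitation vs
drift (no Raup–Crick complement). The seep-active test at the group level
can miss finer-grained activity structure, and RA is a proxy of relative
ribosomal activity, not growth rate. The Mantel correlogram uses
equal-width distance classes; very unbalanced class occupancies at extreme
tree shapes can leave short classes undersampled. Dense tables (depth ≫
pool) push many pairs into the flagged point-mass regime, where βNTI = 0
is reported by convention rather than measured — sparse, realistic tables
avoid this entirely.
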