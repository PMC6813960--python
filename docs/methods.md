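# Methods

This note documents the models and numerical choices behind each stage, what
the synthetic generators do and do not emulate, and the design decisions
taken where conventions genuinely diverge.

## Cycle reconstruction

A marker configuration maps each conversion step of the carbon, nitrogen and
sulfur cycles (and each stress-adaptation theme) to a KO combination. The
step's genetic potential is the sum of the abundances of all genes whose KO
belongs to the combination; its "potential flux" is the within-cycle percent
of that sum. No rate or thermodynamic model is implied — the quantity is
genetic potential only.

**Routing.** Some markers are catalytically bidirectional: the aprA/dsrA
family runs dissimilatory sulfate reduction in sulfate reducers and the
reverse (sulfide oxidation) in sulfur oxidizers, and amoA/pmoA is shared
between ammonia- and methane-oxidizers. Such KOs may appear in several
steps, each flagged `ambiguous` and carrying an ordered clade-pattern list.
A gene is assigned to the first step (configuration order) whose pattern
list matches any rank of its lineage, case-insensitively on the canonical
prefix-free six-rank form; genes matching no list are reported `unassigned`
and excluded everywhere. The ordered-first-match rule is deterministic and
documented; with it, a gene contributes to exactly one step, which makes the
conservation property exact: step sums plus unused-gene abundance equal the
total abundance of marker-matching genes.

**Validation rule.** A KO shared between steps *without* the ambiguous flag
is a configuration error, rejected at load time — silent double counting is
the failure mode this prevents.

**Heatmap.** Taxa contributing strictly more than 1% to at least one step
(per-step filter; a per-cycle variant is available via `per_cycle=True`,
since "the marker genes mixture" can be read either way) are retained and
each row is z-scored across steps with the population (ddof 0) standard
deviation; constant rows become zeros rather than NaN.

**Stress themes** are open gene inventories, not closed cycles, so their
percentages are relative to the total gene abundance of the input table and
do not sum to 100.

**Configuration is data.** The shipped `markers.yaml` (version 1) is a KO
curation from KEGG pathway/BRITE membership for the canonical steps —
RuBisCO/PRK for Calvin-cycle fixation, coxSML for CO oxidation, mcrABG for
methanogenesis, pmoABC/mmoX for methane oxidation, nifDHK, amo/hao/nxr,
nirK/nirS/norBC/nosZ, GS/GOGAT/GDH, urease, cysNDHJI, sat/aprAB/dsrAB, the
sox system, sqr/fcc, and the stress themes. Correctness claims attach to
the aggregation engine; the curation is versioned and overridable and small
inaccuracies in it do not affect the engine's guarantees.

## Diversity

- Chao1 uses the bias-corrected form `S + F₁(F₁−1)/(2(F₂+1))`, defined when
  doubletons are absent. Shannon uses the natural log by default
  (`log_base` exposed); Pielou at S = 1 is defined as 0 to avoid 0/0.
- No rarefaction is applied. Beta diversity defaults to relative abundances,
  which removes depth effects for Bray–Curtis; the normalisation is an
  explicit argument because it changes the indices.
- Bray–Curtis, UPGMA (scipy average linkage) and isotonic regression come
  from scipy/scikit-learn; the alpha-diversity closed forms are implemented
  directly and cross-checked against scikit-bio in the test suite, keeping
  implementation and oracle independent.
- UPGMA similarity cuts: the dendrogram on dissimilarities is cut at height
  `1 − cut/100`; `cut = 100` yields singletons, `cut → 0` one cluster.

## NMDS

Kruskal stress-1, `sqrt(Σ(d − d̂)² / Σ d²)` over configuration distances `d`
and disparities `d̂`, is minimised by alternating (i) pool-adjacent-violators
isotonic regression of `d` on the rank order of the input dissimilarities
(ties pooled — the "primary" tie treatment) and (ii) a Guttman-transform
configuration update. An update that would increase stress-1 terminates the
run — the monotone safeguard — so per-iteration stress is non-increasing by
construction. Defaults: 2 dimensions, 20 restarts (first from the classical
metric-MDS solution, the rest random from the seeded generator), tolerance
1e-6, 300 iterations. Stress depends on dissimilarity ranks only, giving
invariance under strictly increasing transforms; configurations are
reported centred, and stress is invariant to rotation/reflection. Because a
commercial implementation's exact options cannot be known, agreement with
published ordinations is claimed at the property level only.

## SparCC network

Log-ratio variances `t_ij = Var log(f_i/f_j)` are computed from fractions
estimated by averaging Dirichlet(counts + 1) draws (20 by default; 0 draws
selects the deterministic posterior mean). Under the basis decomposition
`t_ij = ω_i² + ω_j² − 2ρ_ij ω_i ω_j` and approximate sparsity, row sums of
`t` give the linear system `[(D−2)I + 𝟙]ω² = t·𝟙`; after solving, the
strongest |ρ| pair above 0.1 is excluded from the system and it is re-solved,
up to D−3 exclusions. ρ is clipped to [−1, 1]; non-positive solved variances
(possible with few samples) are replaced by half the smallest positive `t`
entry of that row, with a warning.

A caveat worth stating: at D = 3 the sparsity approximation provably
redistributes a single planted correlation to zero, so the exact
forward-then-invert oracle in the tests validates the algebraic inversion
`correlation_from_variances` (given true ω²), while the full estimator is
validated by null and planted-pair simulations at realistic D.

p-values are two-sided permutation pseudo-p's: each taxon's counts are
shuffled independently across samples, the full ρ matrix re-estimated, and
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm)`; ties count against
significance. p-values are **not** multiplicity-adjusted by default (the
emulated thresholding uses raw p < 0.01); a Benjamini–Hochberg flag exists.
Edges require |ρ| strictly above 0.65 and p strictly below 0.01 — note that
99 permutations floor p at exactly 0.01, so at least 199 are needed for any
edge to pass.

Genus aggregation precedes estimation; genera present in fewer than 3
samples (configurable) and unclassified genera are dropped, logged. With
fewer than 10 samples a fragility warning is emitted rather than an error,
because 6-sample designs must remain runnable.

## Synthetic generators

- **OTU tables**: per sample, latent log-abundances are multivariate normal
  with a chosen basis correlation (PSD-checked; eigendecomposition handles
  semidefinite cases) and group-specific means; absolute abundances are
  exponentials, multinomially subsampled to the sample's depth. This is the
  compositional model SparCC assumes, so network-stage recovery claims are
  tested *under the estimator's own model* — a green test does not establish
  robustness to other abundance distributions (e.g. zero inflation,
  Dirichlet-multinomial overdispersion), which real data exhibit.
- **Defaults as the stated world**: the bundle generator reproduces the
  emulated study's design — 6 samples in 4 site groups with the published
  sequencing depths (60,608–102,593 reads), 212 OTUs, archaeal qPCR share
  0.4–8.6% of bacterial copies, bacterial copies log-uniform over 1e5–1e8
  per gram (the cold-desert soil biomass span). Planted step weights use the
  published percentages where printed (CO oxidation 20%, denitrification
  9.4%, nitrogen fixation 0.4%, ammonia oxidation 0.9%, sulfur 67.4/32.5%,
  DNA repair 1.46% of total abundance) and fill the remainder with
  assimilation/respiration-dominated splits typical of oligotrophic soils;
  C/N/S markers take 12/10/8% of total gene mass (markers are a minority of
  any metagenome) and other stress themes sub-percent levels.
- **Gene tables**: per (step, taxon) pair, `n_genes` genes with abundance
  `cycle_mass · step_weight · taxon_weight · total_mass / n_genes ·
  exp(N(0, σ²))`. KO draws are restricted to those the routing rules will
  return to the emitting step, so the zero-noise round-trip is exactly the
  identity on step and taxon fractions. The generator does not emulate
  annotation error, chimeric lineages, or assembler coverage bias.
- Each generator owns a `numpy.random.default_rng(seed)`; nothing touches
  global state, and equal seeds give byte-identical outputs.

## Orchestration

`run_all` executes any subset of diversity/network/cycles from one config.
A single seed fans out to per-stage seeds by SHA-256 of `"{seed}:{stage}"`
(taken mod 2³¹), so stages are individually reproducible. The manifest
records tool version, input SHA-256 hashes, all parameters and derived
seeds — and deliberately no wall-clock timestamp, so identical configs give
identical manifests and byte-identical outputs. Stage failures raise
`StageError` naming the stage; input and schema problems raise
`ValidationError` naming the record.

## Known limitations

- SparCC with 6 samples is statistically fragile; the package warns and
  proceeds. Permutation p-values at 6 samples have a coarse support.
- The qPCR archaeal share is reported in both conventions (percent of
  bacterial copies and percent of total) because published spans are
  ambiguous between them.
- Potentials are genetic only; expression (metatranscriptome/metaproteome)
  support is out of scope.
- The heatmap's >1% filter defaults to per-step; per-cycle filtering is a
  flag, and the two can retain different taxon sets.
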