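# Methods

`raretide` analyses a monthly marine metagenomic time series through two
parallel gene pools: the *assembled* fraction (reads that map to contigs,
dominated by abundant community members) and the *unassembled* fraction
(reads left out of the assembly, treated as the rare biosphere's gene pool).
All statistics operate on derived feature-by-sample count tables — 16S OTUs
and protein/KO functional features — never on reads.

## Compositional preprocessing (`tables`)

Count tables are compositions: only within-sample ratios are meaningful.
The pipeline is

1. **Prevalence filter** — drop features whose total count over all samples
   is exactly 1 (sequencing-noise singletons) and features detected (count
   ≥ 1) in fewer than `min_samples` samples (default 20, half of a
   40-sample series). The filter is idempotent and is usually applied to
   the concatenated assembled+unassembled table so both fractions see the
   same feature universe.
2. **Zero replacement** — Bayesian-multiplicative count-zero ("czm")
   imputation: in a sample with total *n*, each zero becomes the proportion
   0.5/*n* and nonzero proportions are multiplicatively shrunk so the
   sample still sums to exactly 1. Imputed values never exceed observed
   proportions in realistic tables; the transform errors on samples so
   shallow that *z*·0.5/*n* ≥ 1 (more zeros than half the library size),
   which cannot occur at real sequencing depths.
3. **CLR** — centered log-ratio per sample, `ln x_i − mean_j ln x_j`;
   columns sum to 0 to < 1e−9.

Rare/abundant labels use the standard 0.01 % within-sample cutoff:
abundant strictly above, rare strictly below. A value exactly at the cutoff
is classed rare (the conservative side of an otherwise unassigned boundary)
and logged.

## Differential abundance between fractions (`fractiondiff`)

A Dirichlet–Monte-Carlo CLR test. For each sample, `n_mc` (default 128)
posterior probability vectors are drawn from Dirichlet(counts + 0.5) and
CLR-transformed; within every instance each feature is compared between the
two fractions with a Welch t-test and a Wilcoxon rank-sum test. Expected
p-values are means over instances; a feature is significant only when
**both** expected p fall below alpha (default 0.05) — the convergence rule,
whose intersection makes the overall call conservative (measured null false
positive rate ≪ alpha). The effect size is the median over instances of the
difference of group-median CLR values; its sign sets the enrichment
direction. Benjamini–Hochberg-adjusted expected p-values are always
computed and can drive the significance call in a stricter mode.

Sampling streams are keyed on (master seed, CRC32 of sample id), not on
table position. Consequences worth knowing: swapping the two tables flips
directions and negates effects but reproduces the identical significance
calls, and running a table against itself yields zero significant features.

## CAG binning (`cagbin`)

Co-Abundance gene Groups are genome proxies for organisms that cannot be
assembled: sets of genes whose temporal profiles covary with one "anchor"
OTU.

**PLS route.** A NIPALS partial least squares regression in regression mode
(Y deflated by X scores) predicts the gene CLR table from the OTU CLR
table; columns are centered and unit-scaled. Optional per-component
`keep_x` sparsity soft-thresholds the X weight vector to the requested
number of OTUs. The fitted latent components define a relevance network:

    weight(otu, gene) = Σ_h cor(x_otu, t_h) · cor(y_gene, t_h)

over X-score vectors t_h, clipped to [−1, 1] — the standard way to
reconstruct pairwise association from shared latent components. Edges with
signed weight below the threshold (default 0.8; CAGs group positively
covarying genes, so negative weights never qualify — an absolute-value mode
exists) and orphan nodes are pruned; each remaining OTU anchors one CAG.
By default every gene joins only its maximum-weight OTU (ties broken by
lexicographic OTU id and logged) so CAGs partition the genes; a `multi`
mode lets genes join several CAGs.

**Canopy route.** A reference-free alternative: genes are visited in table
order; each unassigned gene seeds a canopy that absorbs genes correlating
≥ 0.9 (Pearson, on normalized profiles) with the canopy centroid,
recomputing the centroid to a fixed point; canopies whose centroids
correlate ≥ 0.97 are merged transitively.

`n_components` defaults to 2; recovery runs against the synthetic generator
use one component per planted anchor minus none, i.e. `min(n_samples − 1,
n_otus)` when the anchors number close to the OTUs (7 for the 8-anchor
benchmark below). The 0.8 edge threshold is never tuned.

## CAG network, clusters, keystones (`cagnet`)

A CAG's temporal profile is the per-date **median** over member genes of
within-sample relative abundance (raw counts optional). Redundant CAGs —
full-profile Spearman > 0.95 to a CAG with the same taxonomy label and
amino-acid identity > 95 % when an AAI matrix is supplied — are collapsed
by transitive closure to the member with the most genes. The signed network
joins CAG profiles and environmental series (rank-transformed identically,
no detrending) with edges where Spearman rho > 0.8 or < −0.8, strictly.
Louvain modularity clustering runs on |rho| because modularity is undefined
for negative weights; the sign is preserved on every edge for display and
for centrality. Keystones are ranked by one-step ExpectedInfluence, the sum
of signed incident rho (negatives subtract); the sum of all EI values is
exactly twice the sum of edge weights, which the tests exploit as a
conservation check. Strength (Σ|rho|) is reported as a secondary score.

## Seasonality (`temporal`)

Bray–Curtis dissimilarity between sample count vectors; the lag-similarity
curve averages 1 − BC over all sample pairs separated by the same number of
calendar months. In a seasonal community the curve peaks at 12-month
multiples and dips at half-period lags. ANOSIM uses Clarke's statistic
R = (mean between-group rank − mean within-group rank)/(M/2) on the ranked
off-diagonal dissimilarities with average-rank ties, and a label-permutation
p-value `(1 + hits)/(1 + n_perm)`.

## Pathway coverage (`pathways`)

A KO set covers a pathway by the fraction of the pathway's KOs it contains;
pathways at or above 25 % coverage (inclusive — "at least") are reported.
KO→pathway maps may be many-to-many.

## Synthetic data (`synthdata`)

The generator emulates the statistical structure of the study design, not
its sequences:

* 40 monthly samples over ~3 years; OTU *i* has expected abundance
  `exp(mu_i + A_i · sin(2π(t − phase_i)/P))` with period P = 12 months.
  Phases are stratified evenly over the cycle (annual succession); with a
  shared-period sinusoid the phase is an OTU's only dynamic fingerprint, so
  an even spread is what keeps distinct OTUs statistically distinguishable.
* A `rare_fraction` of OTUs is pinned so their expected relative abundance
  stays below the 0.01 % cutoff all year. Rare OTUs and background (tail)
  genes carry the full seasonal amplitude while abundant OTUs get a damped
  one (`abundant_amplitude_factor`, default 0.3) — reproducing the
  observation that the rare gene pool carries the clear seasonal signal
  while the abundant pool is comparatively arrhythmic.
* Each planted CAG gene is its anchor's expected profile times a fixed
  per-gene lognormal factor times multiplicative lognormal noise
  (`noise_sd`, default 0.2 — a free parameter swept in tests, since no
  quantitative gene-vs-OTU noise model is established). Per-gene factors
  are normalized by the anchor's mean so gene-table compositions are not
  dominated by abundant-anchored CAGs.
* Counts are one multinomial per sample at a fixed `library_size` (default
  50 000), which yields the compositional, zero-inflated tables the
  statistics assume. The noise-free latent matrices are kept on the dataset
  for exact oracle tests.
* Environmental covariates are noise-free sinusoids phase-locked to the
  season: temperature peaks mid-summer, oxygen in antiphase, nitrite offset.
* `assign_fractions` is a desk-scale proxy for the read-mapping split: a
  gene's counts in a sample are "unassembled" when its anchor OTU's
  realized relative abundance is below `coverage_threshold` (default 1 %);
  background genes, which have no anchor, are routed by their own relative
  abundance. Counts are conserved cell-wise.

What the generator does **not** emulate: read-level error, assembly
artifacts, PCR bias, taxonomic structure, overdispersion beyond the
lognormal gene noise, autocorrelated environmental noise, and trends across
years. Passing tests therefore demonstrate correctness of the statistical
machinery under the planted model, not performance on real sequence data.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run the chain at these sizes:
prevalence filter vs brute force on 1000 random toy tables; czm vs an
independent loop-coded oracle on 100 tables; differential-test null
calibration on 20 replicates of 200 features × (20+20) samples at n_mc = 16
and power on 50 replicates with one 8-fold feature; CAG recovery on 8
planted CAGs × 30 genes × 40 samples (ARI ≥ 0.9 at noise 0.2; exact for
both PLS and canopy at noise 0); network oracles on 100 random instances
plus 20 planted 3-block Louvain graphs; the lag-12 vs lag-6 seasonal
contrast over 20 generator seeds; ANOSIM on separated, null and hand-worked
cases; and the 25 % pathway boundary.

## Known limitations

* The relevance-weight definition and the signed-weight reading of the 0.8
  edge threshold are design choices isolated behind `relevance_weights` and
  `build_bipartite(mode=...)`; alternatives swap in without touching CAG
  extraction.
* Louvain on |rho| treats strong negative correlation as affinity for
  clustering purposes; signed-modularity methods would differ.
* Redundancy collapse uses transitive closure, so long chains of pairwise-
  redundant CAGs collapse to a single representative even when the chain's
  endpoints correlate weakly.
* ANOSIM permutations are exhaustive only in spirit; p-values are Monte
  Carlo with the usual +1 correction and are seed-deterministic.
* MSPminer-style binning is not implemented; canopy covers the
  correlation-clustering alternative at desk scale.
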