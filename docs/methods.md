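# Methods

## Scope

`ecoassembly` implements the statistical stage of a microbial-eukaryote
community survey: it starts from a denoised ZOTU (zero-radius OTU) count
table, a rooted phylogeny of the ZOTUs, and per-sample metadata, and ends
with alpha/beta diversity, ordination, group tests, and a null-model
partition of community assembly processes. Read processing (quality
filtering, merging, denoising, taxonomy assignment) is out of scope; the
package expects its inputs to come from the standard upstream tools.

## Normalization

Taxa with fewer than `min_total_count` reads over all samples (default 4)
are removed, the usual guard against denoising artifacts. Samples are then
rarefied once to a common depth — by default the smallest post-filter
sample total — by drawing without replacement from each sample's reads
(multivariate hypergeometric), which preserves support (a taxon absent from
a sample stays absent) and makes downstream richness and total-read
conditioning well defined. Rarefaction is a single draw per seed rather
than an average over repeated draws; the choice is exposed through the seed
and the `rarefaction_depth` option, and the rarefied table is written to
disk so any statistic can be traced to it. Samples shallower than the
target depth are dropped with a warning, never up-sampled.

## Diversity

Alpha indices per sample: observed richness, Shannon entropy (natural log
by default, `base=2` available since toolchains differ), bias-corrected
Chao1 `S_obs + F1(F1-1) / (2(F2+1))` (defined even with no doubletons),
and Faith's phylogenetic diversity. Faith's PD is root-inclusive by
default (branches from the observed tips all the way to the root are
counted, so a single-tip sample scores its root-to-tip path length);
`include_root=False` gives the subtree-only convention. Both conventions
are tested against an independent branch-enumeration implementation and
against scikit-bio.

Beta diversity uses Bray–Curtis on the rarefied counts,
`d(x,y) = Σ|x_i − y_i| / Σ(x_i + y_i)`, and unweighted UniFrac (fraction
of branch length leading to taxa of exactly one community) via scikit-bio.

## Ordination

PCoA is classical scaling: Gower double-centering of −½D², eigen-
decomposition, coordinates scaled by √eigenvalue. Negative eigenvalues
(non-Euclidean inputs) are dropped from the coordinates and reported with
their magnitudes. nMDS minimizes Kruskal stress-1 by SMACOF with
pool-adjacent-violators monotone regression; ties in the input
dissimilarities get the primary treatment (tied pairs are pre-sorted by
the current configuration distances, so they impose no mutual order
constraint). Each fit runs from a PCoA configuration plus `n_starts`
random starts and keeps the lowest-stress solution. The recorded per-
iteration history is the normalized majorization objective
√(Σ(d−d̂)²/Σd̂²), which is monotone non-increasing; the reported final
stress is Kruskal stress-1 √(Σ(d−d̂)²/Σd²). Convergence tolerance is
1e-9 on the objective, 300 iterations maximum, with a `converged` flag
rather than an exception on non-convergence.

## Group statistics

ANOSIM ranks all off-diagonal dissimilarities and computes
`R = (mean between-group rank − mean within-group rank) / (M/2)`,
`M = n(n−1)/2`. The Mantel test correlates the off-diagonal entries of two
distance matrices (Pearson by default, as in vegan; Spearman available)
and permutes rows/columns of one matrix jointly; it is one-sided
(greater), vegan's default. Both tests use the +1-corrected p-value
`(hits+1)/(n_perm+1)` for random permutations — p = 0 is impossible — and
switch automatically to complete enumeration of all distinct relabellings
whenever that count does not exceed the requested permutation number, so
small problems get exact p-values. SIMPER decomposes the average
between-group Bray–Curtis into per-taxon contributions
`δ_i = mean over pairs of |x_ij − x_ik| / Σ_s(x_sj + x_sk)`; because it
runs on the same rarefied counts as the distance matrix, Σδ_i equals the
average between-group dissimilarity exactly (tested at 1e-12). Venn
counts of shared/exclusive taxa use post-rarefaction presence.

## Assembly-process partition

The two-step null-model framework classifies every sample pair.

**Phylogenetic step.** The abundance-weighted beta mean nearest taxon
distance is
`βMNTD(A,B) = ½[Σ_{i∈A} f_iA min_{j∈B} d(i,j) + Σ_{j∈B} f_jB min_{i∈A} d(i,j)]`
on patristic distances d; a taxon present in both communities has
nearest-taxon distance 0, so identical communities score 0. The null
shuffles taxon identities across the tips of the metacommunity phylogeny:
one joint permutation of the patristic matrix's rows and columns per
randomization, shared by all pairs in that randomization (999 by default).
βNTI is the standardized deviate (observed − null mean)/null sd. When the
null sd is below 1e-12 — e.g., all taxa equidistant — βNTI is recorded as
missing with a warning and the pair is excluded from (and counted in) the
partition. |βNTI| > 2 signals selection: positive heterogeneous, negative
homogeneous. The ±2 threshold follows the established practice for this
framework and is a parameter, not a constant.

**Taxonomic step.** For the remaining pairs, observed Bray–Curtis is
compared against null community pairs assembled from the metacommunity:
membership is drawn without replacement with probability proportional to
occurrence frequency, conditioned on the observed richness (implemented by
Gumbel top-k, which is exactly sequential weighted sampling without
replacement); reads are then distributed multinomially with probability
proportional to metacommunity relative abundance restricted to the drawn
taxa, conditioned on the observed read total (hence the requirement of
equal, rarefied depths). `RC_bray = 2[(#(null<obs) + ½#(null=obs))/n_null] − 1`,
with an absolute tie tolerance of 1e-12, lies in [−1, 1].
RC > 0.95 → dispersal limitation, RC < −0.95 → homogenizing dispersal,
otherwise drift. Each sample pair draws from its own RNG stream derived
from the master seed and the pair indices, so results do not depend on
the order pairs are evaluated in.

Both null-model sizes default to 999 and are independently configurable;
a stability test checks that reducing 999 → 499 changes ≤5% of
classifications on a mid-sized scenario.

## Synthetic metacommunities

The generator exists so that every statistic above can be validated
against known ground truth. It builds a Yule (pure-birth) phylogeny,
rescaled to unit height so trait-model parameters are comparable across
tree sizes, and evolves a habitat-preference trait by Brownian motion
(tip variance = `trait_sigma²` × root-to-tip length). Metacommunity
abundances are lognormal. The regimes:

- **selection** — sampling weight ∝ metacommunity abundance ×
  `exp(−(trait_i − env_s)²/(2 filter_width²))`; habitats get distinct
  optima (defaults ±1 on the unit-height trait scale, niche breadth 0.35),
  so cross-habitat pairs experience heterogeneous selection.
- **dispersal_limited** — each sample draws neutrally from its own random
  subset (fraction 0.3) of the pool, with per-sample lognormal drift
  multipliers (σ = 2) on the abundances. The multipliers model isolated
  localities whose relative abundances have drifted apart; without them a
  random-subset community is statistically indistinguishable from the
  Raup–Crick null (random membership at matched richness) and the regime
  would be classified as drift by construction.
- **neutral_drift** — independent multinomial draws from one shared
  metacommunity.
- **mixed** — SW samples dispersal-limited, MP samples neutral, the
  configuration used to emulate an open-water vs. melt-pond contrast; an
  optional `mp_pool_fraction < 1` restricts the MP source pool, which
  reproduces the lower alpha diversity of pond communities.

Read depths are Poisson(`depth_mean`, default 5000); salinity is the
habitat mean (SW ≈ 29, MP ≈ 2.5, typical of Arctic surface sea water and
closed melt ponds) plus unit-variance noise, so salinity-driven Mantel
tests behave as they do on habitat-structured field data.

The default `lognormal_sigma = 1.5` matters: microbial communities are
strongly uneven, and the betaMNTD null degenerates (sd = 0) if every
sample contains every taxon, which is what happens at depth 5000 with a
nearly even metacommunity. At σ = 1.5 sample membership varies realistically
and each pure regime is recoverable; the defaults were fixed by that
recoverability requirement, not tuned to any field dataset.

What the generator does **not** emulate: sequencing error, chimeras, PCR
bias, copy-number variation, temporal dynamics, or spatially explicit
dispersal kernels. Passing the recovery tests therefore shows the
inference machinery is correct and well calibrated under the stated
generative assumptions — not that those assumptions describe any
particular field system.

## Problem sizes and verification

The test suite validates every distance, diversity, and turnover statistic
against independent brute-force implementations (explicit double loops,
ancestor walks, exhaustive permutation enumeration, tree-object tip
relabeling for the betaMNTD null) at 1e-10 on dozens of random small
fixtures, and checks permutation-test calibration (type-I error 0.05 ±
0.02 over 1000 neutral simulations). Regime recovery is evaluated on 50
scenarios per regime at 100 taxa, 8 samples per habitat, ~5000 reads per
sample and 499 null draws — sizes chosen so the full ground-truth sweep
runs comfortably on a single CPU while keeping ≥28 within-habitat pairs
per scenario. The modal class matches the generating regime in ≥80% of
scenarios for each regime at the default thresholds.

## Known limitations

- The Raup–Crick null conditions on observed richness and occurrence
  frequency computed from the analyzed table itself; with very few samples
  the null is accordingly coarse.
- βNTI is undefined for degenerate phylogenies (all tips equidistant) and
  for pairs of effectively identical communities; such pairs are excluded
  and reported rather than imputed.
- nMDS is a local optimizer; multiple starts mitigate but do not eliminate
  local minima.
- The partition attributes each pair to exactly one process; mixtures of
  processes within a pair are not modelled (no per-clade binning).
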