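# Methods

## The analysis model

The pipeline treats a microbiome survey as an OTU-by-sample integer count
matrix with two companion tables: per-sample metadata (host genus,
location, biological vs technical replicate) and per-OTU taxonomy.  All
statistics operate on per-sample relative abundances (counts divided by
sample totals); no rarefaction is applied by default, since every
downstream statistic is either rank-based (Spearman), composition-based
(Bray–Curtis), or explicitly per-sample (Shannon).  An optional seeded
rarefaction mode can be added for sensitivity checks without changing any
interface.

### Community comparison

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is a semimetric on
[0,1] for compositions; identity and symmetry are enforced, the triangle
inequality is neither assumed nor asserted.

One-way PERMANOVA uses the distance-based sums of squares

    SS_total  = (1/N) Σ_{i<j} d²ᵢⱼ
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ
    F         = ((SS_total − SS_within)/(a−1)) / (SS_within/(N−a))

with significance from m seeded whole-label permutations and the
p = (b+1)/(m+1) estimator, where b counts permuted F values at or above
the observed one — p can therefore never be exactly zero and the test is
exactly calibrated under exchangeability.  Default m = 9999.  Pairwise
comparisons run one PERMANOVA per unordered group pair on that pair's
sub-matrix and report raw p-values; a Bonferroni helper is provided but
off by default, matching how such surveys conventionally report pairwise
tests.

NMDS minimizes Kruskal stress-1,
√(Σ(d̂ᵢⱼ − θ(dᵢⱼ))² / Σ d̂ᵢⱼ²), where θ is fitted by monotone (isotonic)
regression on the rank order of the observed dissimilarities.
Optimization is SMACOF majorization; initialization is classical
(Torgerson) metric scaling plus n_restarts − 1 seeded random starts
(default 20 restarts, 2 dimensions, 300 iterations, tolerance 1e-7), and
the best stress is returned, making best-of-restarts stress non-increasing
in the number of restarts.  A standalone stress evaluator allows scoring a
fixed configuration (stress is invariant under rotation, translation, and
uniform scaling).

Cluster analysis is UPGMA (average linkage) implemented directly so that
tie-breaking is deterministic (lexicographic order of the clusters'
smallest member ids) and the ultrametric tree exports to Newick with
merge heights at d/2.  It is cross-checked against SciPy average-linkage
cophenetic distances in the tests.

### Co-occurrence networks

Within one host dataset, OTUs below 0.1% mean relative abundance over
that host's samples are removed first; the mean is taken over the host's
coral samples only (seawater excluded), across all its locations, since
the networks are per-host coral networks.  An OTU at exactly 0.1% is
retained (only "lower than" the threshold is removed).  Whether such
surveys compute this mean with or without seawater or technical
replicates is generally unstated; the scope is a documented, configurable
default.

Spearman ρ is the Pearson correlation of average-tie ranks; the two-sided
p-value uses the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom (the Hmisc-style computation), with |ρ| = 1 mapped to the
smallest representable positive p and constant OTU vectors skipped with a
log message.  An edge requires ρ > 0.6 strictly and p < 0.01 strictly —
positive co-occurrence only.  Network nodes are the endpoints of
qualifying edges: abundance-filtered OTUs with no qualifying partner are
not part of the network (surveys report fewer network nodes than filtered
OTUs, implying exactly this convention).

Topology: mean degree is exactly 2E/N; mean path length and diameter are
taken over finite shortest paths, pooled across components by default
(per-component averaging is available); the clustering coefficient
averages the local coefficient over all nodes with degree < 2
contributing 0.  Communities and modularity Q come from seeded Louvain
optimization on the unweighted graph at resolution 1.0; "modular
structure" means Q > 0.40 strictly.  Because community detection
heuristics and their settings vary across tools, exact reproduction of a
particular survey's Q is not promised — the tests instead verify Q
against hand-computed partitions and the non-negativity guarantee
relative to the trivial partition.

The non-randomness test permutes each OTU's abundance vector across
samples independently, preserving every OTU's marginal distribution while
destroying cross-OTU association, rebuilds the network each replicate,
and compares the qualifying-edge count to the observed one with the
(b+1)/(m+1) estimator (default 999 replicates).  This null is exactly
valid when OTU rows are independent.  On softmax-compositional data the
rows are *not* independent — shared-denominator fluctuations induce weak
cross-OTU association even without planted structure — so on such tables
the test is a test of *any* association, compositional or ecological;
this is a property of all correlation-network methods on relative
abundances, and is why the calibration check uses tables with truly
independent rows.

### Cross-network comparison and profiles

Shared-species analysis is exact set algebra on node ids with per-taxon
tallies (Proteobacteria at class level, everything else at phylum level,
matching the usual network coloring).  The three abundance-profile groups
are assigned by explicit quantitative rules, in precedence order:
location-variable if the coefficient of variation of per-location coral
means exceeds V (default 1.0); else coral-enriched if the coral mean is at
least E times the seawater mean (default E = 10); else seawater-similar
if coral and seawater means are within a factor S (default 3).  OTUs
matching no rule are assigned to the nearest rule's group and flagged.
Published figures of this kind are typically curated visually; these
thresholds are this package's construction, exposed as configuration, so
a particular published split is emulable but not promised.  The heat-map
matrix is log10 percent relative abundance (−2 ↔ 0.01%, −1 ↔ 0.1%,
0 ↔ 1%, 1 ↔ 10%) with zeros as a distinct non-detected category.

## The synthetic study generator

The generator emulates a two-genus coral survey: Galaxea at four
locations and Montipora at four locations (~6 biological replicate
colonies each, 59 samples total including technical replicates and 13
replicated seawater references), ~10,000 reads per sample.  For OTU i in
sample s,

    log aᵢₛ = baselineᵢ + hostᵢ(h(s)) + locᵢ(l(s)) + λ_g f_{g,s} + εᵢₛ

relative abundances are the softmax over OTUs and counts are multinomial
at Poisson(10,000) depth.  Technical replicates redraw only the depth and
multinomial from the same latent state, mirroring how technical replicates
in real surveys cluster tightly.

Parameter defaults, chosen once to put the generator in the regime such
surveys report and documented here:

- **baseline_sd = 2.0** (log scale): OTU baselines span several natural-log
  units so that a minority of the 300 OTUs (typically 70–90) clear the
  0.1% filter, as in real OTU tables where most OTUs are rare.
- **host_effect_sd = 1.5**: host identity is the dominant driver;
  PERMANOVA on host labels rejects decisively and hosts separate in NMDS.
- **location_effect_sd = 0.3**: location structures composition more
  weakly than host, consistent with surveys that find host > location.
- **noise_sd = 1.0**: e-fold residual variation between replicate
  colonies.
- **depth_mean = 10,000** reads, Poisson-distributed per sample.

**Guilds.** A guild is a set of ≥3 OTUs loading on a shared per-sample
latent factor — the planted ground truth for co-occurrence.  Planting is
variance-preserving: a member's residual noise is scaled down so factor
plus residual carry the same marginal variance as any other OTU, and the
loading is capped at the residual budget.  (An additive factor at high
loading would dominate the softmax denominator and induce dense spurious
positive correlation among *all* abundant OTUs — a compositional artifact
that buries the planted structure and produces near-clique networks unlike
any real survey.)  Guild members receive a +3.0 baseline shift so they sit
clearly above the abundance filter; the planted "co-occurring species" are
abundant, as the filter guarantees for real network OTUs.

The loading for a target within-guild Spearman ρ_s uses the bivariate
normal map r = 2 sin(πρ_s/6), λ = noise_sd·√r/factor_sd, times an
inflation factor 1.1 fixed by Monte-Carlo calibration over 200 replicate
simulations at 40 samples.  The observation layers (independent
location-block effects, multinomial counting, zero-count rank ties)
attenuate the realized rank correlation below the latent target: at a
latent target of 0.8 the realized within-guild mean Spearman is ≈ 0.69
(median ≈ 0.71) over 40 samples, inside the 0.6–0.95 band the planted
structure is specified to land in, and saturating near the cap — under
this observation model a realized 0.8 is not reachable without distorting
the composition.

**What the generator does not emulate:** sequencing error, chimeras, or
read-level artifacts (counts are drawn directly); phylogenetic
correlation between related OTUs; overdispersion beyond the log-normal
residual (no per-taxon dispersion parameters); negative interactions
(guild factors only plant positive association).  Passing tests therefore
demonstrate that the statistics are implemented correctly and recover
planted structure under a realistic abundance model — not that the
pipeline is robust to every artifact of real amplicon data.

## Numerical and design choices

- Shannon index defaults to the natural log with a base-2 option; the log
  base of any published table is often unstated, so outputs always carry
  the base label.  Quartiles in group summaries use linear interpolation.
- The (b+1)/(m+1) permutation p-value estimator is used everywhere a
  permutation null appears (PERMANOVA, non-randomness), making p-values
  positive and calibration exact on the permutation grid.
- All randomness flows from a single root seed through named
  `numpy.random.SeedSequence` substreams (structure, taxonomy, sampling;
  per-stage seeds in the pipeline), so a configuration reproduces its
  outputs byte for byte.
- Degenerate inputs fail loudly before computation: zero-total samples,
  duplicate ids, constant distance matrices (pseudo-F undefined),
  all-equal dissimilarities (NMDS undefined), empty graphs, groups of
  size < 2.
- Problem sizes in the test-suite calibration checks (e.g. 16-sample
  40-OTU null tables at 199 permutations for the type-I-error sweep,
  99-replicate nulls over 500 independent tables) are chosen so the
  discrete permutation grid is fine enough for the nominal level to be
  attainable while a full sweep stays a desk-scale computation.

## Known limitations

- Correlation networks on relative abundances inherit compositional
  coupling; the package documents rather than corrects it (no
  SparCC-style compositional correction is attempted).
- The Louvain heuristic is seeded but heuristic: community *labels* are
  reproducible under a fixed seed, community *structure* on weakly
  modular graphs may differ between resolutions or tools.
- Pairwise PERMANOVA reports raw p-values by default (78 tests for 13
  groups); users comparing many groups should consider the provided
  Bonferroni adjustment.
- The profile classification thresholds (E, S, V) are declared defaults,
  not values inferred from any published figure.
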