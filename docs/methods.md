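# Methods

## The analysis in brief

The package analyzes how tree diversity structures soil fungal
communities in a designed forest experiment. The planting follows a
broken-stick scheme: a 16-species pool is recursively halved into plot
communities of 16, 8, 4, 2 and 1 species (31 plots); five soil samples
are taken under each tree species in each plot. Because plot numbers and
within-plot replication differ across richness levels, diversity levels
are compared through a *subsampling* scheme that equalizes sampling
effort: every comparison uses 7 tree species and 7 plots per diversity
class (monoculture, two-species, high = 4/8/16 pooled), with one species
sampled per plot. Each such subsampling combination yields one bipartite
tree × OTU web per class and link threshold, one set of network
statistics, and one set of phi specialization coefficients; distributions
over all combinations are then contrasted across classes with rank
statistics.

## Preprocessing

Order is fixed: (1) OTUs with a grand total of at most 3 reads
(singletons through tripletons) are discarded; (2) each sample is
rarefied to a uniform depth (default 700 reads) by a
multivariate-hypergeometric draw, i.e. uniform subsampling of reads
without replacement; (3) OTUs with fewer than 10 reads in the rarefied
table are pruned; (4) counts become presence/absence.

Samples whose total is below the rarefaction depth are dropped by
default (a `drop_small=False` flag keeps them unrarefied); uniform column
sums are worth more than the handful of shallow samples. Each sample's
rarefaction stream is keyed on a CRC of its identifier plus the global
seed, so results do not depend on column order. Note that pruning runs
*after* rarefaction, so final column sums may sit a few reads below the
depth.

## Combination enumeration

Enumeration is driven by the two-species level: all choices of 7 of the
8 two-species plots and one planted species per chosen plot (8 × 2⁷ =
1024; 576 once one species is excluded, as done for a species with high
mortality in the motivating experiment). Monoculture cells are then
forced (each species has exactly one monoculture). For the high class,
each species must be assigned a distinct plot containing it; among all
perfect matchings we take the lexicographically smallest under (species
order, sorted plot id), computed by greedy fixing with an
augmenting-path feasibility check. The assignment rule is a
reproducibility choice — any fixed deterministic matching would do, and
species choices with no perfect matching are discarded with a logged
count. Combination ids are assigned in sorted order so results join
across output tables. The number of cells per class is a parameter
(default 7) so that smaller designs (e.g. the 8-species test fixture,
which has only 4 two-species plots) can run the identical machinery.

## Webs and their statistics

A web links tree species *s* to OTU *f* when *f* occurs in at least *t*
of the 5 samples of *s*'s cell (*t* ∈ 1…5); OTU columns with no links
are dropped. Statistics, all on binary webs:

- connectance = L/(I·J);
- generality: link-weighted mean effective partner number; for binary
  webs the effective number of an OTU is its degree, giving Σd²/L
  (a plain mean degree would understate Table-style magnitudes on
  asymmetric webs);
- C score: mean over OTU pairs of (r_f−S)(r_g−S)/(r_f·r_g), in [0,1];
- NODF with strict decreasing fill: rows and columns sorted by
  decreasing totals, ordered pairs with strictly larger totals
  contribute 100·overlap/(smaller total), ties contribute 0, row and
  column pairs averaged together;
- mean shared partners: mean pairwise intersection of tree link sets
  (the standard pairwise definition; a published table footnote reads
  like "OTUs linked to ≥2 trees", but the pairwise definition is the
  established metric and matches the reported magnitudes);
- Barber bipartite modularity, maximized by a label-propagation
  optimizer: random initial labels, single-node moves (including opening
  a fresh module) alternated with greedy pairwise module merging until
  neither improves Q, best of `restarts` seeded restarts (default 20).
  Zero-gain merges are taken, so among Q-optimal partitions the fewest
  modules are reported (a complete web is one module). The optimizer
  matches exhaustive partition search on all tested webs of ≤ 10 nodes.
- richness and Shannon entropy (natural log) on counts pooled over the
  class's 35 samples.

Degenerate webs (e.g. a single OTU column at threshold 5 on sparse
data) raise in strict use; the pipeline records NaN for the affected
metrics and excludes them from medians and rank tests.

## Null model

The post-preprocessing count table is shuffled with fixed row and column
sums (Patefield's algorithm, via `scipy.stats.random_table`; 1 × n and
n × 1 tables are forced by their margins and returned as-is), then the
identical incidence → web → NODF pipeline is re-run per combination.
Observed and null NODF distributions are compared per class with a
two-sided Wilcoxon rank-sum test (unpaired; the replicate count per
shuffle is a flag, default 1).

## Phi specialization

Per combination and class, an OTU's plot-level presence is ≥ 1 of the
cell's 5 samples (a flag raises this; the web link threshold is
deliberately independent). For each OTU present somewhere and each of
the 7 species: a = presence in the species' plot, b = presences among
the other 6, c = 1−a, d = 6−b, and φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)).
φ is undefined when a margin is zero — exactly when the OTU occupies
none or all 7 plots — and such records are excluded from medians and
group tests. Summaries: median of strictly positive φ per combination;
Kruskal–Wallis over positive φ grouped by guild with a critical-difference
post hoc; per-OTU maxima ranked, top 200 clustered by average-linkage on
Euclidean distances (the linkage is our choice; only the distance is
conventionally fixed); frequent OTUs are those occupying all 7 plots of
at least one combination at a class, with occupancy histograms for OTUs
frequent at exactly one class.

## Rank statistics

Kruskal–Wallis (tie-corrected, chi-square reference), the
Siegel–Castellan critical-difference post hoc on mean ranks with plain
Bonferroni or Holm step-down adjustment (Holm is the default for
table-style reporting; both appear in the literature this follows), Holm
p-value adjustment, and the two-sample Wilcoxon rank-sum test (exact by
enumeration for n ≤ 12 without ties, otherwise normal approximation with
tie and continuity correction) are implemented directly from their
definitions; only chi-square and normal tail probabilities come from
scipy, and scipy's implementations serve as independent cross-checks in
the test suite. P-values are floored at 1e-15 in formatted output.

## Synthetic data

The generator emulates the occurrence structure the analysis detects,
not the sequencing process. Presence and abundance are separated
(zero-inflation): per sample, an OTU is present with probability
`p_focal` if the plot contains its preferred species, else `p_bg`;
conditional abundance is a log-series draw scaled by a per-OTU lognormal
abundance parameter; reads per sample are multinomial at a uniform
random depth (default 700–3000). Defaults: 2000 OTUs, 20% specialists
with p_focal = 0.5 and p_bg = 0.08, generalist occupancy uniform on
(0.02, 0.3), guild proportions 31% saprotroph / 7% EcM / 5% AM / 5%
pathogen / 46% unknown / 6% other — the composition reported for such
communities. The species-pool halving is random per seed. A
`n_missing_samples` option removes whole samples to emulate field losses
(6 missing reproduces the 394-sample scale of the motivating dataset).

What the generator does **not** model: spatial autocorrelation, soil
covariates, sequencing error, chimeras, compositional biases between
samples, or phylogenetic signal in host preference. Passing tests on
synthetic data therefore demonstrate that the *computational* pathway
recovers planted occurrence structure, not that real communities behave
this way. Multinomial read allocation slightly thins occupancy relative
to the Bernoulli presence draw, so realized occurrence rates sit just
below `p_focal`.

Presets: `tiny` (8 species, 15 plots, 200 OTUs) for fast tests,
`paperlike` (16 species, 31 plots, 2000 OTUs), `null` (no specialists).

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled versions of the
full analysis: the acceptance pipeline uses 600 OTUs and an evenly
spaced subset of 64 of the 576 combinations at the 3/5 threshold with 6
modularity restarts and one null replicate; the parameter-recovery
experiment uses 500 OTUs, 16 combinations and 50 data seeds on a fixed
design. These sizes preserve every qualitative contrast (webs less
nested than null, specialist recovery, level differences) while keeping
runs to minutes. Phi medians over 7 plots have a discrete support, so
specialist-vs-generalist median comparisons at small OTU counts can tie;
500 OTUs makes the comparison stable. The no-enrichment control uses
randomly drawn pseudo-specialist labels over OTUs generated without any
planted preference, making the two groups exchangeable by construction.

Floats in result TSVs are serialized at 6 significant digits for
byte-stable outputs; seeds are split hierarchically (master → stage →
per-combination) and recorded in the run manifest.

## Known limitations

- The modularity optimizer is a heuristic; its optimality is verified
  exhaustively only on small webs, and on large webs Q is a lower bound.
- The pipeline assumes exactly 5 samples per (plot, species) cell when
  building webs; designs with missing cells must be handled upstream
  (the phi pathway only requires non-empty cells).
- BIOM support covers the 2.1 HDF5 layout read-only; TSV is canonical.
- Weighted (quantitative) webs, weighted NODF, nestedness temperature,
  and alternative null models (swap, quasiswap, proportional) are out of
  scope.
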