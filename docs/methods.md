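# Methods

## Analysis model

The pipeline assumes the classic replicated two-group microarray design
per platform: linear-scale intensities for a progenitor condition and a
designated reference condition, with per-sample presence calls
(Present / Marginal / Absent) produced upstream by the array software.
Stages and their contracts:

**Flag filter.** A gene is retained when it carries a P or M call in at
least `min_called` (default 2) replicates of at least one condition;
the reference counts as a condition, so genes expressed only at the
reference stage (candidates for down-regulation) survive. The filter is
idempotent and order-preserving.

**Normalization.** Each gene's samples are divided by the median of its
reference samples. Medians are robust to a single outlying reference
replicate; a non-positive reference median is a data error naming the
gene.

**Differential test.** Fold change is the mean of the per-sample
condition ratios (configurable to ratio-of-means); down-regulation is
reported as the reciprocal magnitude so a 0.5 ratio prints as 2.0-fold
down. The p-value is a two-sided two-sample t-test on log2 values —
Welch by default, pooled-variance Student as an option. Because the
t-statistic is invariant to a common shift of both groups, testing the
log2 ratios is identical to testing the raw log2 intensities. A gene
with zero variance in both groups gets p = 1 when the means agree
(nothing happened) and p = 0 otherwise (an exact repeatable change).
No multiple-testing correction is applied by default, matching the
classical raw-p volcano convention; Benjamini–Hochberg is available
(`adjust="bh"`).

**Volcano filter.** Up-regulated: fold ≥ `min_fold` (1.2, inclusive —
"at least 20% change"), ratio > 1, p < `alpha` (0.05, strict). Down is
symmetric. Raising `min_fold` or lowering `alpha` can only shrink the
signature.

**Intersection.** Conserved sets are the direction-wise intersections
of the two platform signatures. Discordant genes (opposite directions)
and platform-only genes are reported separately; the five output sets
partition the union of the inputs. The reduction fraction
1 − |conserved| / |smaller signature| quantifies how much the
concordance requirement compresses the candidate list.

**Enrichment.** Category significance is the upper hypergeometric tail
P(X ≥ overlap) — a right-tailed Fisher exact test. The default gene
universe is every gene surviving the flag filter on either platform,
the natural "detectable background" choice. The weighted developmental
score is −log10 p(up) + log10 p(down), base 10 by the convention of
commercial pathway tools; it is exactly antisymmetric under swapping
the lists, and zero p-values are clamped to the smallest positive
double before the logarithm.

**Network growth.** Seeds are the conserved genes found in the
interaction database. A non-seed molecule is admitted when it has at
least `min_seed_links` (default 2) edges to seeds — partners must
*connect* seeds, not merely touch one; `min_seed_links=1` recovers the
plain first neighborhood. Edges are all database edges among included
nodes. Graphs are simple and undirected throughout; interaction-type
labels ride along as metadata and do not enter the topology math.

**Topology.** Degree distribution P(k) = n_k/N (including a k = 0 bin
when isolated nodes exist, so ΣP(k) = 1); clustering coefficient
C_i = 2e_i/(k_i(k_i−1)) in the Watts–Strogatz form, with C_i := 0 for
degree < 2 and such nodes excluded from the degree-binned C(k) profile
(configurable), matching common network-analyzer behavior. Both
scale-free and hierarchy diagnostics are unweighted least-squares fits
in base-10 log–log coordinates over bins with nonzero mass (no
pseudocounts); fewer than three usable bins is a fit error. Average
degree is 2|E|/N; the mean distinct-neighbor count is reported
alongside (identical on simple graphs, retained for inputs that carried
multi-edges before canonicalization).

**Hubs, scores, cover.** Hubs default to the top 9 nodes by
within-subnetwork degree; a tie at the boundary expands the set rather
than dropping a tied node arbitrarily, and the expansion is recorded.
Relative pathway connectivity Y_i = x_i/N is the fraction of hubs gene
i directly neighbors. An axis "hits" the hubs adjacent to its receptor
node (the receptor anchors the axis; a ligand absent from the network
does not disqualify it; a path-length ≤ L option exists for sensitivity
analysis). The minimal cover is found by enumerating axis subsets in
increasing size — exact and certificate-carrying up to `exact_limit`
(20) candidate axes, far above the natural scale of the problem (a
handful of axes, about nine hubs); beyond that a greedy max-coverage
fallback runs with `minimal=False`. Ties among equal-size covers break
by larger summed receptor Y_i, then lexicographic axis names. An
infeasible instance returns the best partial cover with the uncovered
hubs listed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with a planted, recoverable answer at every stage.

*Expression.* Both platforms measure one shared gene universe: 55
conserved up + 233 conserved down (the default conserved pool), 150
platform-specific genes per platform per direction, and 2000 background
genes, over 3 biological replicates per condition. Values are simulated
on the log2 scale — baseline ~ U(8, 12) for expressed genes, a silent
quarter of the background at U(4, 6) — with i.i.d. Gaussian replicate
noise (sd 0.25) and reported linear (2^x), so the t-test on log2 values
is exact for the model. True effects: magnitude |N(1.0, 0.25)| clipped
at 0.5 (every planted gene is genuinely ≥ 1.4-fold), sign by direction;
conserved genes share sign *and* magnitude across platforms, background
genes have zero effect. Flags derive from latent log2 thresholds
(Absent < 6.5 ≤ Marginal < 7.0 ≤ Present) and are corrupted at a 2%
miscall rate. One integer seed drives named substreams (expression /
network / annotations), so identical seeds give byte-identical outputs.

*Filter sensitivity.* Under these conditions the signature stage is
deliberately power-limited: a 3-vs-3 two-sample t-test at a log2 effect
of 1.0 and noise sd 0.25 has per-platform power ≈ 0.88 (Welch; ≈ 0.94
pooled), and conserved recovery requires independent detection on both
platforms, so expected recall is roughly power², ~70–80% — with
unplanted contamination well under 5%. This is a property of the
three-replicate design itself, not of the implementation; passing the
recovery tests therefore demonstrates correct mechanics and calibrated
false-positive control, not that three microarray replicates suffice to
catch every 2-fold change.

*Network.* The molecule graph grows by preferential attachment with
triad closure (Holme–Kim; `m=4` edges per node for interactome-like
density at the default 400 nodes; the standalone diagnostic generator
defaults to a sparser `m=2`, which yields the cleanest power-law tail),
jointly producing power-law degrees and degree-dependent clustering —
the scale-free + hierarchical combination. The 9 planted hubs are the
top-degree nodes; their degrees are topped up with edges to seed genes
until every hub's seed-neighbor count exceeds the maximum non-hub
degree, which makes top-9 selection exact both in the database graph
and in any grown sub-network (seed neighbors always survive growth).
Ten ligand–receptor axes take planted up-regulated genes as receptors
(each ligand enters as a degree-1 "binds" partner). The three planted
covering axes split the hubs into one group each and are wired to
exactly their group; every decoy axis touches strictly fewer hubs than
the smallest group. A counting argument then makes the planted triad
the *unique* minimum cover (any k-subset using j ≥ 1 decoys covers at
most Σ(top k−j groups) + j·(min group − 1) < 9 hubs), and generation
verifies this exhaustively, regenerating from a fresh substream on
failure (bounded retries).

*What the generator does not emulate:* probe-level effects, batch and
dye effects, heteroscedastic per-gene variances, correlated replicate
noise, dropout, or curated-database biases (literature skew, study
coverage). Recovery results on synthetic data bound what the pipeline
can do when its model holds; real-array performance depends on upstream
normalization quality.

## Numerical and design choices

- Fold boundary inclusive (≥ 1.2), alpha strict (< 0.05).
- Welch default for the t-test: replicate variances on real arrays are
  rarely equal; the pooled test is one flag away when they are.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; clustering
  from `networkx`; both are cross-checked in the test suite against
  independent brute-force enumeration (combinatorial summation,
  triangle counting) on exhaustive small domains.
- Enrichment ties break by category name; hub ties expand; cover ties
  break by summed Y then names — every ordering in the pipeline is
  deterministic and permutation-invariant.
- Degenerate inputs have defined behavior rather than crashes: empty
  hub set → vacuously feasible empty cover; empty gene list → all
  enrichment p = 1; all-equal-degree network → fully tied, expanded hub
  set; infeasible cover → partial cover with `feasible=False`.
- Problem sizes in tests and the acceptance script (20-seed sweeps,
  ≤ 25-node oracle graphs, 1000-node topology graphs, 500 random cover
  instances) were chosen to exercise every guarantee exhaustively while
  keeping a full run in seconds on a laptop.

## Known limitations

- The conserved-signature recall ceiling discussed above: with three
  replicates, genes near the clip boundary (log2 effect ≈ 0.5) are
  detected on both platforms only ~15% of the time.
- The growth policy treats the database as ground truth; false edges
  propagate directly into hub degrees.
- The exact cover solver is exponential in the number of candidate
  axes; `exact_limit` guards runtime, and the greedy fallback carries
  no minimality certificate.
- GraphML export is write-only; the pipeline's interchange formats are
  the plain-text TSV/GMT/SIF/JSON set.
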