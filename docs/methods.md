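# Methods

## Interactome and distances

All analyses run on the largest connected component (LCC) of a simple
undirected protein–protein interaction graph over opaque gene-identifier
strings. Edges are unweighted: the hop count is the only distance used.
Self-loops are dropped at load time and duplicate edges (either
orientation) collapse to one. Restricting to the LCC guarantees every
closest-distance query is finite; callers who skip it get an explicit
error when a source gene cannot reach the target set.

## Closest-distance proximity and the degree-matched null

The proximity from gene set `S` to gene set `T` is

    d(S, T) = (1/|S|) * Σ_{u∈S} min_{v∈T} d(u, v),

the average distance from each source gene to its nearest target gene.
It is asymmetric by construction; the package fixes the convention
first-argument → second-argument everywhere (disease → pathway for
spans, drug targets → pathway for rankings). Genes absent from the
interactome are dropped and recorded; the computation proceeds if at
least one gene survives on each side.

Raw distances are incomparable across sets because high-degree proteins
are close to everything. The null model therefore resamples **both**
endpoints: in each of `n_random` realizations (default 1000), `S` and
`T` are replaced by random gene sets of the same size whose members are
drawn, without replacement, from the degree bin of the corresponding
original gene. The z-score is

    z(S, T) = (d(S,T) − μ_random) / σ_random.

Degree bins group nodes by exact degree and merge adjacent degree
groups (ascending) until each bin holds at least `min_bin_size` nodes
(default 100, the convention for genome-scale interactomes of ~10⁴
nodes; a short final bin merges backwards). On small synthetic graphs
the default would lump a sixth of the graph into one bin and destroy
the matching, so desk-scale analyses here use `min_bin_size` of 25–50
for graphs of 300–500 nodes, keeping the bin fraction comparable to the
genome-scale setting. If a bin cannot supply enough distinct nodes the
draw widens to adjacent bins with a warning; sampling with replacement
is never used.

When the null distribution is degenerate (σ = 0 up to floating-point
noise relative to the statistic's scale) the z-score is flagged
undefined (NaN) and any significance decision on it returns "not
significant". Because both endpoints are resampled independently, the
null is degenerate only when the statistic is genuinely constant over
all degree-matched draws (e.g. S = T = V).

A pathway is **significantly proximal** to a disease at `z ≤ −2`
(one-sided, about two standard deviations below the random
expectation); the set of such pathways is the disease's **pathway
span**. The −2 cutoff is exposed as `z_cut`.

## Random-walk engine

As an alternative statistic, `rwr_scores` iterates the
random-walk-with-restart fixed point

    s ← r·e + (1 − r)·Wᵀ s

with `W` the column-normalized adjacency matrix, `e` uniform over the
seed set, restart probability `r = 0.5` and L1 convergence tolerance
1e-6 (both configurable; non-convergence after `max_iter` raises with
the last residual). The proximity statistic is the mean visit
probability over `T` with restarts on `S`; its z-score against the same
degree-matched null is **negated** so that "more proximal ⇒ more
negative" holds for both engines and a single `z ≤ −2` threshold serves
both. Random walks are intrinsically biased toward hubs, which is why
the shortest-path engine with degree-matched sampling is the default.

## Overlap enrichment and multiple testing

Conventional enrichment is the one-sided (upper-tail) Fisher's exact
test on the 2×2 membership table of a query set and a pathway in a
fixed gene universe; the default universe for a pathway collection is
all genes appearing in the collection intersected with the interactome.
Two-sided tests (used for disease–disease links) follow the
sum-of-smaller-point-probabilities convention of mainstream statistics
packages. Benjamini–Hochberg adjustment is the standard step-up
procedure, order-preserving, monotone and capped at 1. Both are
delegated to scipy/statsmodels internally and verified in the test
suite against exhaustive hypergeometric enumeration and a hand-rolled
step-up oracle. (BH is deliberately *not* claimed to be idempotent;
step-up re-application changes values in general.)

## Diseasome construction

Each disease pair is evaluated on up to four independent evidence
channels, each only from its own inputs:

- **shared genes** — two-sided Fisher on the gene overlap, p ≤ 0.05;
  default universe: union of all profile genes.
- **shared symptoms** — same test on symptom sets after keeping
  associations with TF-IDF strictly above 3.5; default universe: union
  of post-filter symptoms across profiles (a pair of identical profiles
  alone therefore carries no information — the universe must be wider
  than the sets).
- **comorbidity** — relative risk RR = c·n / (p_i·p_j) from
  co-occurrence counts, linked when RR > 1 (strict). Inputs are count
  tables, not patient-level records.
- **shared pathways** — two-sided Fisher on the overlap of the two
  pathway spans within the pathway collection (universe = collection
  size).

An edge exists when any channel fires; every evaluated channel's
statistic is kept on the edge. Network summary metrics are
`avg_degree = 2|E|/n` and the mean local clustering coefficient over
all `n` nodes, with degree-0/1 nodes contributing 0 (standard
convention, required for averaging).

## PxEA

Given `D`, the full pathway collection ranked ascending by proximity
z-score to a drug's targets (ties broken by observed distance, then
pathway id), and `C ⊂ D`, the pathway set of interest (typically the
intersection of two disease spans), the running sum gains
`(|D|−|C|)/|C|` at each pathway of `C` and loses `|C|/(|D|−|C|)`
otherwise. The enrichment score is the **maximum prefix sum, floored
at 0**. The increments sum to `|D|−2|C|` over the full ranking — a
rank-invariant constant — which is precisely why the score must be the
running maximum rather than the total: only the prefix maximum is
sensitive to where `C` sits in the ranking. Consequently
`0 ≤ ES ≤ |D|−|C|`, with the upper bound attained iff `C` occupies the
top `|C|` ranks.

Significance: the ranking is shuffled uniformly (equivalently, the
positions of `C` are re-drawn uniformly among `|D|` slots; the score
depends on `D` only through those positions) and

    p = #(ES_random > ES_observed) / n_perm

with strict inequality and no pseudocount; `p = 0` is stored as 0 and
reported in text as `< 1/n_perm`. Default `n_perm = 10,000`, so the
smallest reportable nonzero p is 1e-4. In a screen, drugs with
identical usable target sets are scored once (guaranteeing identical
results), p-values are BH-adjusted across drugs, and the table is
sorted by ES descending with ties broken by drug id. Drugs with no
target in the interactome are reported unscored.

## Synthetic data and what the benchmarks show

`toy_interactome` generates connected Barabási–Albert (right-skewed
degrees, the realistic choice) or Erdős–Rényi graphs;
`plant_disease_module` grows a connected module by snowball sampling,
emulating the local coherence of disease genes. Gold-standard pathways
take a random k% of a disease's genes (size round-half-up, floor 1);
controls are uniform random node sets of matching sizes — deliberately
*not* degree-matched, since they model arbitrary annotation noise.

The **noise experiment** crosses diseases × k ∈ {10,25,50,75,90} × 10
replicates × {gold, control} × engine and records the proximity z of
each pathway (source) to the disease genes (target); two diseases give
exactly 100 gold pathways per engine. Because gold pathways are subsets
of the disease genes, their observed distance is exactly 0 and the z
becomes more negative as k grows (larger sets shrink the null σ),
reproducing the qualitative robustness pattern: gold pathways stay
significant (z ≤ −2) at every noise level while controls hover near 0.
Desk scale: a 500-node BA graph, modules of 25 genes, 200 null
realizations.

The **planted-drug screen** builds 20 pathways of 8 genes on a 300-node
BA graph: five pathways of interest each contain two of the planted
drug's five targets (emulating a shared disease-pathology core the drug
hits), the rest are uniform random, as are ten decoy drugs' target
sets. The planted drug ranks first by ES with an adjusted p below every
decoy across seeds. An earlier design using snowball modules as the
pathways of interest fails informatively: such modules are hub-rich,
and with coarse degree bins every drug looks proximal to them — the
benchmark therefore also documents why degree-bin resolution matters.

What these synthetic benchmarks do **not** show: real interactomes are
an order of magnitude larger, noisier and biased by study effort; real
pathway annotations overlap heavily and are degree-biased; drug target
lists are sparse and incomplete. Passing them demonstrates correctness
of the statistics and the expected qualitative behaviour of the method,
not performance on any particular biological corpus.

## Numerical choices and problem sizes

- Null realizations default to 1000; desk-scale runs in the test suite
  and the reproduction script use 100–200, which is ample for |z| ≫ 2
  decisions and keeps the full suite around a minute.
- Permutations default to 10,000; the synthetic screen uses 2000.
- Deterministic iteration order (lexicographic node/pathway ids)
  everywhere a choice could leak RNG state; per-pathway and per-drug
  seeds are spawned from a single seed sequence, so results are
  bit-reproducible under a fixed seed and independent of collection
  order.
- Monte-Carlo agreement tests use 3 standard-error tolerances against
  exhaustive enumeration.

## Known limitations

- Only the closest-distance and RWR proximity variants are implemented
  (no centre/separation/kernel measures).
- Gene identifiers are opaque case-sensitive strings; no id mapping.
- The comorbidity channel consumes pre-aggregated count tables; raw
  claims processing and ICD→MeSH mapping are out of scope.
- ES is the maximum prefix sum; alternatives (maximum absolute
  deviation, terminal sum) exist in the GSEA family but the terminal
  sum is rank-invariant here and the absolute deviation rewards
  *avoidance* of `C`, which is not the screening question.
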