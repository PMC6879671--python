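# Methods

This note records the models, parameter choices and numerical decisions
behind `coexdriver`, and what the synthetic benchmarks do and do not show.

## Pipeline model and assumptions

The pipeline assumes a two-condition design with independent samples, a
log2-scale expression matrix in which group mean differences are
meaningful, and an undirected, unweighted interaction graph whose edges
are symmetric by nature.  Stages run strictly in order (differential
expression → interaction map → centrality → regulator-allied subnetwork →
correlation maps → differential co-expression → semantic similarity →
drivers → enrichment → GWAS overlap) and every stage is a pure function of
its inputs plus the configuration, so reruns are byte-identical.

### Differential expression

Welch's unequal-variance *t*-test is the default: with unbalanced designs
(e.g. 7 controls vs 16 cases) the pooled-variance assumption is fragile,
and Welch costs essentially nothing when variances happen to be equal.  A
pooled-variance variant is available (`t_test_variant: student`).  The BH
step-up adjustment is applied to the full per-gene p-vector; the selection
filter uses adjusted p by default, with `use_raw_p` exposed because
pre-adjustment filtering is a common alternative operating point.  Genes
with zero variance in both groups are flagged degenerate and assigned
t = 0, p = 1 rather than propagating NaNs.  The signed fold change is the
microarray convention 2^Δ / −2^−Δ, so its magnitude is never below 1 and a
threshold of 1.2 reads "at least 1.2-fold in either direction".  p-values
that underflow to 0 in scipy are clamped to the smallest positive float so
that the BH contract (p ∈ (0, 1]) holds.

### Centrality and the regulator-allied subnetwork

Degree and betweenness are computed on the whole cleaned interaction map,
never on a subgraph, because hub/bottleneck status is a property of the
global interactome.  Betweenness uses Brandes accumulation (via networkx)
normalized by (N−1)(N−2)/2 so values are comparable across network sizes;
disconnected pairs contribute nothing.  The hub rule mean + 2·SD uses the
sample SD (n−1); a population-SD switch exists.  Hub calls use a strict
inequality so that regular graphs — SD = 0 — have no hubs, which is the
only self-consistent reading of the rule.  Bottlenecks are the first
ceil(0.25·N) nodes by descending centrality with lexicographic
tie-breaking, extended to include every node tied with the last one in;
without tie expansion the selection would depend on sort order.  The
subnetwork is the induced subgraph on hubs ∪ bottlenecks ∪ panel; panel
genes absent from the map are reported in the manifest instead of being
silently dropped.

### Correlation and differential co-expression

Pearson r is computed per condition across that condition's samples only
(at least 3).  The co-expression threshold r ≥ 0.8 is signed: the method
targets loss of *positive* co-regulation, and |r| would conflate sign
flips with maintained coupling.  Zero-variance genes make their pairs
degenerate; these are excluded and counted, not scored 0.  The
differential filter |r_control − r_case| ≥ 0.5 is applied in both mapping
directions (control-selected pairs looked up in case, and vice versa), and
the difference is bounded by 2, attained only for perfect correlations of
opposite sign.  No correlation p-values are computed — the filters act on
magnitude alone.

### Semantic similarity

Wang's measure is implemented from the recursion: S_X(X) = 1 and
S_X(t) = max over children c of t within X's ancestor closure of
w(c→t)·S_X(c), with w(is_a) = 0.8 and w(part_of) = 0.6 — the weights
conventional for this measure; both are configurable.  Term scores combine
shared versus total S-mass and are clamped to [0, 1] to guard against
float summation-order excursions.  Gene-level scores are best-match
averages over the two annotation sets, restricted to one namespace
(molecular_function by default).  A gene with no usable annotation makes
the pair *skipped and logged*, never scored 0: absence of annotation is
missing data, not evidence of dissimilarity.  Obsolete terms are dropped
and alt_ids resolved at OBO load; annotation evidence codes are not
filtered (a hook exists).

### Driver genes

"Connected directly or indirectly" is bounded at path length 2 within the
filtered pair graph.  Unbounded connectivity would make almost any two
genes in the same component "connected" and the call vacuous; one
intermediate is the shortest nontrivial indirect link.  The bound is
configurable (`path_bound`).  Both condition graphs are built by the same
filter chain (correlation ≥ 0.8 in that condition, |Δr| ≥ 0.5 against the
other, semantic score ≥ 0.5), restricted to pairs touching the panel — a
restriction that preserves all ≤2-edge paths between panel genes, since
every edge on such a path has a panel endpoint.  Note one consequence: a
pair stably co-expressed in both conditions is excluded from both graphs
by the Δr filter, so "lost connectivity" is always judged against the
*differential* structure.

### Enrichment and GWAS overlap

Over-representation is the upper-tail hypergeometric test with the
expression matrix's gene universe as background (the natural default when
the true assay background is unknown), gene sets intersected with the
universe, sets below 2 effective members excluded, BH across the tested
sets within one collection, and both p ≤ 0.01 and FDR < 0.05 enforced.
The GWAS join keeps association rows for driver genes at p ≤ 0.01 grouped
by trait, and lists drivers with no catalog rows explicitly.

## Synthetic data

`generate_expression` uses a one-factor Gaussian model: module member
values are baseline + a·z_s + ε with z_s ~ N(0,1) shared per sample and
ε ~ N(0, noise_sd²).  Two members of one module then have population
correlation a²/(a² + noise_sd²) in closed form, which is what makes a hard
correlation threshold analyzable.  Defaults: baseline N(7, 0.5) log2
units (typical microarray intensity), noise_sd 0.3, loading 0.9.
`generate_ppi` grows a preferential-attachment graph (scale-free degree
distribution) and wires planted hubs to extra uniform-random partners.
`generate_go_dag` builds a single-root random DAG in which every non-root
term picks 1–3 earlier parents, guaranteeing acyclicity and root
reachability.

The benchmark scenario (`disruption_scenario`) plants one seed/nkpf module
active in control only (the ground-truth "lost" connectivity), one
seed/nkpf module active in both conditions (a negative control), mean
shifts of 1.5 log2 units on all panel and module genes — in the range
reported for such regulator panels (linear fold changes up to ±3), and
necessary because the shared module factor inflates the sampling noise of
group means — plus extra shifted genes, a 120-gene interactome with four
planted hubs, and a 40-term ontology in which module partners share a
dedicated term.  At the benchmark operating point (loading 0.95, noise
0.2) the within-module correlation is ≈ 0.96, comfortably above the 0.8
threshold at 20–40 samples per condition; the recovery benchmark uses 40
samples per condition so that the case-side correlation of a lost pair
(mean 0, SE ≈ 0.16) rarely drifts above the Δr margin by chance.

What the generator does **not** emulate: probe-level intensities, batch
and array artifacts, heavy-tailed or heteroscedastic noise, correlated
null genes, annotation noise, and literature-biased interaction coverage.
Passing the recovery benchmarks therefore demonstrates that the
implementation detects the structure its filters are defined on, not that
the thresholds are optimal for any particular real dataset.

## Problem sizes and tolerances

Oracle comparisons use sizes where brute force is exact and fast: 200
random graphs of ≤ 25 nodes for betweenness (agreement to 1e-9), 1,000
random p-vectors of length ≤ 50 for BH (1e-12), random DAGs of ≤ 30 terms
for S-values (1e-12), and exhaustive draw enumeration up to a 12-gene
universe for the hypergeometric tail.  Recovery benchmarks use 10
replicates of a 300-gene 10+10 design for differential expression
(mean sensitivity ≥ 0.9, mean FDR ≤ 0.1 at a 1-log2 shift) and 20
replicates of the disruption scenario for driver calling (≥ 95% of
replicates recover the planted pair).  Floating-point guards: correlations
clipped to [−1, 1], semantic scores clamped to [0, 1], underflowed
p-values raised to the smallest positive float.

## Known limitations

The correlation stage stores all pairwise values in a dictionary, which is
comfortable for subnetwork-scale inputs (10⁵–10⁶ pairs) but not for
whole-transcriptome all-pairs analysis.  The driver rule judges
connectivity only through the differential pair graph, so regulator pairs
whose coupling degrades gradually (|Δr| < 0.5) are invisible by design.
Hub/bottleneck thresholds inherit the arbitrariness of their published
operating points (2 SD; top 25%); both are configurable but no
data-driven calibration is attempted.
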