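# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `hubprior`, and what the synthetic study conditions do
and do not establish about real data.

## Differential expression (diffexpr)

The per-gene score is a regularized two-sample t statistic
`d = (x̄_D − x̄_C)/(se + s₀)` with `se` the pooled two-sample standard
error. The exchangeability fudge constant `s₀` damps the scores of
low-variance genes; `s₀ = "auto"` (default) sets it to the median of the
pooled standard errors, a simple and stable stand-in for a full percentile
search, and a fixed numeric value can be configured instead. The test is
unpaired even when disease and control samples originate from the same
subjects — a deliberate convention of this pipeline's study design.

q-values come from a label-permutation null. For each candidate threshold c
(the observed |d| values), `FDR(c) = median_b #{|d*_b| ≥ c} / #{|d| ≥ c}`,
clipped to [0, 1]; a gene's q is the minimum FDR over the rejection regions
containing it, which is automatically monotone non-increasing in |d|. When
the requested permutation count reaches the number of distinct label
assignments, the null is enumerated exactly. Degenerate genes (zero pooled
variance and zero mean difference) get d = 0.

The default selection threshold is q ≤ 0.98 with direction "positive" —
an extremely permissive filter that retains most up-trending genes. It is
kept as the pipeline's standard condition (the point of the DE stage here
is to seed the network, not to control error), but both the threshold and
the direction are configurable, and the permissiveness is worth
re-examining for any real analysis.

## Network topology (network_topology)

The disease network is the induced subgraph of the interaction network on
the DE genes (both endpoints must be DE), isolated nodes removed. Degree
hubs are nodes with degree strictly greater than `AVG + 2·Std`, with Std
the sample (n−1) standard deviation; strictness makes regular graphs
degenerate cleanly to zero hubs. Betweenness is normalized by
(N−1)(N−2)/2; disconnected pairs contribute no paths. "Top 50%" for
bottlenecks is taken over the *positive* betweenness values (≥ the median
of the nonzero mass, ties kept); including the zero mass would spuriously
label about half of all leaves as bottlenecks. Bottleneck and degree-hub
flags are combined by union.

## Differential co-expression (network_variation)

`AvgPCC = Σ(Dᵢ − Cᵢ)/n` over a hub's usable interactors, where usable
means non-constant expression in both groups under the observed labelling;
constant profiles are dropped from n rather than assigned a correlation of
zero, and hubs with no usable interactor are excluded with a recorded
reason. |AvgPCC| ≤ 2 by construction.

The permutation null reassigns sample labels (group sizes preserved,
topology untouched). The default p-value is two-sided,
`p = #{|RandomPCC| ≥ |AvgPCC|}/B`: the printed one-sided form
`#{AvgPCC ≥ RandomPCC}/B` approaches 1 rather than 0 for strongly negative
effects and is available verbatim as `sidedness="paper_literal"` for
comparison. No pseudo-count is added by default (p = 0 is possible); a
smoothed `(1+b)/(1+B)` estimator is available. Bonferroni uses the number
of hubs actually tested. With B = 500, the discreteness of p contributes a
Kolmogorov–Smirnov distance of order 1/B against U(0,1), well inside the
calibration tolerance used in the tests.

## Wang semantic similarity (semantic_similarity)

S-values follow the standard recursion: `S_A(A) = 1`, and walking rootward
`S_A(t) = max_c w_rel · S_A(c)` over children c of t on paths toward A,
with contribution weights `w_is_a = 0.8`, `w_part_of = 0.6` (the measure's
conventional defaults; configurable). The recursion is evaluated in
topological order over the ancestor closure and equals the maximum over
paths of the product of edge weights (property-tested against an explicit
path-enumeration oracle). Terms with disjoint ancestor closures get
similarity 0 with a warning.

Gene similarity defaults to the mean of S_GO over the full cross product
of the two term sets (`all_pairs_avg`); best-match averaging
(`best_match_avg`) is implemented as an alternative, since the two
conventions genuinely differ and published analyses have used either.
Hub selection takes the *median* similarity between a hub and its annotated
interactors (median of an even count = mean of the two central values) with
a strict > 0.5 cutoff; unannotated interactors are skipped and hubs with no
annotated interactor are excluded, not failed.

One plausible-sounding monotonicity property is *not* true of this
measure and is deliberately not asserted in general: annotating two genes
with a shared ancestor term can lower their all-pairs-average similarity
when the base terms are more similar to each other than to that ancestor
(e.g. child/parent terms in a w = 0.8 chain: 0.764 drops to 0.721 after
adding the root to both sets), because the added cross-pairs dilute the
mean. The property holds — and is tested — for weakly related base terms
such as siblings.

## Prioritization and evaluation (prioritization)

The prioritized list is the union of the Step-1 and Step-2 selections with
provenance flags, ordered "both" first, then decreasing |AvgPCC|, then gene
id. Reference overlap is a plain intersection reported with both set
sizes. The tissue filter passes a gene if, in at least one target tissue
(defaults: "whole brain", "prefrontal cortex"), expression is ≥ 1.5× the
gene's median across all tissues — a scale-invariant, per-gene criterion;
housekeeping genes are reported separately and never counted as
tissue-specific (whether they should be excluded or merely compared is
ambiguous in the pipeline's provenance, so the filter makes the choice
explicit and visible). Enrichment is an in-repo one-sided hypergeometric
test per GO term with annotations propagated to ancestors and
Benjamini–Hochberg correction — a reproducible, offline replacement for
web-service enrichment tools; its term counts are not expected to match
any external service.

## Classification (classification)

`CoeDiff(G, s) = Σᵢ |x(Imᵢ, s) − x(G, s)|` per sample and hub (the
sign-preserving sum is available as an option). The absolute form is
invariant under a joint shift of hub and interactors, so the feature
carries co-expression structure rather than raw expression level.
Evaluation is leave-one-out: each fold trains a fresh 100-tree random
forest (fixed seed, so reports are reproducible) and records the held-out
sample's disease-vote fraction — a continuous per-fold score is required
to sweep a ROC over single-sample folds. AUC equals the Mann–Whitney
probability with ties counted half. Features are not standardized (tree
ensembles are scale-invariant). Note that LOOCV with permuted labels is
mildly pessimistic (the held-out class is underrepresented in training),
so chance-level means sit slightly below 0.5.

## Synthetic study conditions (synthetic)

The generator emulates the statistical structure the pipeline detects,
with one seed fixing every output byte-for-byte:

- **Network**: preferential attachment (m = 2) over 300 genes. Planted
  hubs are chosen greedily in degree-descending order subject to pairwise
  *disjoint closed neighbourhoods*, then wired to additional unclaimed
  nodes up to a minimum degree of 12. Disjointness is what makes the
  planted signal clean — shared interactors or hub–hub edges would dilute
  AvgPCC of later hubs well below the planted effect — and the top-up keeps
  every planted hub detectable by the degree/betweenness rules.
- **Expression**: 20+20 samples. Interactors of a planted hub are
  `r·hub + √(1−r²)·noise` with r = 0.8 in control and 0.0 in disease
  columns (linear mixing gives the exact target population correlation),
  so the expected AvgPCC is ≈ −0.8 under the D−C convention. A +1.0 mean
  shift on planted hubs *and* their interactors in disease samples makes
  the planted neighbourhoods positively differentially expressed — so the
  permissive positive-direction DE selection retains them — while leaving
  CoeDiff unchanged (hub and interactors shift together); the
  classification signal therefore comes from the decorrelation itself.
  A +8 offset mimics log-scale positivity.
- **Ontology**: a depth-3, branching-3 tree (40 terms) plus ~10% extra
  is_a edges pointing strictly rootward (acyclicity by construction); 85%
  of tree edges are is_a, the rest part_of. Each planted neighbourhood is
  annotated within one depth-2 subtree; the hub itself always coherently,
  interactors with probability 0.9; background genes draw 2 terms
  uniformly. Within-subtree term pairs then score ≈ 0.66–1.0 and
  cross-subtree pairs ≈ 0.17–0.39, separating the median-similarity rule's
  inputs around the 0.5 cutoff.
- **Tissue and lists**: 10 tissues including the two brain targets;
  planted genes are raised to 4× their cross-tissue median in both brain
  tissues; 30 housekeeping genes are uniformly high (max/median < 1.5);
  the reference set is half the planted hubs plus 20 decoys.

Dedicated evaluation fixtures: a 200-hub null (disjoint stars over i.i.d.
noise) for p-value calibration, and a 30-hub star fixture with fully
coherent annotation for 10 planted hubs for the similarity-selection
check.

What the synthetic conditions do **not** emulate: microarray probe-level
noise and normalization artifacts, the actual GO topology (tens of
thousands of terms, deep multi-parent paths), realistic PPIN false
positive/negative structure, correlated background co-expression, or
batch effects. Passing tests therefore demonstrate that the estimators are
implemented correctly and recover cleanly planted structure at realistic
sample sizes — not that the pipeline's selections would be biologically
correct on any particular real dataset.

## Problem sizes and numerical conventions

Standard conditions: 300 genes, 20+20 samples, 6 planted hubs, 200 label
permutations for the co-expression null (100 for the DE FDR), 100 trees,
chosen so a full end-to-end run completes in a few seconds and the whole
validation suite in a couple of minutes on one CPU. Larger networks and
permutation counts scale linearly. One global seed derives fixed per-stage
seeds (offsets 11/22/33) so stages are independently reproducible; run
reports contain no timestamps and hash identically across repeated runs.
Ties: quantile thresholds keep exact ties (≥); the degree cutoff is
strict (>); the similarity cutoff is strict (>). Pearson correlations with
a zero-variance profile in a permuted group are dropped from that
permutation's average rather than imputed.

## Known limitations

- The permissive q ≤ 0.98 DE gate means the "disease network" is close to
  the full network restricted to up-trending genes; results are sensitive
  to this choice and it should be tightened for confirmatory analyses.
- Eq-style one-sided p-values (`paper_literal`) are provided for
  comparability but are misleading for negative effects; the two-sided
  default is recommended.
- The enrichment stage on the standard synthetic conditions typically
  finds no BH-significant terms: the prioritized list spreads over six
  different annotation subtrees, so no single term is over-represented —
  an honest property of the fixture, not a defect of the test.
- GAF parsing keeps the DB Object ID column and ignores evidence codes;
  real analyses may want evidence-code filtering.
- LOOCV AUC on 40 samples has high variance; the reported AUC should be
  read with the permuted-label baseline alongside.
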