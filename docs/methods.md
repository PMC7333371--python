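# Methods

This note records the models behind each senonet stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that pin down boundary behavior.

## Network construction

**Correlation networks.** Pearson correlations are computed across samples;
genes with zero sample variance are excluded outright (their correlation is
undefined and they must not seed edges). The edge rule is `r ≥ t` on the
*signed* correlation by default — co-expression resources rank positive
co-expression — with an absolute-value mode (`absolute=True`) for analyses
that treat strong anticorrelation as connectivity.

**Threshold selection.** For each threshold on a strictly increasing grid
(default 0.00–0.99, step 0.01) we record edges, nodes incident to at least
one kept edge, and density `E / (N(N−1)/2)`. Counting only edge-incident
nodes is what makes the node/edge trade-off produce an interior minimum:
raising the threshold removes edges but also drops isolated genes.
Thresholds keeping zero edges have undefined density and are excluded from
selection. The minimum-density threshold is selected; ties break toward the
*lowest* threshold, which keeps the most catalog genes in the network at the
same density. On the planted two-module fixture this lands strictly between
the background and module correlations, and only within-module edges
survive — note this guarantee needs a module-only fixture: free-floating
noise genes attach by sparse spurious edges that *lower* density, an
inherent property of the density criterion rather than an implementation
artifact.

**Seed subnetworks.** Both network classes use the same first-order rule:
nodes are the seeds plus their direct partners; edges are *all* input edges
with both endpoints included (partner–partner edges kept,
partners-of-partners excluded); self-loops and duplicate edges are removed
first. The rule is idempotent. Gene identifiers compare case-sensitively
after whitespace trimming; alias and orthologue mapping are out of scope.

## Topology and candidate ranking

Betweenness is pair-normalized within each connected component (a node's
score is the fraction of its component's shortest paths crossing it);
closeness is the reciprocal of the mean shortest-path distance to
*reachable* nodes, so higher always means more central — the literature
sometimes inverts the sign convention, and we standardize on
reciprocal-of-mean so "top CC" means largest. Cross-component distances are
treated as unreachable rather than infinite. Local clustering is the
realized fraction of neighbor–neighbor edges, defined 0 below degree 2.

**Increased connectivity (IC).** For node `v` with `k` neighbors, `x` of
them seeds, IC is the one-sided hypergeometric upper tail `P(X ≥ x)` when
`k` nodes are drawn from the `N − 1` other nodes of `v`'s component, of
which `K` are seeds (excluding `v` itself when `v` is a seed). The
component, not the whole graph, is the sampling universe — a node cannot
draw neighbors outside its component. BH adjustment runs across all nodes
of the network in one family; significance is called at adjusted p < 0.05.
The implementation is verified against exhaustive neighbor-subset
enumeration on small graphs.

**Candidate rule.** A node qualifies by membership in the top tier (default
1%) of ≥ 2 of degree/BC/CC, or by significant adjusted IC plus one
second-tier (default 5%) membership. Top-tier sets take the `ceil(q% · N)`
largest values with ties at the cut included. Seeds are flagged but kept
unless `novel_only` — the interesting candidates are usually the non-seed
ones. Output orders by number of qualifying criteria, then BC descending,
then label.

**Power-law fit.** Least squares on (log degree, log frequency) over
degrees ≥ 1 with nonzero frequency, reporting slope, `exp(intercept)`, the
log-log Pearson correlation and R². This is the network-analyzer convention
and is deliberately *not* a maximum-likelihood tail fit; it exists for
comparability of slope/R² reporting, not as a rigorous scale-free test.

**Module detection.** Agglomeration ordered by edge clustering value,
`ECV(u,v) = |N(u)∩N(v)|² / (|N(u)\{v}| · |N(v)\{u}|)` (0 when a denominator
term vanishes), ties broken lexicographically. An edge extends a cluster
freely while an endpoint is unassigned; merging two existing clusters
requires the merged cluster to keep total internal degree
`> (λ/2) ×` total external degree (λ = 2 gives the weak-community rule).
Edges with ECV = 0 never trigger a merge: a bridge whose endpoints share no
neighbor carries no cohesion evidence, and without this rule any
connected graph would eventually merge into one cluster (the whole graph
trivially satisfies the weak condition). Clusters below `min_size_fraction
× N` (default 1%) are discarded to the unassigned set.

## Overlap statistics

Fisher's exact test on the 2×2 overlap table; `direction` compares the
observed overlap to its expectation `ab/N`. The sample odds ratio uses the
convention ∞ for a zero denominator cell and 0 for an empty first set
(p = 1). One-sided "greater" is the default for enrichment claims;
two-sided is available where a symmetric question is asked. The background
universe is always caller-supplied — printed p-values in the literature
routinely depend on unstated backgrounds, so no default genome size is
baked in. BH families are per analysis table (one correction across a heat
matrix's cells). Heat values are `−log2(p_enriched)` above expectation,
`+log2(p_depleted)` below, 0 at exact expectation; cells with an empty
tissue set are undefined rather than 0. The rank-sum shift test uses the
exact null below combined n = 20 without ties, otherwise the normal
approximation with continuity correction.

The dual-direction adjustment addresses genes differentially expressed in
both directions across tissues: pooled directional lists would double-count
them, so each such gene stays in both lists and the universe grows by one
per gene.

## Tissue-scrambling permutation null

Scrambling permutes each tissue's (adjusted p, effect) *pairs* across that
tissue's genes — pairs are never split, tissues are independent — so every
per-tissue significant-set size is preserved exactly and a catalog gene is
significant-up in tissue `t` with probability `m_t / G_t`. Input p-values
are taken as already multiple-testing adjusted per tissue (the null
scrambles published adjusted results; it does not recompute tests). Effects
are stored on the 50-year scale; per-year inputs must be rescaled upstream.
The significance filter is `p < 0.05` and `|effect| > log2(1.5) ≈ 0.585`,
both strict.

`P(count > k)` is estimated as the fraction of (simulation × gene)
observations exceeding `k`, pooled across the catalog genes'
tissue-presence patterns (a gene absent from a tissue contributes
probability 0 there); an alternative max-over-genes statistic per
simulation would control a family-wise error instead and is not
implemented. `k*` is the smallest `k` with `P(count > k) < 0.05`;
multi-tissue calls use the strict inequality `n > k*`. The default is
10,000 simulations with a mandatory seed; the analytic Poisson-binomial
tail (dynamic programming over tissues) serves as an independent oracle,
and tests require agreement within 3 Monte-Carlo standard errors at 2,000
simulations, computed with the simulation (not the pooled observation) as
the unit since observations within one scramble share the permutation.

## Conservation and phylogenetic diversity

The two-proportion z-test uses the pooled proportion and a two-tailed
normal p; BH correction across species is applied by the caller. Faith's
PD sums the branch lengths spanning the sampled tips; `include_root`
(default on, matching the R phylodiversity ecosystem) adds the MRCA-to-root
path, which materially changes single-tip PD (root-path length vs 0). The
expected PD under binomial tip sampling is the closed form
`Σ_b L_b (1 − (1−p)^{n_b})` in the root-inclusive convention; no
conditioning on a non-empty sample is applied (an empty draw contributes
PD 0), so the Monte-Carlo oracle must count empty draws as 0. The sampling
probability `p` is an explicit parameter. Polytomies are accepted;
zero-length branches contribute 0. Branch sums iterate in tree preorder so
repeated runs are bitwise identical.

## Screen scoring

Z-scores are per experiment and marker, referenced to the negative-control
(cyclophilin B) wells: `(target well-mean − control well-mean) / control
well-SD`, with the sample SD (ddof = 1). Reported Z is the unweighted mean
across experiments — replicate-count weighting is not described in the
screening convention we follow, and unweighted means are the conservative
default. Positive-control wells are carried through but never enter the
reference. A zero control SD aborts with the experiment and marker named.

Direction conventions: senescence decreases cell number and Ki67 index and
increases cell area, nuclear area, p16, p21, IL-6 and SA-β-gal. The Ki67
flag is strict (`Z < −1`, a decrease *greater than* one Z); all other
markers are inclusive at the boundary (`|Z| ≥ 1` in the senescence
direction) — the boundary had to be pinned somewhere and this split is
configurable (`strict=`). "Altered at least one morphological measure"
means a senescence-direction *increase* in cell or nuclear area; an
`either_direction` mode relaxes every flag to `|Z| ≥ 1`. Top hit = Ki67
flag AND cell-number flag AND a morphology flag. Summary percentages round
half-up to one decimal; published tables occasionally truncate instead
(21/26 printed as 80.7), and such values are reported here as computed
(80.8).

## Synthetic data: what it emulates and what it does not

- `gen_expression` — genes in a module share a standard-normal latent
  factor with loading `sqrt(r)`, giving expected pairwise correlation
  exactly `r`. It emulates co-expression *structure*, not RNA-seq
  marginals: values are Gaussian, there is no count noise, library-size or
  batch effect, and cross-module correlations concentrate around the
  (random) factor–factor sample correlation rather than spreading
  independently.
- `gen_scalefree_graph` — preferential attachment from an `m`-clique, so
  the edge count is exactly `C(m,2) + m(n−m)`. Degree distributions are
  heavy-tailed but the graph lacks the protein-complex cliquishness of real
  interactomes. The planted high-IC node attaches to 75% (ceiling) of the
  seeds and is non-seed, because candidate discovery must surface non-seed
  nodes.
- `gen_deg_tables` — per tissue, exact numbers of significant-up/-down
  genes; planted genes occupy significant slots exactly where stated and
  are excluded from random fill elsewhere, so their tissue counts are by
  construction. Non-significant p-values are uniform on (0.05, 1]; the
  generator writes already-adjusted p-values because the downstream null
  scrambles adjusted results.
- `gen_screen` — Gaussian wells around per-marker control means; designed
  hits shift by `shift × SD` in the senescence direction. No plate-position
  effects, no segmentation noise, no dose–response.
- `gen_tree` — pure-birth (Yule) process with unit birth rate: exponential
  waiting times with rate equal to the number of extant lineages, uniform
  choice of the splitting lineage; ultrametric with strictly positive
  lengths.

Passing tests on these fixtures show the *machinery* is correct (filters,
counts, tails, recovery of planted signal at stated effect sizes); they say
nothing about robustness to the noise structure of real expression,
interaction or imaging data.

## Problem sizes and test budgets

The default demonstration pipeline and the reproduction script use sizes
chosen to make every stage's statistical behavior visible while completing
in seconds to minutes on one CPU: 10-tissue panels of a few hundred genes
with 2,000 scrambles, 150–400-node graphs over 20 seeds, 20-tip trees with
10,000 Monte-Carlo draws, and screen plates of 26 targets with 3
experiments. The exhaustive oracles sweep all overlap instances up to
universe 10 (with randomized checks to 20) and all labeled 4-node graphs
for IC (randomized to 8 nodes). The full-scale analyses the machinery is
built for (thousands of network nodes, 10,000 scrambles) run with the same
code paths by raising the corresponding parameters.

## Known limitations

- The ECV agglomeration is a fully specified stand-in for hierarchical
  PIN-clustering tools whose internals are not published alongside their
  parameters; it reproduces clique/bridge behavior but is not a reimplementation
  of any specific tool.
- The density-minimizing threshold is sensitive to free-floating noise
  genes (see above); with realistic noise the selected threshold sits where
  a few spurious edges survive, which is faithful to the criterion, not a
  bug.
- Wilcoxon exact p-values are unavailable with ties (the normal
  approximation is used).
- The IC statistic conditions on the observed degree; it does not model
  degree-correlated seed placement.
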