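# Methods

## Scope and inputs

`pathwaylens` starts where upstream annotation ends: each sample is a set of
KEGG ortholog groups (KO) or EC numbers with RNA-Seq evidence, and pathways
are sets of such groups (from a two-column TSV or derived from KGML files).
KO and EC identifiers are accepted side by side but never translated into
one another — translation needs an external database and is out of scope, as
are assembly, BLAST annotation and any KEGG network access.

## The uniform binary activity model

Assumptions: (*uniformity*) a molecule from an ortholog group participates
in each active pathway containing the group with equal probability;
(*binary activity*) a pathway is active exactly when its activity level
reaches a threshold.  Participation is
`g_w = 1/(1 + Σ_{w'∋g, w'≠w} δ(w'))`; note that the pathway's own status
never gates its own level — the sum runs over *other* pathways and the
constant 1 stays even when δ(w)=0.  The level is `f_w = Σ_{g∈w} g_w` and
`δ(w) = 1 iff f_w ≥ T_w` (equality counts as active).

The iteration starts all-active and alternates level and status updates.
The status vector lives in {0,1}^|W|, so the trajectory must revisit a state
within 2^|W| steps; detection is by exact hash of the status vector with its
first-occurrence index, which finds any period, not just the common k=2.
Reported levels are the arithmetic mean of f over one terminal cycle — the
only definition that is well-posed for oscillating trajectories (a fixed
point is a period-1 cycle).  `max_iter` (default 1000) is a safety valve;
hitting it raises an error carrying the partial trace.

**Threshold.** No canonical T_w exists; the default global T_w = 1.0 demands
one full ortholog-group-equivalent of participation.  Rather than privilege
a value, the suite checks the property that matters: rankings of cycle-mean
levels are stable under a two-fold threshold change (Spearman ρ > 0.8 on
synthetic families).

**Which membership enters the model.** The EM branch runs on pathways
restricted to sample-expressed groups, with a configurable minimum of 1
expressed group; the graph branch excludes pathways with fewer than 3 mapped
ortholog groups, which carry too little signal for topology statistics.
Both cutoffs are CLI flags.

## Pathway graphs from KGML

One node per `<entry>` of type `ortholog`, `gene` or `enzyme`; labels are
the space-separated identifiers of the `name` attribute with `ko:`/`ec:`
prefixes stripped.  One directed edge per `<relation>`.  `map` entries never
become nodes; `compound` entries are collapsed (every enzyme feeding a
compound is connected to every enzyme the compound feeds) and removed, so
the graph is a network of enzymes.  Parallel edges and self-loops are
dropped at parse time: the density and degree statistics below would
otherwise depend on multigraph conventions that nothing downstream defines.

## Induced-subgraph metrics

On the subgraph induced by mapped nodes (both endpoints mapped):

* `density = |E|/(|V|−1)`, defined as 0 when |V| ≤ 1 (such pathways are
  excluded by the ≥3 filter anyway);
* `x = (#out-degree-0 + #in-degree-0)/(2|V|)`, defined as 0 on the empty
  graph.  Each node contributes at most two of the 2|V| terms, so x ∈ [0,1];
  reading the normalization as division by 2|V| is what makes small worked
  values like 2/18 ≈ 0.11 come out on a 9-node, single-source single-sink
  subgraph.
* Components are **weakly** connected: KEGG maps are largely linear
  cascades, where weak connectivity matches visual connectedness.  The
  largest-component node and edge counts are independent maxima.

## Null models and the empirical p-value

*Vertex label swapping* fixes the topology and exchanges the mapped flag
(with its KO/EC labels) between two nodes whose flags differ; the mapped
count is conserved.  *Edge swapping* fixes the labelling and rewires
(a→b, c→d) into (a→d, c→b), rejecting swaps that would create a self-loop
or duplicate edge, so every node's in- and out-degree is invariant.  Swap
counts are **attempted** swaps: ineligible draws are counted but have no
effect, which guarantees termination on rigid graphs; at the default of 10^6
attempts the difference from accepted-swap counting is irrelevant for
mixing.  The full annotated graph is permuted and the induced subgraph
re-derived per ensemble member.

An ensemble holds m (default 200) pairwise-distinct members — distinct
mapped-node assignments for the vertex model, distinct edge sets for the
edge model.  A slot that cannot find a fresh state within `max_retries`
(default 100) attempts raises an error advising a smaller m; silently
duplicating nulls would bias the rank.  The observed record is ranked in the
ensemble by (density descending, x ascending) and **placed after any
equal-keyed null member** — a conservative tie rule that can only inflate p.
`p = rank/m`, clipped to 1 when the observed graph ranks below all m
members.  Significance classes: p ≤ 0.5% most significant, p < 1% very
significant, p < 5% significant.  No multiple-testing correction is applied
across pathways on either branch; this mirrors the method's design and is a
deliberate non-addition.

## Differential analysis

Activity: ratio of cycle-mean levels, `up` at ≥ 1.5, `down` at ≤ 0.66, with
a zero denominator reported as `undefined` (levels preserved; no pseudocount
— zeros are informative).  Significance: `probDiff = (1−p_small)·p_large`,
symmetric, in [0,1), maximal when one sample is strongly significant and the
other is not; strictly greater than 0.5 calls the pathway differentially
significant.  Report output is rounded to two decimals; full precision is
kept internally.  Pathways present in only one input are kept in the outer
join with an explicit one-sided marker.

## Synthetic fixtures

The generators emulate the structural conditions the methods rely on:
directed simple graphs at the realistic minimum pathway size (15 nodes, 40
edges by default), pathway families whose members are drawn partly from a
shared pool (default overlap fraction 0.3, so pathways genuinely compete
for groups), a binary mapped labelling (default mapped fraction 0.5), and
planted-active pathways whose members are fully expressed over a background
expression rate (default 10% of remaining groups — non-degenerate but
separable).  They do not simulate reaction semantics, read-level noise,
KEGG's actual map topologies, or annotation error, so passing tests
demonstrate correctness of the inference machinery on structured inputs,
not biological validity on real data.  All generators are seed-driven and
bit-for-bit reproducible.

## Problem sizes in the test suite

Unit and property tests run at small sizes (families of ≤ 8 pathways for
hypothesis properties, exhaustive brute-force cross-checks at ≤ 4 pathways
over ≤ 6 groups).  Ensemble-based checks run at m = 50 with 10^4 attempted
swaps per graph — enough for the walk to mix on 15-node graphs while keeping
the whole suite under a minute; the self-null uniformity check uses 60
replicates over 3 coarse rank bins (χ², α = 10⁻³), coarse because the
conservative tie rule slightly favours high ranks by construction.  The
acceptance script uses the full m = 200 with 3·10^3 attempted swaps on a
30-node graph.

## Known limitations

* The binary expression model ignores abundance; a weighted variant is a
  natural extension but only the binary model is implemented.
* Empirical p-values are bounded below by 1/m; resolution beyond 0.5%
  requires a larger ensemble.
* The KGML reader covers entry/relation structure only — no reaction
  stoichiometry and no `maplink` cross-references as edges.
* Degenerate graphs (all nodes one flag, < 2 edges) pass through the null
  models unchanged with a warning; they are normally removed by the ≥3
  mapped-groups filter before reaching them.
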