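# Methods

## Scope and data model

The package operates on three inputs: (a) KGML pathway XML (a KEGG-style
global metabolic map, or the synthetic dialect the fixture generator emits),
(b) per-strain gene tables mapping locus tag → KO → experimental essentiality
label, and (c) a KO annotation table carrying the "//"-joined KEGG pathway and
COG annotation strings, reaction identifiers (#R), gene name and description.
Annotation strings are stored verbatim at load time; no tokenization happens
until a grouping operation explicitly asks for it. Input tables enforce at
most one KO per gene (duplicate locus tags are rejected), reflecting a
best-single-hit KO assignment upstream.

## The reaction matrix and the remapping search

Each reaction becomes an undirected edge between its substrate and product
compounds; a reaction with several substrates or products expands into one
edge per substrate × product pair sharing a single reaction record, because
the matrix the search operates on is compound × compound. Reaction direction
is ignored: the traversal rule only speaks of "the node at the other end of
an edge", and metabolic-map neighborhoods, not fluxes, are what the search
measures. Parallel edges (reversible duplicates, isozyme reactions) are kept
distinct in the graph for gene-level bookkeeping and collapse by maximum
score in the matrix.

Edge scores: 5 if at least one gene on the reaction is experimentally
essential, 1 if all genes are non-essential, 0 where no reaction exists.
Locus tags missing from the label table default to non-essential with a
warning, since knockout studies label essentials exhaustively but often leave
non-essentials implicit.

The search from a start edge explores both endpoints independently. From an
endpoint, an entered edge (u, v) is traversed through iff it scores 5 or some
score-5 edge touches v; otherwise it is recorded as reached but not continued
through. The reached set is the closure of this rule, so it is independent of
visit order — the implementation expands nodes with a stack, but any order
yields the same set (the permutation tests assert this on shuffled edge
lists). An edge reached through endpoint u belongs to u's side; edges
reachable from both sides count for both, which makes "essential support on
both endpoint sides" well defined on cycles.

Decision rule: a score-1 edge is reclassified as a missing (gap) essential
gene iff both its endpoint sides reach a score-5 edge. The rescored matrix S′
(sum of original scores over each start edge's section, the start edge's own
score included so every existing edge keeps S′ ≥ 1) is computed and reported
as a diagnostic, but the both-sides criterion is the decision rule; no
numeric threshold on S′ is applied anywhere.

All sections are evaluated against the original scores in a single pass.
Reclassification feeding back into the traversal would cascade (a gap gene
relabels its other map locations essential, which would seed new searches,
potentially without a fixed point), so gene-level propagation — labeling the
other edges that carry a recovered gap gene — runs once, after the pass, and
is reported separately (`propagated_edges`). Gap genes exclude locus tags
already sitting on an originally essential edge.

Degenerate inputs: self-loop edges are kept in the graph but never enter the
matrix (diagonal stays 0); components without any score-5 edge can never
produce a gap call; an empty edge list yields an empty result.

## Scoring

E_score for a KO with tallies (eg_e, eg_m, non_eg) over N strains is
((eg_e + eg_m)/(eg_e + eg_m + non_eg + 1))² × ((eg_e + eg_m + non_eg)/N).
The +1 in the denominator shrinks scores for rarely observed KOs; the second
factor rewards broad appearance. The score is zero iff the KO was never
essential anywhere, strictly increasing in the essential count, and bounded
by (N/(N+1))² — 0.938 at N = 31, verified by brute force over all integer
tallies. Per-strain tallying classifies each KO once per strain with
precedence experimental-essential > missing-essential > non-essential when
several genes of one strain share the KO; the tie rule mirrors the edge rule
(one essential gene suffices). Unknown labels never enter tallies.

KOs without their own tally that share a reaction identifier with tallied
KOs inherit the mean E_score of their reaction partners and are flagged
`reaction_linked` in the output. Mean inheritance is the least-surprising
transfer and keeps the inherited score inside the partners' range. The
reaction expansion itself is single-hop, not a transitive closure: one
application adds only KOs directly sharing a reaction with the seed set.

P_score components group KOs by byte-identical full annotation string
(the worked examples in the literature match whole multi-pathway strings,
not tokens; per-token grouping is available behind `match="token"` for
sensitivity analysis). A KO's own E_score is excluded from its group mean,
which keeps the operation well defined even for scored KOs. The empty
annotation string forms its own group, so a KO with an empty COG cell still
receives a P_score_COG (the mean over other annotation-less KOs); only a KO
with both strings empty gets no P_score. The combined P_score is by default
the raw arithmetic mean of the two components — both already live on [0, 1],
and the published worked examples use raw values — with a min-max
standardized mode (`mode="minmax_standardized"`, rescaling each component
across all KOs before averaging) available by configuration.

Scores are stored at full precision; reports round to 3 decimals.

## Prediction and evaluation

Default thresholds are τ_E = 0.6 on E_score and τ_P = 0.03 on P_score
(both inclusive, both plain configuration values). The default combination
rule is strict E-priority: decide on E_score whenever one exists, fall back
to P_score otherwise, since the experimental score is the stronger signal
and P_score is supplementary. An `either` rule (essential when either score
clears its threshold) is available; predictions where the unused score
disagrees are flagged `conflict` for user review. Genes without a KO, or
whose KO has neither score, are `unscored` and excluded from metrics, as are
scored genes without a usable experimental label (warned). Metrics with a
zero denominator are reported absent rather than zero; report rounding is 2
decimals.

## The synthetic generator

`simulate_pathway` emulates the biology that creates gap genes: each planted
paralog pair is a score-1 edge carrying two non-essential genes, flanked on
both compound ends by score-5 edges, embedded in a connected map. The
construction (pair blocks behind two-edge score-1 buffers off a hub, a
score-1 chain, pendant essential edges spaced ≥ 4 chain positions apart,
parallel duplicates restricted to score-5 edges or to edges with no
essential-adjacent endpoint) guarantees by design that every planted gap
satisfies the both-sides criterion and every other score-1 edge violates it;
the tests re-verify this with a path-enumeration oracle that is independent
of the search implementation. Defaults — 40 compounds, 48 reactions, 25 %
essential edges, 3 paralog pairs, 31 strains — are a small but structurally
representative map; the strain panel draws per-KO presence i.i.d. Bernoulli
(default 0.8) with essential KOs always labeled essential when present.

What the generator does not emulate: real ko01100 topology (hub compounds
like pyruvate with degree in the hundreds, scale-free degree structure),
phylogenetic correlation between strains, partial essentiality or
condition-dependent labels, multi-substrate reactions (generated reactions
are 1-substrate/1-product, though the parser and graph builder handle the
general case), and annotation noise. Passing tests therefore demonstrate the
correctness of the algorithmic machinery and exact recoverability under
clean conditions, not expected field performance on real genomes; on real
data, growth-medium effects (supplemented essential compounds) and imperfect
KO assignment will lower precision well below the synthetic ceiling.

## Numerical and design choices

- Deterministic traversal order (sorted by compound id, then reaction id) is
  used for reproducible traces, but results are order-independent by
  construction and asserted so under random edge permutations.
- All randomness flows through `numpy.random.default_rng` seeded from the
  config; panel generation decouples its stream with a fixed offset.
- Problem sizes in the test and acceptance suites (4-compound exhaustive
  enumeration plus seeded multigraphs up to 8 compounds and 10 edges for
  oracle equivalence; 100 seeds for planted-gap recovery) were chosen as the
  smallest sets that exercise every branch of the traversal rule: cycles,
  parallel edges, one-sided support, bare leaves and disconnected pieces.

## Known limitations

- The remapping pass is deliberately single-pass; an iterated fixed-point
  variant is out of scope.
- Reaction expansion and E_score inheritance treat all reaction partners
  equally; no weighting by annotation quality.
- The expert-judgment layer that a curator might apply on top of P_score is
  not modeled.
- Genome-scale quantities reported for the full KEGG/DEG corpora (hundreds of
  gap genes per genome, score-distribution moments, validation-panel
  sensitivities) require those external resources and are not reproducible
  from the synthetic fixtures; the property-based suite covers the mechanism
  instead.
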