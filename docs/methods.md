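# Methods

## Model

`triadnet` treats gene–gene association evidence as an undirected
multigraph over a locus-tag gene space. Each edge carries exactly one
evidence type — co-expression (CoEx), yeast two-hybrid (Y2H) or
literature text-mining (EVEX) — and at most one edge per
(gene pair, type) may exist, so parallel edges between a pair always
differ in type. Directionality in text-mining events (regulator vs
target, polarity) is kept as edge metadata only; all graph semantics
are undirected.

### Co-expression

Input is a genes × conditions matrix of log2(treatment/control) fold
changes. Pairwise Pearson correlation uses pairwise-complete
observations: a pair's correlation is computed over the conditions both
genes observe, and is undefined (never an edge) when fewer than
`min_overlap` conditions are shared (default 3 — expression compendia
have gaps, and below three points a correlation is vacuous) or when
either profile has zero variance over the shared conditions. An edge is
admitted when |r| ≥ `threshold` (default 0.7); both correlation signs
count, and the signed r is stored on the edge. No multiple-testing
correction is applied — the method uses a hard magnitude threshold
chosen from the correlation histogram, not p-values. The histogram
helper bins every defined off-diagonal correlation once per unordered
pair over [−1, 1].

### Text-mining projection

Events connect gene families (or single genes). An event between
families A and B yields an EVEX edge for every ordered-independent pair
(a, b), a ∈ A, b ∈ B, a ≠ b; within-family self-pairs are dropped.
Events landing on the same gene pair merge into one edge:

- `article_ids`, `source_organisms`, `event_types` — set union;
- `confidence` — maximum over contributing events;
- `polarity` — taken from the highest-confidence contributing event;
- `speculation` / `negation` — true only if *every* contributing event
  carries the flag: one plain assertion outweighs a hedged or negated
  mention;
- `is_self_species` — true iff any contributing event's organism list
  includes the target taxon.

Events citing an unknown family are skipped, logged and counted in a
rejects report. Negated events are ingested and flagged rather than
discarded; exclusion is deferred to the motif filters (below).
Taxonomic distance, when a parent-pointer taxonomy table is supplied,
is the hop count to the nearest common ancestor, minimized over source
organisms; without a table the field stays empty.

### Annotation handling

A description classifies as *hypothetical* or *unknown* when it
contains that word as a token (case-insensitive — source annotations
embed the keyword in longer phrases like "hypothetical protein (FeS
assembly protein)"); an absent/empty description is *unannotated*;
anything else is *annotated*. If a description contains both keywords,
*hypothetical* wins (checked first).

Family descriptions are pooled by canonicalization: lowercase, strip
every non-alphanumeric character, pick the canonical form shared by the
most member descriptions, and report its most frequent original surface
form. Ties break deterministically: lexicographically smallest
canonical form; shortest-then-lexicographic representative. Enrichment
transfers the family description onto hypothetical/unknown/unannotated
genes only — an existing meaningful annotation is never overwritten —
and reports coverage (fraction of genes with a meaningful annotation)
before and after. Annotation comparison is three-valued: *identical*
up to case and surrounding whitespace, *substring* when one canonical
form contains the other, else *other*.

### Integration

Merging ≥ 2 networks unions nodes and (pair, type) edge keys. Node
attributes merge first-non-empty in input order; conflicting non-empty
values keep the earlier network's value and are logged — the input
order rule exists purely to make merges deterministic. An optional id
map translates foreign identifiers (e.g. Entrez) into the locus-tag
space before the union; unmapped ids are reported and, under strict
mode, dropped. Circular-evidence exclusion is declarative: given a
list of tainted article ids (typically the publication behind an
experimental input network), every EVEX edge supported *only* by
tainted articles is removed, edges with at least one independent
article survive with the tainted ids stripped, and CoEx/Y2H edges are
never touched. Nodes isolated by edge removal are retained.

### Motif filters and ranking

Triangle enumeration anchors at a gene list and emits, for every node
triple containing an anchor whose three pairs are each connected, one
motif per combination of parallel-edge choices, in canonical sorted
order.

The candidate-gene filter keeps a motif iff its three chosen edges span
≥ 2 distinct evidence types (EVEX/CoEx/Y2H; self- vs foreign-species is
a rank attribute, not a type) and no key–candidate pair inside the
motif is joined by a self-species EVEX edge *anywhere in the network* —
not merely among the chosen edges. The stricter global reading matches
the rule's purpose (the association is already known for the target
organism, whichever edge the motif happened to pick). The negation
flag is handled asymmetrically: negated EVEX edges may not serve as
motif sides (they assert the absence of an association) unless
`allow_negated` is set, but a negated self-species edge still triggers
the known-pair disqualification, which reads the rule literally and
conservatively. Motifs whose three members are all key genes nominate
no candidate and are dropped; both non-key members of an accepted motif
are reported as candidates.

Ranking is lexicographic because the source rules are stated in
priority order without a combining formula: first the sorted per-edge
rank profile (self-species EVEX 1, foreign EVEX 2, CoEx 3, Y2H 4;
elementwise, smaller better), then larger-better counts of (j) key
genes outside the motif adjacent to the candidate, (jj) two-step paths
(intermediate node outside the motif) from candidate to any key gene,
and (jjj) edges among the motif's nodes beyond the three chosen. When
a motif has two candidate members, each count is evaluated per
candidate and the maximum kept — a motif is ranked by its strongest
candidate. Remaining ties break on the sorted node triple, so output
order is fully deterministic.

The hypothetical-protein filter swaps roles: anchors are entry genes
(default: every hypothetical/unknown/unannotated gene), a motif must
additionally contain ≥ 1 annotated member, and the known-pair rule
guards entry–annotated pairs. Any triangle through the entry gene
gives it one direct edge and a two-edge indirect path by construction,
so no extra path-type constraint is imposed. The hypothesis table maps
each entry gene to its annotated partners' descriptions.

## Synthetic data

The generator emulates the three input sources with planted, recorded
truth. Expression blocks share one latent profile plus independent
Gaussian noise σ (within-block correlation ≈ 1/(1 + σ²), so σ = 0.25
gives r ≈ 0.94, comfortably above the 0.7 threshold). Event tables
draw self-species and tainted-citation labels at configurable rates.
Planted filter scenarios construct the three evidence networks
directly: each planted triad rotates through evidence-type assignments,
each decoy violates exactly one rule (single-type triangle; a
self-species EVEX key–candidate edge; for the HP case, an
all-unannotated triangle), and triads are node-disjoint with key genes
touching nothing else — so the expected filter output is exact by
construction, not merely highly probable.

Two presets write complete input file sets. `small` (~120 background
genes, 36 conditions) is the smoke-test scale. `paper-shaped`
approximates the source-data scales: 2,850-gene universe, a 1,900-gene
co-expression span tiled with 380 five-gene blocks over 68 conditions
(the compendium size of the motivating study; with 68 observations a
chance |r| ≥ 0.7 is vanishingly rare, so background expression cannot
contaminate planted structure), a 1,900-gene Y2H span with ~3,200
random pairs, and an 800-gene text-mining span grouped into families
with 900 events at 10% self-species and 2% tainted rates. Planted
genes live outside the background pools: planted CoEx edges are
realized as tight expression profiles (one latent per connected planted
component, signs propagated by BFS, noise 0.02), planted EVEX edges as
singleton-family events. Because keys touch only planted structure,
candidate-triad recovery through the full file-based pipeline is
deterministic. All generators draw from per-component substreams of
one seed; the same seed reproduces byte-identical files.

What the generator does *not* emulate: realistic microarray noise and
batch structure, degree heterogeneity and hub proteins, citation-count
skew across articles, and family-size distributions of real gene
catalogs. Passing tests therefore demonstrate algorithmic correctness
(the filters implement the stated rules exactly; the builders match
their oracles), not biological recall/precision on real data — the
motivating study itself notes an unknown false-positive proportion
among text-mining edges.

## Numerical and I/O choices

Pearson correlation delegates to pandas (`DataFrame.corr` with
`min_periods`), which implements pairwise-complete observations;
undefined values propagate as NaN and are excluded from edges. Stored
correlations are clipped to [−1, 1] to absorb floating-point overshoot.
Floats serialize with `%.10g`, and round-trip equality is asserted to
six significant digits. SIF files carry only the topology
(`node TAB type TAB node`, lowercase type as the interaction label);
node and edge attributes travel in sidecar TSVs that the reader
re-attaches when present — a bare SIF CoEx edge gets NaN for its
unknown correlation. GraphML is self-contained with lists
pipe-joined. Duplicate (pair, type) keys on read are an error naming
the key; malformed lines report their line number.

## Problem sizes

The default test suite and the acceptance script run at the scales
above: 100-seed scenario sweeps, 200-gene correlation oracles,
≤ 30-node exhaustive triangle enumeration, and one paper-shaped
end-to-end run (a few seconds each on a single core). These sizes were
chosen so every oracle can be exhaustive or near-exhaustive while the
whole suite stays fast enough to run on every change.

## Known limitations

- Rule (ii)'s global reading is stricter than a chosen-edges-only
  reading; on densely connected real networks it rejects more motifs.
- Event merging keeps one aggregated EVEX edge per gene pair rather
  than typed parallel text-mining edges; the event-type set is
  preserved, but per-type confidences are collapsed to the maximum.
- The 76%-of-genome style coverage figures depend on a gene-universe
  definition (chromosome vs plasmids); reports expose raw counts and
  leave denominators to the caller.
- Only triads are mined; larger motifs and motif-enrichment statistics
  are out of scope.
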