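# Methods

## Entity recognition

Entities are recognized by exact dictionary chunking: the lexicon maps
normalized surface forms (names and synonyms) to a canonical `(type, id)`
pair, and text is scanned left to right, taking at each position the longest
surface that matches at token boundaries (a match may not begin or end inside
an alphanumeric run). Longest-leftmost selection makes the output
deterministic and suppresses embedded shorter surfaces ("insulin" inside
"insulin resistance"). Matching is line-based: titles and abstracts are
joined with a newline and normalized per line, so no chunk can span the
title/abstract boundary.

Normalization (shared by the lexicon, the chunker, the query filter and the
evaluation matcher) is NFKC + lowercase + whitespace-run collapse + edge
punctuation stripping. Exact matching on mixed-case dictionaries needs a
stated case policy; we fold case by default because dictionary entries such
as gene symbols appear in prose in many casings, and the policy object makes
case-sensitive matching available. A consequence inherited from the approach
itself is that dictionary homonyms of common English words ("large",
"impact", "set" as gene names) are matched like any other surface; no
disambiguation is attempted, so frequency tables can carry such artifacts,
exactly as they do with real biomedical dictionaries.

A surface mapped to two different entities is a hard error by default
(silent ambiguity corrupts every downstream count); a `first-wins` override
exists for dirty dictionaries.

## Network construction

The citing set is selected by term containment at token boundaries on
normalized title/abstract text — a deliberate, reproducible emulation of a
keyword search rather than a query-language parser. References that do not
resolve inside the corpus are dropped (the analog of keeping only cited
papers with resolvable identifiers) and counted. Duplicate references within
one record collapse on ingestion, so one citing paper contributes at most one
citation event per cited paper.

Projection pairs each document's entity *set*: per paper arc and ordered
entity pair, the arc weight grows by one. Set semantics (rather than mention
multiplicity) reflects that a citation links works, not individual mentions;
a mention-multiplicity mode exists behind a flag. The accumulator is an
associative map keyed by the ordered entity pair, giving amortized
constant-time weight increments; the result is invariant to arc order.

## Network statistics: the two-view convention

Degrees, degree histograms and density use the **directed loopful** view:
density is m/n² (so the complete digraph with loops has density exactly 1),
and a loop adds one to both the in- and out-degree of its node. Components,
bi-components, k-cores, geodesic distances, clustering, closeness and
betweenness use the **underlying undirected, unweighted, loop-free simple
graph**: connectivity claims about citation networks ("any two entities can
reach each other") are semi-path statements, and cohesion concepts
(articulation points, cores, triangles) are defined on simple graphs. Arc
weights are citation multiplicities, not distances, and are ignored by every
statistic.

Distance-based measures on a disconnected graph are computed on the largest
component and flagged as such in the result object. The mean geodesic
distance is the average over ordered pairs; the diameter comes with a
deterministic (lexicographically smallest) achieving pair. Closeness is
Freeman-normalized, (N−1)/Σd; betweenness is the unnormalized
geodesic-fraction sum over unordered pairs. Ranked tables break ties by
(score descending, type, id) so output is reproducible.

The power-law exponent of a degree histogram is the discrete maximum
likelihood estimate: γ̂ maximizes −γ Σ log k − n log ζ(γ, xmin) with the
Hurwitz zeta normalizer, solved by bounded scalar minimization on
γ ∈ (1.0001, 12); a log–log least-squares slope is returned as a diagnostic
only. `xmin` defaults to 1 and should be raised when the head of the
distribution departs from a pure power law (see below).

## Synthetic data

The generator emulates a query-selected citation corpus:

- **Documents** appear in temporal order and cite only earlier documents (a
  DAG, matching citation temporality). Reference counts are Poisson with
  mean `refs_per_doc` (default 5), clipped for the earliest documents.
- **Attachment** is uniform or linear preferential with the classic
  Barabási–Albert kernel — citation weight proportional to (mean out-degree
  + current in-degree) — whose in-degree tail exponent tends to 3. Because
  the finite-size law is ∝ (k+m)⁻³, the pure-power MLE is biased low at
  small `xmin`; tail fits in the test-suite use xmin = 4·`refs_per_doc`,
  beyond the offset scale.
- **Mentions**: each document embeds Poisson-many (mean 4) entity surfaces,
  entities drawn from a Zipf(s = 1) popularity law over the lexicon (heavy-
  tailed frequency tables, as real corpora show), surfaces drawn uniformly
  among an entity's synonyms. Surfaces are unique random words engineered so
  that no accidental token-boundary match exists; the planted mention
  multiset per document is therefore exactly what the chunker must recover,
  which is the end-to-end NER oracle.
- **Planted interactions**: a focal drug (the most popular drug by default)
  and partner entities (least popular of their type, so their baseline
  signal is negligible) are planted via dedicated seed documents that
  mention exactly one partner each. Documents mentioning the focal entity —
  a fraction `focal_doc_fraction` = 0.8 of the corpus, because a
  query-selected collection is centred on its focal entity — up-weight the
  seed documents by β when choosing references. Seed documents are spread
  over corpus positions [0.05n, 0.15n]: placed at the very head they would
  become preferential-attachment hubs even at β = 1 (first-mover advantage,
  faking a null signal); placed late they lack subsequent citers. At the
  default signal strength (β = 20, 500 documents, 5 partners) at least 80%
  of partners reach the top-5 in-degree list of their type across seeds,
  while β = 1 shows no enrichment.

What the generator does **not** model: real language (abstracts are word
salad around embedded surfaces), homonymy and ambiguity of surface forms,
publication-year effects beyond ordering, and curation noise in reference
sets. Passing tests therefore demonstrate the correctness of the pipeline's
mechanics and the recoverability of planted structure — not NER accuracy or
ranking performance on real literature.

All randomness flows from one integer seed through per-purpose child
streams; every emitted file is byte-identical across runs with the same
seed.

## Evaluation

Reference sets are name-matched, not ID-matched: curated vocabularies and
extraction lexicons rarely share identifiers, so an entity matches a
reference record when any of its normalized names (preferred name plus
lexicon synonyms) equals the record's normalized name and the types agree.
Duplicate reference names keep the best (lowest) rank with a warning. Band
summaries default to ranks 1–10 / 11–100 / 101+; bands must be disjoint and
cover [1, ∞). Generic terms can be excluded via a plain-text stoplist.
Association scores carried by the reference are pass-through only — never
recomputed.

## Test-suite design and problem sizes

Every graph statistic is checked against an independent naive oracle
(union-find, Floyd–Warshall, matrix-power geodesic counting, full triple
enumeration, subset enumeration for cores and bicomponents) on 200+ random
digraphs of up to 9 nodes — small enough for exponential oracles, large
enough to exercise every articulation/tie case. Pipeline-level suites use
corpora of 40–500 documents; power-law recovery uses 10⁵ i.i.d. draws and an
8,000-document preferential-attachment corpus. These sizes keep the full
suite under a minute while leaving every stochastic check multiple seeds
wide.

## Known limitations

- Exact chunking cannot recognize inflected or misspelled surfaces, and the
  stated normalization is intentionally conservative (internal punctuation
  is significant).
- Frequency semantics ("how often is an entity in the citing set") default
  to document frequency; mention counting is available but changes table
  order for verbose entities.
- Pajek and TSV network files do not carry display names (the encoding keeps
  the parseable `TYPE__ID` label so round-trips are lossless); the CLI
  restores names from the lexicon, and GraphML carries them natively.
- Whether "links" in a reported network size means distinct weighted arcs or
  raw pair events is corpus-dependent; the package reports both (`m` and
  `total_weight`).
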