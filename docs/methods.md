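# Methods

This note documents the retrieval model implemented by `mrank`, the choices
made where the design was open, and what the packaged fixtures do and do
not emulate.

## Model representation

An annotated model is a pair of machine-readable source (SBML Level 2) and
annotation information (MIRIAM URN triplets attached to the model or its
elements). Parsing walks the RDF blocks inside `<annotation>` elements and
accepts qualifiers from the thirteen BioModels.net names under either the
`bqbiol` or `bqmodel` vocabulary; unknown qualifiers and non-MIRIAM
resources are skipped with a warning rather than failing the parse, since
deposited models routinely contain both. SBO terms given as `sboTerm`
attributes are folded in as annotations with namespace `biomodels.sbo` and
qualifier `is`, so they participate in URI search like any other
annotation.

URNs are normalized once at parse time: namespace lowercased,
percent-escapes decoded into the stored identifier, and the canonical URI
text re-encoded with `:` as `%3A`. Normalization is idempotent, which the
property suite asserts.

Featurization splits a model into 26 features over six dimensions.
Tokenization lowercases and splits on any character that is neither an
ASCII letter nor a digit, keeping length-1 tokens so chemical formulae
(`c8h10n4o2`) survive. Unnamed elements fall back to their id token
(`re1`), because auto-generated ids are frequently the only handle a
deposited model offers. Dates are stored as single ISO tokens
(`2009-06-15`) so range clauses can re-parse them; they are the one
deliberate exception to the "tokens contain only letters and digits" rule.

Two schema points were genuinely open and are decided here: the user
content dimension carries a single `content` feature (weight 1) fed from
free-form tags, and the administrative dimension carries `id`,
`additionalID` and `path`. With those choices the shipped schema has 26
features; the schema object documents its own count.

## Weights

Two weight matrices ship as YAML defaults: per-feature weights (URI
features of the central constituents dominate at 5; descriptions at 3–4;
dates and administrative fields at 1) and per-qualifier weights (`is` 2.0,
`isHomologTo` 1.7, the part/version family 1.5, the encoding family 1.3,
the rest 1.0). `bqbiol` and `bqmodel` share one weight per qualifier name.
Both matrices are plain data; callers can load alternatives from files.

## Scoring

The scorer is a per-field vector-space sum:

    score(c) = sum over non-MUST_NOT clauses s:  W(f_s) * B_s * sim_s(c)

* Term clauses: `sim = (sum_t b_t * tf·idf(t,c,f)) / ||c_f||` with
  `tf = sqrt(count)` and `idf = 1 + ln(N / (1 + df))`, document-side
  normalization only. The query side is left unnormalized so that matching
  more optional clauses strictly increases the score.
* URI clauses: `sim = sum_u b_u * Q(best qualifier linking u in c)`. URI
  clauses are deliberately **not** field-normalized: a model annotating
  many species must not be penalized for one exact URI hit — the qualifier,
  not field verbosity, carries the relevance signal.
* Date clauses contribute an indicator, so a matched date range yields only
  the small `W(date) * B` increment.

The scorer interface is a free function over the index, so alternative
similarity functions can be swapped in without touching selection. Ties
break by ascending model id everywhere, making runs reproducible.
Candidate selection is pure set algebra and is checked in the tests against
an exhaustive per-model clause evaluation; ranking is checked against an
independent brute-force scorer that recomputes every tf, idf, norm and
clause sum from the raw representations (agreement to 1e-9 relative).

## Semantic resolution

The semantic index holds one entry per distinct URI occurring in the
corpus: qualifier-typed model links plus content terms from an offline
lexicon. Resolution scores entries by tf-idf cosine between the query bag
and entry content (document frequencies over semantic entries), drops
zero scores, applies the qualifier filter (an entry survives when *some*
model links it under a named qualifier, vocabulary-agnostic), and returns
the top k. Weights are plain cosine in (0, 1]; no max-normalization is
applied, and no attempt is made to reproduce any particular production
system's boost values numerically. Default k = 10. Ties break by ascending
URI text.

The lexicon is a versioned package fixture (URI → descriptive text), not a
live resolver; URIs missing from it are still indexed and reachable by
direct URI query, just not by keyword.

## Ontology expansion

Expansion is breadth-first over the undirected OBO term graph from all
classes whose name or exact synonym matches the query term: every name and
synonym within radius r is emitted with weight `decay^distance`, defaults
radius 2 and decay 0.5. `is_a` and `part_of` count equally for distance; a
per-relation edge-weight map (default all 1) is exposed for callers who
want relation-aware decay. Expansion weight multiplies into the clause
boost, and ontology-derived clauses are always SHOULD regardless of the
parent clause — expansions are suggestions, never requirements.

## Query assembly

A MUST constituent clause and its semantically derived URI clause form one
composite group satisfied when either member matches, so "the species must
be exactly caffeine" is satisfiable by a model that never spells the word
but carries the annotation. The literal clause is always retained next to
the derived URI clause, covering models that provide the search term but
no annotation. Every assembled clause carries a provenance label
(user/semantic/ontology) and the user-labeled subset reconstructs the
parsed query exactly.

`date:` in the query grammar aliases the creation (submission) date;
`modificationDate` is addressable by name. Query-by-example builds one
SHOULD clause per non-empty feature with unit boosts and enrichment off;
self-retrieval at rank 1 is asserted on every generated test corpus.

## Synthetic corpus generator

The generator emulates a small curated repository: models with 2–5 species,
1–2 compartments and 1–3 reactions drawn from a built-in vocabulary of real
compounds, processes and compartments with genuine ChEBI/KEGG/GO
identifiers; roughly every fourth element keeps only its auto-generated id,
mirroring the semantically poor names common in deposited models.
Annotation density defaults to 0.9 and the qualifier mix is dominated by
`is` (0.55), reflecting that identity annotations are the rule in curated
corpora; authors, dates (2007–2010) and notes are drawn deterministically
from one seeded stream, and the XML is templated text, so equal specs give
byte-identical corpora. Density changes toggle annotation blocks only — the
random draws are made unconditionally, so corpus structure is invariant in
the density parameter.

What the generator does **not** emulate: real corpus scale (hundreds of
models, hundreds of thousands of resolved terms), kinetic laws and maths,
multi-qualifier annotation stacks on one element, CellML/BioPAX sources,
and noisy or broken RDF. Passing tests therefore demonstrate correctness
of the retrieval arithmetic and the pipeline contracts, not ranking quality
on a production repository.

The worked-example fixture packages a four-entry lexicon for the caffeine
example whose content strings mimic what a live resolver would return for
the ChEBI and KEGG entries (names, synonyms, formulae, cross-reference
text). The third model's deliberately weak match is a synthetic stand-in:
it links xanthine and glyoxylate via `isVersionOf` only, so the
is-restricted resolution still yields exactly three URIs while the model
ranks last through the lower qualifier weight — the mechanism, not any
particular score value, is what the fixture pins down.

## Problem sizes and numerics

Tests run on corpora of at most 20 models; the oracle-equivalence check
uses 100 seeded corpora with random 1–5-clause queries at 1e-9 relative
tolerance, and the acceptance script uses 50 corpora. These sizes keep the
whole suite under a few seconds while exercising every code path; the
algorithms are O(postings) and scale linearly in corpus size. Scores are
plain double precision; the only tolerance-sensitive spot is summation
order in norms, which serialization round-trips preserve bit-identically
by sorting postings.

## Known limitations

* Only SBML ingestion is implemented; CellML/BioPAX are out of scope.
* No fuzzy, phrase or proximity operators — wildcard prefix and date ranges
  only.
* The index is rebuilt offline; there are no incremental updates.
* Qualifier restrictions act at resolution time (which URIs are kept), not
  as hard constraints on how a matching model must link a URI — matching
  via a weaker qualifier is allowed and simply scores lower, which is what
  lets a weakly linked model appear at the bottom of a result list instead
  of vanishing.
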