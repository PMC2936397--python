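"""Query parsing, expansion and assembly; the search engine facade.

Two query types are supported.  Query-by-value (QBV) takes a textual
expression in the grammar

    [+|-]feature[@qualifier,...]:(term term^boost ...)
    [+|-]date:([dd/MM/yyyy - dd/MM/yyyy])        # either side may be *

where ``+`` marks a MUST clause, ``-`` a MUST_NOT clause and no prefix a
SHOULD clause.  Query-by-model-example (QBME) featurizes a whole model and
searches every non-empty feature verbatim, with enrichment switched off —
the example model itself supplies the context a keyword query lacks.

Assembly expands each constituent-description clause twice: the semantic
index resolves its terms to a weighted URI list that becomes a sibling
clause on the corresponding URI feature, and each ontology contributes
decayed related terms as SHOULD clauses.  The original literal clause is
retained so plain term matches still count.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from mrank.corpus import (
    DEFAULT_SCHEMA,
    URI_FEATURES,
    AnnotatedModel,
    FeatureSchema,
    ModelRepresentation,
    featurize,
    parse_date,
)
from mrank.ontology import OntologyGraph, expand_term
from mrank.retrieval import (
    ModelIndex,
    ScoredModel,
    WeightConfig,
    rank,
    retrieve_candidates,
)
from mrank.semantic_index import SemanticIndex, resolve_terms
from mrank.tokens import QUALIFIER_NAMES, tokenize


class QueryParseError(ValueError):
    """Malformed query expression; message carries the offending position."""


#: query-grammar alias: `date:` restricts the submission (creation) date.
FEATURE_ALIASES = {"date": "creationDate"}

#: constituent description feature -> its URI sibling feature.
_URI_SIBLING = {**URI_FEATURES, "modelName": "modelURI"}

_CLAUSE_RE = re.compile(
    r"""(?P<prefix>[+-]?)
        (?P<feature>[A-Za-z][A-Za-z0-9]*)
        (?:@(?P<quals>[A-Za-z,]+))?
        :\(\s*(?P<body>[^()]*)\)""",
    re.VERBOSE,
)


@dataclass
class SubQuery:
    feature: str
    occurrence: str = "SHOULD"  # MUST | SHOULD | MUST_NOT
    terms: list[tuple[str, float]] = field(default_factory=list)  # (term, boost)
    qualifier_restriction: set[str] | None = None
    date_range: tuple[_dt.date | None, _dt.date | None] | None = None
    enrich: bool = True

    def __post_init__(self) -> None:
        if (self.date_range is None) == (not self.terms):
            raise QueryParseError(
                f"clause on {self.feature!r} must carry terms or a date range"
            )


@dataclass
class Query:
    clauses: list[SubQuery]
    mode: str = "QBV"  # QBV | QBME

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for clause in self.clauses:
            if clause.feature in seen:
                raise QueryParseError(f"duplicate feature {clause.feature!r}")
            seen.add(clause.feature)


@dataclass
class Clause:
    """One clause of an assembled query, as executed against the index."""

    feature: str
    occurrence: str
    kind: str  # term | uri | date
    boost: float = 1.0
    terms: tuple[tuple[str, float], ...] = ()
    uris: tuple[tuple[str, float], ...] = ()
    date_range: tuple[_dt.date | None, _dt.date | None] = (None, None)
    qualifier_restriction: frozenset | None = None
    origin: str = "user"  # user | semantic | ontology
    group: int | None = None


@dataclass
class AssembledQuery:
    clauses: list[Clause]

    def provenance(self) -> dict[int, str]:
        return {i: c.origin for i, c in enumerate(self.clauses)}

    def user_clauses(self) -> list[Clause]:
        return [c for c in self.clauses if c.origin == "user"]


# ---------------------------------------------------------------------------
# Parsing


def _parse_terms(body: str, feature: str, pos: int) -> list[tuple[str, float]]:
    terms: list[tuple[str, float]] = []
    for raw in body.split():
        text, _, boost_text = raw.partition("^")
        boost = 1.0
        if boost_text:
            try:
                boost = float(boost_text)
            except ValueError:
                raise QueryParseError(
                    f"malformed boost {boost_text!r} in {feature!r} at position {pos}"
                ) from None
            if boost <= 0:
                raise QueryParseError(
                    f"boost must be positive in {feature!r} at position {pos}"
                )
        token = text.lower().strip()
        if token:
            terms.append((token, boost))
    return terms


def _parse_date_range(
    body: str, feature: str, pos: int
) -> tuple[_dt.date | None, _dt.date | None]:
    body = body.strip()
    if not (body.startswith("[") and body.endswith("]")):
        raise QueryParseError(f"date range must be bracketed at position {pos}")
    inner = body[1:-1]
    if " - " not in inner:
        raise QueryParseError(f"malformed date range {body!r} at position {pos}")
    parts = [p.strip() for p in inner.split(" - ")]
    if len(parts) != 2:
        raise QueryParseError(f"malformed date range {body!r} at position {pos}")

    def side(text: str) -> _dt.date | None:
        if text in ("*", ""):
            return None
        try:
            return parse_date(text)
        except ValueError:
            raise QueryParseError(
                f"unparseable date {text!r} at position {pos}"
            ) from None

    return side(parts[0]), side(parts[1])


def parse_query(text: str, schema: FeatureSchema = DEFAULT_SCHEMA) -> Query:
    """Parse a QBV expression into a structured :class:`Query`."""
    clauses: list[SubQuery] = []
    cursor = 0
    stripped = text.strip()
    if not stripped:
        raise QueryParseError("empty query")
    for m in _CLAUSE_RE.finditer(text):
        between = text[cursor : m.start()].strip()
        if between:
            raise QueryParseError(
                f"unparseable fragment {between!r} at position {cursor}"
            )
        cursor = m.end()
        feature = m.group("feature")
        is_date_clause = feature in FEATURE_ALIASES or schema.dimensions.get(feature) == "dates"
        feature = FEATURE_ALIASES.get(feature, feature)
        if feature not in schema:
            raise QueryParseError(
                f"unknown feature {m.group('feature')!r} at position {m.start()}"
            )
        occurrence = {"+": "MUST", "-": "MUST_NOT", "": "SHOULD"}[m.group("prefix")]
        restriction: set[str] | None = None
        if m.group("quals"):
            restriction = {q for q in m.group("quals").split(",") if q}
            unknown = restriction - QUALIFIER_NAMES
            if unknown:
                raise QueryParseError(
                    f"unknown qualifier(s) {sorted(unknown)} at position {m.start()}"
                )
        body = m.group("body")
        if is_date_clause:
            clause = SubQuery(
                feature=feature,
                occurrence=occurrence,
                date_range=_parse_date_range(body, feature, m.start()),
                qualifier_restriction=restriction,
            )
        else:
            terms = _parse_terms(body, feature, m.start())
            if not terms:
                raise QueryParseError(f"empty clause on {feature!r} at position {m.start()}")
            clause = SubQuery(
                feature=feature,
                occurrence=occurrence,
                terms=terms,
                qualifier_restriction=restriction,
            )
        clauses.append(clause)
    trailing = text[cursor:].strip()
    if trailing:
        raise QueryParseError(f"unparseable fragment {trailing!r} at position {cursor}")
    if not clauses:
        raise QueryParseError("no clauses found")
    return Query(clauses=clauses)


def free_text_query(text: str, schema: FeatureSchema = DEFAULT_SCHEMA) -> Query:
    """A prefix-free expression searched across all term features as SHOULD."""
    tokens = tokenize(text)
    if not tokens:
        raise QueryParseError("empty query")
    terms = [(t, 1.0) for t in tokens]
    clauses = [
        SubQuery(feature=f, occurrence="SHOULD", terms=list(terms))
        for f, dim in schema.dimensions.items()
        if not f.endswith("URI") and dim != "dates"
    ]
    return Query(clauses=clauses)


# ---------------------------------------------------------------------------
# Assembly


def _sub_to_clause(sub: SubQuery, group: int | None = None) -> Clause:
    if sub.date_range is not None:
        return Clause(
            feature=sub.feature,
            occurrence=sub.occurrence,
            kind="date",
            date_range=sub.date_range,
            origin="user",
            group=group,
        )
    return Clause(
        feature=sub.feature,
        occurrence=sub.occurrence,
        kind="term",
        terms=tuple(sub.terms),
        qualifier_restriction=(
            frozenset(sub.qualifier_restriction) if sub.qualifier_restriction else None
        ),
        origin="user",
        group=group,
    )


def assemble(
    query: Query,
    sem: SemanticIndex | None,
    onts: Sequence[OntologyGraph] = (),
    k: int = 10,
    radius: int = 2,
    decay: float = 0.5,
) -> AssembledQuery:
    """Expand and assemble a parsed query into the final engine query.

    A MUST constituent clause and its semantically derived URI clause form
    one composite group: either member satisfies the MUST requirement, so a
    model annotated with a resolved URI matches even if it never spells the
    literal term.  Ontology-derived terms are always SHOULD — expansions
    are suggestions, never requirements.
    """
    constituent_features = set(DEFAULT_SCHEMA.constituent_term_features())
    clauses: list[Clause] = []
    group_counter = 0
    for sub in query.clauses:
        expandable = (
            sub.enrich
            and sub.date_range is None
            and sub.feature in constituent_features
        )
        group: int | None = None
        derived: list[Clause] = []
        if expandable:
            uri_sibling = _URI_SIBLING.get(sub.feature)
            if sem is not None and uri_sibling is not None:
                weighted = resolve_terms(
                    sem,
                    [t for t, _b in sub.terms],
                    qualifier_filter=sub.qualifier_restriction,
                    k=k,
                )
                if weighted:
                    derived.append(
                        Clause(
                            feature=uri_sibling,
                            occurrence=sub.occurrence,
                            kind="uri",
                            uris=tuple((w.uri, w.weight) for w in weighted),
                            origin="semantic",
                        )
                    )
            existing = {t for t, _b in sub.terms}
            expansion_terms: dict[str, float] = {}
            for ont in onts:
                for term, boost in sub.terms:
                    for exp in expand_term(ont, term, radius=radius, decay=decay):
                        if exp.distance == 0 or exp.term_text in existing:
                            continue
                        weight = boost * exp.weight
                        if weight > expansion_terms.get(exp.term_text, 0.0):
                            expansion_terms[exp.term_text] = weight
            if expansion_terms:
                derived.append(
                    Clause(
                        feature=sub.feature,
                        occurrence="SHOULD",
                        kind="term",
                        terms=tuple(sorted(expansion_terms.items())),
                        origin="ontology",
                    )
                )
        semantic_derived = [c for c in derived if c.origin == "semantic"]
        if sub.occurrence == "MUST" and semantic_derived:
            group_counter += 1
            group = group_counter
            for c in semantic_derived:
                c.group = group
        clauses.append(_sub_to_clause(sub, group=group))
        clauses.extend(derived)
    return AssembledQuery(clauses=clauses)


# ---------------------------------------------------------------------------
# Engine


@dataclass
class Engine:
    """Holds the built indexes and configuration for searching."""

    model_index: ModelIndex
    semantic_index: SemanticIndex | None = None
    ontologies: Sequence[OntologyGraph] = ()
    weights: WeightConfig = field(default_factory=WeightConfig.default)
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    k: int = 10
    radius: int = 2
    decay: float = 0.5


def search_qbv(engine: Engine, text: str, enrich: bool = True) -> list[ScoredModel]:
    """Parse, assemble, retrieve and rank a query-by-value expression.

    Expressions without any ``feature:(...)`` clause are treated as free
    text across all term features.
    """
    if _CLAUSE_RE.search(text):
        query = parse_query(text, engine.schema)
    else:
        query = free_text_query(text, engine.schema)
    if not enrich:
        for sub in query.clauses:
            sub.enrich = False
    assembled = assemble(
        query,
        engine.semantic_index,
        engine.ontologies,
        k=engine.k,
        radius=engine.radius,
        decay=engine.decay,
    )
    candidates = retrieve_candidates(engine.model_index, assembled)
    return rank(engine.model_index, candidates, assembled, engine.weights)


def search_qbme(
    engine: Engine, example: AnnotatedModel | ModelRepresentation
) -> list[ScoredModel]:
    """Query by model example: every non-empty feature, verbatim, SHOULD.

    Enrichment is off; qualifier weights still apply to the URI clauses.
    """
    rep = (
        example
        if isinstance(example, ModelRepresentation)
        else featurize(example, engine.schema)
    )
    clauses: list[Clause] = []
    for feature, terms in sorted(rep.assignments.items()):
        clauses.append(
            Clause(
                feature=feature,
                occurrence="SHOULD",
                kind="term",
                terms=tuple(sorted((t, 1.0) for t in terms)),
                origin="user",
            )
        )
    for feature, entries in sorted(rep.uri_assignments.items()):
        uris = sorted({u for u, _q in entries})
        clauses.append(
            Clause(
                feature=feature,
                occurrence="SHOULD",
                kind="uri",
                uris=tuple((u, 1.0) for u in uris),
                origin="user",
            )
        )
    assembled = AssembledQuery(clauses=clauses)
    candidates = retrieve_candidates(engine.model_index, assembled)
    return rank(engine.model_index, candidates, assembled, engine.weights)
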