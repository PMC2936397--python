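"""Per-feature inverted index, tf-idf statistics, candidate selection, ranking.

Candidate selection follows extended-boolean semantics: a clause matches a
model when at least one of its terms or URIs occurs in the clause's feature
field; MUST clauses intersect, SHOULD clauses union, MUST_NOT clauses
subtract.  Ranking is a weighted vector-space sum over the non-negative
clauses:

    score(c) = sum_s  W(f_s) * B_s * sim_s(c)

where W is the per-feature weight, B_s the clause boost, and sim_s a
document-side-normalized tf-idf dot product for term clauses, a
qualifier-weighted sum for URI clauses, and an indicator for date clauses.
URI clauses are deliberately not field-normalized: a model annotating many
species must not be penalized for an exact URI hit — the qualifier linking
the URI, not field verbosity, carries the relevance signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable

import yaml

from mrank.corpus import ModelRepresentation, parse_date
from mrank.tokens import QUALIFIER_NAMES

if TYPE_CHECKING:  # pragma: no cover - typing only
    from mrank.query import AssembledQuery, Clause


def tf_weight(count: int) -> float:
    """Term-frequency component: sqrt of the in-field count."""
    return math.sqrt(count) if count > 0 else 0.0


def idf_weight(doc_count: int, df: int) -> float:
    """Inverse-document-frequency component: 1 + ln(N / (1 + df))."""
    return 1.0 + math.log(doc_count / (1.0 + df))


class DuplicateModelError(ValueError):
    pass


class UnknownModelError(KeyError):
    pass


class UnsatisfiableQueryError(ValueError):
    """A query with neither MUST nor SHOULD clauses selects nothing."""


# ---------------------------------------------------------------------------
# Weight configuration (shipped defaults: per-feature and per-qualifier)


#: Documentation-level importance of each dimension.
DIMENSION_IMPORTANCE = {
    "administrative": "low",
    "persons": "medium",
    "dates": "low",
    "publication": "high",
    "constituents": "very high",
    "user_content": "very high",
}


@dataclass(frozen=True)
class WeightConfig:
    feature_weights: dict[str, float]
    qualifier_weights: dict[str, float]
    dimension_importance: dict[str, str] = field(
        default_factory=lambda: dict(DIMENSION_IMPORTANCE)
    )

    def __post_init__(self) -> None:
        unknown = set(self.qualifier_weights) - QUALIFIER_NAMES
        if unknown:
            raise ValueError(f"unknown qualifiers in config: {sorted(unknown)}")

    def feature(self, name: str) -> float:
        return self.feature_weights[name]

    def qualifier(self, qualified: str) -> float:
        """Weight for a (possibly vocabulary-prefixed) qualifier name.

        ``bqbiol_is`` and ``bqmodel_is`` share one weight per bare name.
        """
        bare = qualified.split("_", 1)[-1] if "_" in qualified else qualified
        return self.qualifier_weights[bare]

    @classmethod
    def default(cls) -> "WeightConfig":
        data = resources.files("mrank.data")
        feats = yaml.safe_load((data / "feature_weights.yaml").read_text())
        quals = yaml.safe_load((data / "qualifier_weights.yaml").read_text())
        return cls(feature_weights=feats, qualifier_weights=quals)

    @classmethod
    def from_files(cls, feature_path: str, qualifier_path: str) -> "WeightConfig":
        with open(feature_path) as fh:
            feats = yaml.safe_load(fh)
        with open(qualifier_path) as fh:
            quals = yaml.safe_load(fh)
        return cls(feature_weights=feats, qualifier_weights=quals)


# ---------------------------------------------------------------------------
# Model index


@dataclass
class ModelIndex:
    """Inverted postings per (feature, term) and (feature, URI)."""

    postings: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    uri_postings: dict[tuple[str, str], dict[str, tuple[str, ...]]] = field(
        default_factory=dict
    )
    model_ids: list[str] = field(default_factory=list)

    @property
    def doc_count(self) -> int:
        return len(self.model_ids)

    # -- statistics -----------------------------------------------------

    def df(self, feature: str, term: str) -> int:
        return len(self.postings.get((feature, term), ()))

    def idf(self, feature: str, term: str) -> float:
        return idf_weight(self.doc_count, self.df(feature, term))

    def field_terms(self, feature: str) -> Iterable[str]:
        for f, t in self.postings:
            if f == feature:
                yield t

    def field_norm(self, model_id: str, feature: str) -> float:
        return self._norms.get((model_id, feature), 0.0)

    def __post_init__(self) -> None:
        self._id_set = set(self.model_ids)
        self._rebuild_norms()

    def _rebuild_norms(self) -> None:
        sq: dict[tuple[str, str], float] = {}
        for (feature, term), plist in self.postings.items():
            idf = self.idf(feature, term)
            for model_id, count in plist.items():
                w = tf_weight(count) * idf
                key = (model_id, feature)
                sq[key] = sq.get(key, 0.0) + w * w
        self._norms = {k: math.sqrt(v) for k, v in sq.items()}

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "model_ids": self.model_ids,
            "postings": [
                {"feature": f, "term": t, "models": dict(sorted(p.items()))}
                for (f, t), p in sorted(self.postings.items())
            ],
            "uri_postings": [
                {
                    "feature": f,
                    "uri": u,
                    "models": {m: sorted(q) for m, q in sorted(p.items())},
                }
                for (f, u), p in sorted(self.uri_postings.items())
            ],
        }
        return json.dumps(obj, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelIndex":
        obj = json.loads(text)
        postings = {
            (e["feature"], e["term"]): dict(e["models"]) for e in obj["postings"]
        }
        uri_postings = {
            (e["feature"], e["uri"]): {m: tuple(q) for m, q in e["models"].items()}
            for e in obj["uri_postings"]
        }
        return cls(
            postings=postings,
            uri_postings=uri_postings,
            model_ids=list(obj["model_ids"]),
        )


def build_model_index(reps: Iterable[ModelRepresentation]) -> ModelIndex:
    """Build the inverted index from featurized models.

    Raises :class:`DuplicateModelError` on repeated model ids.
    """
    postings: dict[tuple[str, str], dict[str, int]] = {}
    uri_postings: dict[tuple[str, str], dict[str, tuple[str, ...]]] = {}
    model_ids: list[str] = []
    seen: set[str] = set()
    for rep in reps:
        if rep.model_id in seen:
            raise DuplicateModelError(f"duplicate model id {rep.model_id!r}")
        seen.add(rep.model_id)
        model_ids.append(rep.model_id)
        for feature, terms in rep.assignments.items():
            for term, count in terms.items():
                postings.setdefault((feature, term), {})[rep.model_id] = count
        for feature, entries in rep.uri_assignments.items():
            quals: dict[str, set[str]] = {}
            for uri, qualified in entries:
                quals.setdefault(uri, set()).add(qualified)
            for uri, qs in quals.items():
                uri_postings.setdefault((feature, uri), {})[rep.model_id] = tuple(
                    sorted(qs)
                )
    return ModelIndex(postings=postings, uri_postings=uri_postings, model_ids=model_ids)


def term_weight(index: ModelIndex, feature: str, term: str, model_id: str) -> float:
    """tf·idf of *term* in *model_id*'s *feature* field; 0 when absent."""
    if model_id not in index._id_set:
        raise UnknownModelError(model_id)
    plist = index.postings.get((feature, term))
    if not plist or model_id not in plist:
        return 0.0
    return tf_weight(plist[model_id]) * index.idf(feature, term)


# ---------------------------------------------------------------------------
# Clause matching


def _term_occurrences(index: ModelIndex, feature: str, term: str) -> list[str]:
    """Concrete index terms a (possibly wildcard, possibly multi-token)
    clause term stands for.  A trailing ``*`` makes the last token a prefix
    pattern."""
    tokens = term.split()
    out: list[str] = []
    for tok in tokens:
        if tok.endswith("*"):
            prefix = tok[:-1]
            out.extend(t for t in set(index.field_terms(feature)) if t.startswith(prefix))
        else:
            out.append(tok)
    return out


def _models_matching_term(index: ModelIndex, feature: str, term: str) -> set[str]:
    """Models whose *feature* field contains every token of *term*."""
    tokens = term.split()
    result: set[str] | None = None
    for tok in tokens:
        if tok.endswith("*"):
            prefix = tok[:-1]
            matched: set[str] = set()
            for t in set(index.field_terms(feature)):
                if t.startswith(prefix):
                    matched |= set(index.postings[(feature, t)])
        else:
            matched = set(index.postings.get((feature, tok), ()))
        result = matched if result is None else result & matched
        if not result:
            return set()
    return result or set()


def _clause_matches(index: ModelIndex, clause: "Clause") -> set[str]:
    if clause.kind == "term":
        out: set[str] = set()
        for term, _boost in clause.terms:
            out |= _models_matching_term(index, clause.feature, term)
        return out
    if clause.kind == "uri":
        out = set()
        for uri, _boost in clause.uris:
            plist = index.uri_postings.get((clause.feature, uri), {})
            if clause.qualifier_restriction is None:
                out |= set(plist)
            else:
                for model_id, quals in plist.items():
                    bares = {q.split("_", 1)[-1] for q in quals}
                    if bares & clause.qualifier_restriction:
                        out.add(model_id)
        return out
    if clause.kind == "date":
        start, end = clause.date_range
        out = set()
        for term in set(index.field_terms(clause.feature)):
            try:
                d = parse_date(term)
            except ValueError:
                continue
            if (start is None or d >= start) and (end is None or d <= end):
                out |= set(index.postings[(clause.feature, term)])
        return out
    raise ValueError(f"unknown clause kind {clause.kind!r}")


def retrieve_candidates(index: ModelIndex, query: "AssembledQuery") -> set[str]:
    """Extended-boolean candidate selection.

    Clauses sharing a composite ``group`` (a MUST constituent clause and its
    semantically derived URI sibling) are satisfied when either member
    matches.
    """
    must_sets: list[set[str]] = []
    should: set[str] = set()
    must_not: set[str] = set()

    grouped: dict[object, set[str]] = {}
    for clause in query.clauses:
        matches = _clause_matches(index, clause)
        if clause.occurrence == "MUST_NOT":
            must_not |= matches
        elif clause.occurrence == "MUST":
            if clause.group is not None:
                grouped.setdefault(clause.group, set()).update(matches)
            else:
                must_sets.append(matches)
        else:
            should |= matches
    must_sets.extend(grouped.values())

    has_positive = any(c.occurrence in ("MUST", "SHOULD") for c in query.clauses)
    if not has_positive:
        raise UnsatisfiableQueryError("query has neither MUST nor SHOULD clauses")

    if must_sets:
        candidates = set(index.model_ids)
        for s in must_sets:
            candidates &= s
    else:
        candidates = should
    return candidates - must_not


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class ScoredModel:
    model_id: str
    score: float
    explanation: list[tuple[str, float]] = field(default_factory=list)


def _clause_label(clause: "Clause") -> str:
    prefix = {"MUST": "+", "MUST_NOT": "-", "SHOULD": ""}[clause.occurrence]
    if clause.kind == "date":
        start, end = clause.date_range
        body = f"[{start or '*'} - {end or '*'}]"
    elif clause.kind == "uri":
        body = " ".join(u for u, _ in clause.uris[:3]) + ("..." if len(clause.uris) > 3 else "")
    else:
        body = " ".join(t for t, _ in clause.terms)
    return f"{prefix}{clause.feature}:({body})"


def _clause_similarity(
    index: ModelIndex, clause: "Clause", model_id: str, weights: WeightConfig
) -> float:
    if clause.kind == "term":
        norm = index.field_norm(model_id, clause.feature)
        if norm == 0.0:
            return 0.0
        total = 0.0
        for term, boost in clause.terms:
            for tok in _term_occurrences(index, clause.feature, term):
                total += boost * term_weight(index, clause.feature, tok, model_id)
        return total / norm
    if clause.kind == "uri":
        total = 0.0
        for uri, boost in clause.uris:
            plist = index.uri_postings.get((clause.feature, uri), {})
            quals = plist.get(model_id)
            if not quals:
                continue
            eligible = [
                q
                for q in quals
                if clause.qualifier_restriction is None
                or q.split("_", 1)[-1] in clause.qualifier_restriction
            ]
            if eligible:
                total += boost * max(weights.qualifier(q) for q in eligible)
        return total
    if clause.kind == "date":
        return 1.0 if model_id in _clause_matches(index, clause) else 0.0
    raise ValueError(f"unknown clause kind {clause.kind!r}")


def rank(
    index: ModelIndex,
    candidates: set[str],
    query: "AssembledQuery",
    weights: WeightConfig,
) -> list[ScoredModel]:
    """Score candidates with the weighted vector-space sum and sort.

    Ties are broken by ascending model id for determinism.
    """
    results: list[ScoredModel] = []
    positive = [c for c in query.clauses if c.occurrence != "MUST_NOT"]
    for model_id in candidates:
        explanation: list[tuple[str, float]] = []
        score = 0.0
        for clause in positive:
            sim = _clause_similarity(index, clause, model_id, weights)
            contribution = weights.feature(clause.feature) * clause.boost * sim
            if contribution != 0.0:
                explanation.append((_clause_label(clause), contribution))
            score += contribution
        results.append(ScoredModel(model_id=model_id, score=score, explanation=explanation))
    results.sort(key=lambda r: (-r.score, r.model_id))
    return results


def explain(result: ScoredModel) -> str:
    """Human-readable per-clause contribution table for one scored model."""
    lines = [f"model {result.model_id}  score {result.score:.6f}"]
    width = max((len(label) for label, _ in result.explanation), default=10)
    for label, contribution in result.explanation:
        lines.append(f"  {label:<{width}}  {contribution:12.6f}")
    lines.append(f"  {'total':<{width}}  {sum(c for _, c in result.explanation):12.6f}")
    return "\n".join(lines)
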