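"""Semantic index: URI -> qualifier-typed model links + resolved content.

The index contains every MIRIAM URI occurring in any indexed model.  Each
entry records which models link that URI under which (vocabulary-prefixed)
qualifier, plus a bag of content terms resolved from an offline lexicon —
names, synonyms, formulae, cross-reference text.  ``resolve_terms`` turns
keywords into a weighted, ranked list of URIs by tf-idf cosine similarity
over the entries' content, so a user can type "caffeine",
"1,3,7-trimethylxanthine" or "c8h10n4o2" and reach the same annotation.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from mrank.retrieval import idf_weight, tf_weight
from mrank.tokens import normalize_urn, tokenize


@dataclass
class Lexicon:
    """Offline mapping from normalized URI to descriptive free text."""

    entries: dict[str, str] = field(default_factory=dict)

    def describe(self, uri: str) -> str:
        return self.entries.get(uri, "")

    @classmethod
    def from_json(cls, text: str) -> "Lexicon":
        raw = json.loads(text)
        return cls({normalize_urn(k): v for k, v in raw.items()})

    @classmethod
    def from_tsv(cls, text: str) -> "Lexicon":
        entries: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            uri, _, description = line.partition("\t")
            entries[normalize_urn(uri)] = description.strip()
        return cls(entries)


@dataclass
class SemanticEntry:
    uri: str
    links: dict[str, set[str]] = field(default_factory=dict)  # qualified -> model ids
    content_terms: Counter = field(default_factory=Counter)

    def models(self, qualifier: str | None = None) -> set[str]:
        """Union of linked model ids, optionally restricted to one bare
        qualifier name (vocabulary-agnostic: ``is`` matches both
        ``bqbiol_is`` and ``bqmodel_is``)."""
        out: set[str] = set()
        for qualified, ids in self.links.items():
            if qualifier is None or qualified.split("_", 1)[-1] == qualifier:
                out |= ids
        return out

    def bare_qualifiers(self) -> set[str]:
        return {q.split("_", 1)[-1] for q in self.links}


@dataclass
class WeightedURI:
    uri: str
    weight: float
    matched_qualifiers: set[str] = field(default_factory=set)


class SemanticIndex:
    """All URIs of a corpus with their links and resolved content."""

    def __init__(self, entries: dict[str, SemanticEntry]):
        self.entries = entries
        self._df: Counter = Counter()
        for entry in entries.values():
            self._df.update(set(entry.content_terms))

    @property
    def doc_count(self) -> int:
        return len(self.entries)

    def idf(self, term: str) -> float:
        return idf_weight(self.doc_count, self._df[term])

    def _content_norm(self, entry: SemanticEntry) -> float:
        return math.sqrt(
            sum(
                (tf_weight(c) * self.idf(t)) ** 2
                for t, c in entry.content_terms.items()
            )
        )

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        obj = [
            {
                "uri": e.uri,
                "links": {q: sorted(ids) for q, ids in sorted(e.links.items())},
                "content_terms": dict(sorted(e.content_terms.items())),
            }
            for e in sorted(self.entries.values(), key=lambda e: e.uri)
        ]
        return json.dumps(obj, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SemanticIndex":
        entries = {}
        for raw in json.loads(text):
            entries[raw["uri"]] = SemanticEntry(
                uri=raw["uri"],
                links={q: set(ids) for q, ids in raw["links"].items()},
                content_terms=Counter(raw["content_terms"]),
            )
        return cls(entries)


def build_semantic_index(corpus: Iterable, lexicon: Lexicon) -> SemanticIndex:
    """One entry per distinct URI in any model representation.

    URIs absent from the lexicon get entries with empty content — they are
    still reachable by direct URI queries, just not by keyword.
    """
    entries: dict[str, SemanticEntry] = {}
    for rep in corpus:
        for _feature, uri_entries in rep.uri_assignments.items():
            for uri, qualified in uri_entries:
                entry = entries.get(uri)
                if entry is None:
                    entry = entries[uri] = SemanticEntry(
                        uri=uri,
                        content_terms=Counter(tokenize(lexicon.describe(uri))),
                    )
                entry.links.setdefault(qualified, set()).add(rep.model_id)
    return SemanticIndex(entries)


def resolve_terms(
    index: SemanticIndex,
    terms: Iterable[str],
    qualifier_filter: set[str] | None = None,
    k: int = 10,
) -> list[WeightedURI]:
    """Map keywords to the top-*k* URIs by tf-idf cosine over entry content.

    With a qualifier filter only entries linked to some model under one of
    the named (bare) qualifiers are kept.  Zero-score entries are dropped;
    ties break by ascending URI text.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    query = Counter(terms)
    if not query:
        return []
    q_vec = {t: tf_weight(c) * index.idf(t) for t, c in query.items()}
    q_norm = math.sqrt(sum(w * w for w in q_vec.values()))
    scored: list[WeightedURI] = []
    for entry in index.entries.values():
        if qualifier_filter is not None:
            matched = entry.bare_qualifiers() & qualifier_filter
            if not matched:
                continue
        else:
            matched = entry.bare_qualifiers()
        dot = sum(
            w * tf_weight(entry.content_terms[t]) * index.idf(t)
            for t, w in q_vec.items()
            if t in entry.content_terms
        )
        if dot <= 0.0:
            continue
        norm = index._content_norm(entry)
        weight = dot / (q_norm * norm) if norm > 0 else 0.0
        if weight > 0.0:
            scored.append(
                WeightedURI(uri=entry.uri, weight=weight, matched_qualifiers=set(matched))
            )
    scored.sort(key=lambda w: (-w.weight, w.uri))
    return scored[:k]


def lookup_models(
    index: SemanticIndex, uri: str, qualifier: str | None = None
) -> set[str]:
    """Models linking *uri*, optionally restricted to one bare qualifier."""
    entry = index.entries.get(normalize_urn(uri))
    if entry is None:
        return set()
    return entry.models(qualifier)
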