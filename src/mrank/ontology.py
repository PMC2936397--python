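"""Ontology-based query expansion.

A query term matching an ontology class by name or exact synonym is
expanded to the names and synonyms of all classes within a bounded
undirected graph distance, each carrying a multiplicatively decayed weight
``decay ** distance`` (optionally modulated per relation label).  Expansions
let a search for "caffeine" also reach models annotated with the
structurally related xanthine, ranked lower than direct hits.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

_SYNONYM_TEXT = re.compile(r'"([^"]*)"')


class OBOError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """Directed term graph (child -> parent edges labeled is_a/part_of)."""

    graph: nx.MultiDiGraph
    name: str = ""
    _by_label: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_label:
            for term_id, data in self.graph.nodes(data=True):
                for label in self.labels_of(term_id):
                    self._by_label.setdefault(label, set()).add(term_id)

    def labels_of(self, term_id: str) -> list[str]:
        data = self.graph.nodes[term_id]
        labels = []
        name = data.get("name")
        if name:
            labels.append(name.strip().lower())
        for raw in data.get("synonym", ()):
            m = _SYNONYM_TEXT.search(raw)
            if m and m.group(1):
                labels.append(m.group(1).strip().lower())
        return labels

    def find(self, label: str) -> set[str]:
        return set(self._by_label.get(label.strip().lower(), ()))


def load_obo(document: str) -> OntologyGraph:
    """Parse OBO 1.2 flat-file text (or a path to one) into a graph.

    Obsolete terms are excluded.  Raises :class:`OBOError` on unparseable
    stanzas, naming the offending line where the underlying parser does.
    """
    try:
        if "\n" in document or "[Term]" in document:
            graph = obonet.read_obo(io.StringIO(document))
        else:
            graph = obonet.read_obo(document)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OBOError(f"cannot parse OBO document: {exc}") from exc
    name = graph.graph.get("name", "") or graph.graph.get("ontology", "") or ""
    return OntologyGraph(graph=graph, name=str(name))


@dataclass
class ExpandedTerm:
    term_text: str  # lowercase token sequence (space-joined)
    weight: float
    distance: int
    origin: str  # source ontology term id


def expand_term(
    ont: OntologyGraph,
    term: str,
    radius: int = 2,
    decay: float = 0.5,
    edge_weights: dict[str, float] | None = None,
) -> list[ExpandedTerm]:
    """All names/synonyms within undirected distance *radius* of *term*.

    The seed's own labels come back at distance 0 with weight 1; a term at
    distance d carries ``decay**d`` times the product of per-relation edge
    weights along the path (all 1 by default, so is_a and part_of count
    equally).  An unmatched term yields an empty expansion and the caller's
    query proceeds unexpanded.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must be in (0, 1)")
    seeds = ont.find(term)
    if not seeds:
        return []
    edge_weights = edge_weights or {}

    undirected: dict[str, list[tuple[str, str]]] = {}
    for u, v, key in ont.graph.edges(keys=True):
        undirected.setdefault(u, []).append((v, key))
        undirected.setdefault(v, []).append((u, key))

    # layered BFS keeping, per node, the best weight at its first (shortest)
    # distance — with uniform edge weights this is plain decay**distance.
    best: dict[str, tuple[int, float]] = {s: (0, 1.0) for s in seeds}
    frontier = dict.fromkeys(seeds, 1.0)
    for distance in range(1, radius + 1):
        nxt: dict[str, float] = {}
        for node, w in frontier.items():
            for neighbor, label in undirected.get(node, ()):
                cand = w * decay * edge_weights.get(label, 1.0)
                if neighbor in best and best[neighbor][0] < distance:
                    continue
                if neighbor not in nxt or cand > nxt[neighbor]:
                    nxt[neighbor] = cand
        for node, w in nxt.items():
            if node not in best:
                best[node] = (distance, w)
            elif best[node][0] == distance and w > best[node][1]:
                best[node] = (distance, w)
        frontier = nxt
        if not frontier:
            break

    out: list[ExpandedTerm] = []
    for term_id, (distance, weight) in best.items():
        for label in ont.labels_of(term_id):
            out.append(
                ExpandedTerm(
                    term_text=" ".join(label.split()),
                    weight=weight,
                    distance=distance,
                    origin=term_id,
                )
            )
    out.sort(key=lambda e: (e.distance, -e.weight, e.term_text, e.origin))
    return out
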