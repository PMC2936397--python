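"""Independent brute-force reference implementations for the tests.

Everything here recomputes scores directly from raw model representations
with plain loops — no inverted index, no reuse of the library's scoring
path — so it can serve as an oracle for the production ranker.
"""

from __future__ import annotations

import math

from mrank.corpus import ModelRepresentation, parse_date


def bf_df(reps: list[ModelRepresentation], feature: str, term: str) -> int:
    return sum(1 for r in reps if r.assignments.get(feature, {}).get(term, 0) > 0)


def bf_idf(reps: list[ModelRepresentation], feature: str, term: str) -> float:
    return 1.0 + math.log(len(reps) / (1.0 + bf_df(reps, feature, term)))


def bf_term_weight(
    reps: list[ModelRepresentation], rep: ModelRepresentation, feature: str, term: str
) -> float:
    count = rep.assignments.get(feature, {}).get(term, 0)
    if count == 0:
        return 0.0
    return math.sqrt(count) * bf_idf(reps, feature, term)


def bf_field_norm(
    reps: list[ModelRepresentation], rep: ModelRepresentation, feature: str
) -> float:
    terms = rep.assignments.get(feature, {})
    return math.sqrt(
        sum(bf_term_weight(reps, rep, feature, t) ** 2 for t in terms)
    )


def _bf_wildcard_expand(reps, feature: str, token: str) -> list[str]:
    if not token.endswith("*"):
        return [token]
    prefix = token[:-1]
    vocab = set()
    for r in reps:
        vocab |= set(r.assignments.get(feature, {}))
    return sorted(t for t in vocab if t.startswith(prefix))


def bf_clause_matches(reps, clause) -> set[str]:
    """Exhaustive per-model clause evaluation (set algebra oracle)."""
    out = set()
    for r in reps:
        if clause.kind == "term":
            field = r.assignments.get(clause.feature, {})
            hit = False
            for term, _b in clause.terms:
                ok = True
                for tok in term.split():
                    expansions = _bf_wildcard_expand(reps, clause.feature, tok)
                    if not any(field.get(e, 0) > 0 for e in expansions):
                        ok = False
                        break
                if ok:
                    hit = True
                    break
            if hit:
                out.add(r.model_id)
        elif clause.kind == "uri":
            entries = r.uri_assignments.get(clause.feature, [])
            for uri, qualified in entries:
                if any(uri == u for u, _b in clause.uris):
                    bare = qualified.split("_", 1)[-1]
                    if (
                        clause.qualifier_restriction is None
                        or bare in clause.qualifier_restriction
                    ):
                        out.add(r.model_id)
        elif clause.kind == "date":
            start, end = clause.date_range
            for term in r.assignments.get(clause.feature, {}):
                try:
                    d = parse_date(term)
                except ValueError:
                    continue
                if (start is None or d >= start) and (end is None or d <= end):
                    out.add(r.model_id)
    return out


def bf_candidates(reps, query) -> set[str]:
    must_groups: dict[object, set[str]] = {}
    must_sets = []
    should = set()
    must_not = set()
    for clause in query.clauses:
        matches = bf_clause_matches(reps, clause)
        if clause.occurrence == "MUST_NOT":
            must_not |= matches
        elif clause.occurrence == "MUST":
            if clause.group is not None:
                must_groups.setdefault(clause.group, set()).update(matches)
            else:
                must_sets.append(matches)
        else:
            should |= matches
    must_sets.extend(must_groups.values())
    if must_sets:
        cands = {r.model_id for r in reps}
        for s in must_sets:
            cands &= s
    else:
        cands = should
    return cands - must_not


def bf_score(reps, rep: ModelRepresentation, query, weights) -> float:
    """Recompute one candidate's score from scratch."""
    total = 0.0
    for clause in query.clauses:
        if clause.occurrence == "MUST_NOT":
            continue
        if clause.kind == "term":
            norm = bf_field_norm(reps, rep, clause.feature)
            if norm == 0.0:
                continue
            s = 0.0
            for term, boost in clause.terms:
                for tok in term.split():
                    for expanded in _bf_wildcard_expand(reps, clause.feature, tok):
                        s += boost * bf_term_weight(reps, rep, clause.feature, expanded)
            sim = s / norm
        elif clause.kind == "uri":
            sim = 0.0
            for uri, boost in clause.uris:
                quals = [
                    q.split("_", 1)[-1]
                    for u, q in rep.uri_assignments.get(clause.feature, [])
                    if u == uri
                ]
                if clause.qualifier_restriction is not None:
                    quals = [q for q in quals if q in clause.qualifier_restriction]
                if quals:
                    sim += boost * max(weights.qualifier_weights[q] for q in quals)
        else:  # date
            sim = 1.0 if rep.model_id in bf_clause_matches(reps, clause) else 0.0
        total += weights.feature_weights[clause.feature] * clause.boost * sim
    return total


def bf_rank(reps, query, weights) -> list[tuple[str, float]]:
    by_id = {r.model_id: r for r in reps}
    cands = bf_candidates(reps, query)
    scored = [(m, bf_score(reps, by_id[m], query, weights)) for m in cands]
    scored.sort(key=lambda x: (-x[1], x[0]))
    return scored
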