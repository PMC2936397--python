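import datetime
import math
import random
from collections import Counter

import pytest

from _oracle import bf_candidates, bf_field_norm, bf_rank
from mrank.corpus import ModelRepresentation
from mrank.query import AssembledQuery, Clause
from mrank.retrieval import (
    DuplicateModelError,
    ModelIndex,
    UnknownModelError,
    UnsatisfiableQueryError,
    WeightConfig,
    build_model_index,
    explain,
    rank,
    retrieve_candidates,
    term_weight,
)


def rep(model_id, assignments=None, uris=None):
    return ModelRepresentation(
        model_id=model_id,
        assignments={f: Counter(t) for f, t in (assignments or {}).items()},
        uri_assignments=uris or {},
    )


@pytest.fixture()
def toy_reps():
    return [
        rep("m1", {"species": ["caffeine", "atp"], "author": ["jane", "roe"],
                   "compartment": ["gut"], "creationDate": ["2009-05-01"]}),
        rep("m2", {"species": ["caffeine"], "author": ["john", "doe"],
                   "creationDate": ["2008-01-01"]}),
        rep("m3", {"species": ["xanthine"], "author": ["ada", "stone"],
                   "creationDate": ["2009-07-01"]},
            {"speciesURI": [("urn:miriam:kegg.compound:C00385", "bqbiol_is")]}),
        rep("m4", {"species": ["glucose", "atp"], "author": ["jane", "roe"],
                   "creationDate": ["2010-02-01"]}),
    ]


@pytest.fixture()
def toy_index(toy_reps):
    return build_model_index(toy_reps)


class TestBuild:
    def test_shared_term_posting(self, toy_index):
        assert set(toy_index.postings[("species", "caffeine")]) == {"m1", "m2"}

    def test_empty_corpus(self):
        assert build_model_index([]).doc_count == 0

    def test_duplicate_model_id_rejected(self):
        with pytest.raises(DuplicateModelError):
            build_model_index([rep("m1"), rep("m1")])

    def test_norms_match_bruteforce(self, toy_reps, toy_index):
        for r in toy_reps:
            for feature in r.assignments:
                assert toy_index.field_norm(r.model_id, feature) == pytest.approx(
                    bf_field_norm(toy_reps, r, feature), rel=1e-12
                )

    def test_serialization_round_trip_bit_identical(self, toy_index):
        text = toy_index.to_json()
        clone = ModelIndex.from_json(text)
        assert clone.to_json() == text
        assert clone.field_norm("m1", "species") == toy_index.field_norm("m1", "species")


class TestTermWeight:
    def test_single_occurrence_in_one_of_two_models(self):
        index = build_model_index(
            [rep("a", {"species": ["pep"]}), rep("b", {"species": ["atp"]})]
        )
        # tf = 1, idf = 1 + ln(2 / (1 + 1)) = 1
        assert term_weight(index, "species", "pep", "a") == pytest.approx(1.0)

    def test_absent_term_is_zero(self, toy_index):
        assert term_weight(toy_index, "species", "zyzzyva", "m1") == 0.0

    def test_unknown_model_raises(self, toy_index):
        with pytest.raises(UnknownModelError):
            term_weight(toy_index, "species", "caffeine", "nope")

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_ubiquitous_term_idf_below_one_and_decreasing(self, n):
        index = build_model_index(
            [rep(f"m{i}", {"species": ["water"]}) for i in range(n)]
        )
        idf = index.idf("species", "water")
        assert idf == pytest.approx(1 + math.log(n / (n + 1)))
        assert idf < 1

    def test_idf_antimonotone_in_document_frequency(self):
        reps = [rep(f"m{i}", {"species": ["rare"] if i == 0 else ["common"]})
                for i in range(10)]
        for r in reps[5:]:
            r.assignments["species"]["rare2"] = 1
        index = build_model_index(reps)
        assert index.idf("species", "rare") > index.idf("species", "rare2")
        assert index.idf("species", "rare2") > index.idf("species", "common")


def term_clause(feature, terms, occ="SHOULD", boost=1.0, group=None):
    return Clause(feature=feature, occurrence=occ, kind="term", boost=boost,
                  terms=tuple((t, 1.0) for t in terms), group=group)


class TestRetrieveCandidates:
    def test_must_not_author(self, toy_index):
        query = AssembledQuery(clauses=[
            term_clause("species", ["caffeine", "xanthine", "glucose"]),
            term_clause("author", ["john doe"], occ="MUST_NOT"),
        ])
        result = retrieve_candidates(toy_index, query)
        assert "m2" not in result
        assert result == {"m1", "m3", "m4"}

    def test_must_with_no_match_is_empty(self, toy_index):
        query = AssembledQuery(clauses=[term_clause("species", ["zyzzyva"], occ="MUST")])
        assert retrieve_candidates(toy_index, query) == set()

    def test_unsatisfiable_query_raises(self, toy_index):
        query = AssembledQuery(clauses=[term_clause("author", ["x"], occ="MUST_NOT")])
        with pytest.raises(UnsatisfiableQueryError):
            retrieve_candidates(toy_index, query)

    def test_mixed_query_matches_set_algebra_oracle(self, toy_reps, toy_index):
        query = AssembledQuery(clauses=[
            term_clause("species", ["caffeine", "xanthine"], occ="MUST"),
            term_clause("compartment", ["gut"]),
            term_clause("author", ["doe"], occ="MUST_NOT"),
        ])
        assert retrieve_candidates(toy_index, query) == bf_candidates(toy_reps, query)

    def test_wildcard_prefix_match(self, toy_index):
        query = AssembledQuery(clauses=[term_clause("species", ["caff*"], occ="MUST")])
        assert retrieve_candidates(toy_index, query) == {"m1", "m2"}

    def test_date_range(self, toy_index):
        clause = Clause(feature="creationDate", occurrence="MUST", kind="date",
                        date_range=(datetime.date(2009, 1, 1), None))
        query = AssembledQuery(clauses=[clause])
        assert retrieve_candidates(toy_index, query) == {"m1", "m3", "m4"}

    def test_composite_group_satisfied_by_either_member(self, toy_index):
        literal = term_clause("species", ["caffeine"], occ="MUST", group=1)
        uri = Clause(feature="speciesURI", occurrence="MUST", kind="uri",
                     uris=(("urn:miriam:kegg.compound:C00385", 0.5),), group=1)
        query = AssembledQuery(clauses=[literal, uri])
        assert retrieve_candidates(toy_index, query) == {"m1", "m2", "m3"}


class TestRank:
    def test_is_outranks_is_described_by(self, weights):
        uri = "urn:miriam:obo.chebi:CHEBI%3A27732"
        reps = [
            rep("strong", {"species": ["a"]}, {"speciesURI": [(uri, "bqbiol_is")]}),
            rep("weak", {"species": ["a"]}, {"speciesURI": [(uri, "bqbiol_isDescribedBy")]}),
        ]
        index = build_model_index(reps)
        query = AssembledQuery(clauses=[
            Clause(feature="speciesURI", occurrence="MUST", kind="uri", uris=((uri, 1.0),))
        ])
        result = rank(index, retrieve_candidates(index, query), query, weights)
        assert [r.model_id for r in result] == ["strong", "weak"]
        assert result[0].score > result[1].score
        assert result[0].score == pytest.approx(2.0 * 5)  # Q(is) * W(speciesURI)
        assert result[1].score == pytest.approx(1.0 * 5)

    def test_identical_models_tie_broken_by_id(self, weights):
        reps = [rep("b", {"species": ["atp"]}), rep("a", {"species": ["atp"]})]
        index = build_model_index(reps)
        query = AssembledQuery(clauses=[term_clause("species", ["atp"])])
        result = rank(index, retrieve_candidates(index, query), query, weights)
        assert result[0].score == pytest.approx(result[1].score)
        assert [r.model_id for r in result] == ["a", "b"]

    def test_matching_more_should_clauses_increases_score(self, toy_index, weights):
        narrow = AssembledQuery(clauses=[term_clause("species", ["caffeine"])])
        wide = AssembledQuery(clauses=[
            term_clause("species", ["caffeine"]),
            term_clause("compartment", ["gut"]),
        ])
        narrow_score = {
            r.model_id: r.score
            for r in rank(toy_index, retrieve_candidates(toy_index, narrow), narrow, weights)
        }
        wide_score = {
            r.model_id: r.score
            for r in rank(toy_index, retrieve_candidates(toy_index, wide), wide, weights)
        }
        assert wide_score["m1"] > narrow_score["m1"]  # m1 also matches gut
        assert wide_score["m2"] == pytest.approx(narrow_score["m2"])

    def test_scores_match_bruteforce(self, toy_reps, toy_index, weights):
        query = AssembledQuery(clauses=[
            term_clause("species", ["caffeine", "atp"], occ="MUST"),
            term_clause("author", ["jane"]),
            Clause(feature="creationDate", occurrence="SHOULD", kind="date",
                   date_range=(datetime.date(2009, 1, 1), datetime.date(2009, 12, 31))),
        ])
        mine = rank(toy_index, retrieve_candidates(toy_index, query), query, weights)
        expected = bf_rank(toy_reps, query, weights)
        assert [(r.model_id) for r in mine] == [m for m, _s in expected]
        for r, (_m, s) in zip(mine, expected):
            assert r.score == pytest.approx(s, rel=1e-12)

    def test_boost_monotonicity(self, toy_index, weights):
        def order(boost):
            q = AssembledQuery(clauses=[
                term_clause("species", ["caffeine", "xanthine", "glucose"]),
                term_clause("compartment", ["gut"], boost=boost),
            ])
            return [r.model_id for r in
                    rank(toy_index, retrieve_candidates(toy_index, q), q, weights)]

        low = order(1.0)
        high = order(50.0)
        assert high.index("m1") <= low.index("m1")  # only m1 matches gut


class TestExplain:
    def test_single_clause_contribution_equals_score(self, toy_index, weights):
        query = AssembledQuery(clauses=[term_clause("species", ["xanthine"])])
        (result,) = rank(toy_index, retrieve_candidates(toy_index, query), query, weights)
        assert len(result.explanation) == 1
        assert result.explanation[0][1] == pytest.approx(result.score)

    def test_contributions_sum_to_score(self, toy_index, weights):
        query = AssembledQuery(clauses=[
            term_clause("species", ["caffeine"]),
            term_clause("author", ["jane"]),
            term_clause("compartment", ["gut"]),
        ])
        for result in rank(toy_index, retrieve_candidates(toy_index, query), query, weights):
            assert sum(c for _l, c in result.explanation) == pytest.approx(
                result.score, rel=1e-9
            )
            report = explain(result)
            assert result.model_id in report

    def test_date_only_match_is_reported(self, toy_index, weights):
        query = AssembledQuery(clauses=[
            term_clause("species", ["xanthine"]),
            Clause(feature="creationDate", occurrence="SHOULD", kind="date",
                   date_range=(datetime.date(2009, 1, 1), None)),
        ])
        results = {r.model_id: r for r in
                   rank(toy_index, retrieve_candidates(toy_index, query), query, weights)}
        labels = [l for l, _c in results["m3"].explanation]
        assert any("creationDate" in l for l in labels)
        # the date clause contributes exactly W(creationDate) * 1
        date_contrib = [c for l, c in results["m3"].explanation if "creationDate" in l]
        assert date_contrib == [pytest.approx(weights.feature("creationDate"))]


class TestWeightConfig:
    def test_qualifier_shared_across_vocabularies(self, weights):
        assert weights.qualifier("bqbiol_is") == weights.qualifier("bqmodel_is") == 2.0

    def test_unknown_qualifier_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(feature_weights={}, qualifier_weights={"bogus": 1.0})
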