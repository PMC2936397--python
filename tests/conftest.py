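import pytest

from mrank.corpus import featurize, parse_model
from mrank.fixtures import worked_example_fixture
from mrank.query import Engine
from mrank.retrieval import WeightConfig, build_model_index
from mrank.semantic_index import build_semantic_index


@pytest.fixture(scope="session")
def worked_example():
    """(reps, model_index, semantic_index, ontology, lexicon) for the
    caffeine example corpus."""
    corpus, lexicon, ontology = worked_example_fixture()
    reps = [featurize(parse_model(doc, mid)) for mid, doc in corpus]
    model_index = build_model_index(reps)
    semantic_index = build_semantic_index(reps, lexicon)
    return {
        "corpus": corpus,
        "lexicon": lexicon,
        "ontology": ontology,
        "reps": reps,
        "model_index": model_index,
        "semantic_index": semantic_index,
    }


@pytest.fixture(scope="session")
def weights():
    return WeightConfig.default()


@pytest.fixture()
def engine(worked_example, weights):
    return Engine(
        model_index=worked_example["model_index"],
        semantic_index=worked_example["semantic_index"],
        ontologies=[worked_example["ontology"]],
        weights=weights,
    )
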