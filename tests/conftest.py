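import numpy as np
import pytest

import mothra


@pytest.fixture(scope="session")
def fixture_corpus() -> list[str]:
    return mothra.generate_fixture_corpus(60, seed=1)


@pytest.fixture(scope="session")
def corpus_vocab(fixture_corpus) -> mothra.Vocabulary:
    return mothra.Vocabulary.from_corpus(fixture_corpus)


@pytest.fixture(scope="session")
def default_vocab() -> mothra.Vocabulary:
    return mothra.Vocabulary.default()


@pytest.fixture(scope="session")
def ngram_policy(fixture_corpus) -> mothra.NGramPolicy:
    return mothra.train_policy(
        fixture_corpus, mothra.PolicyConfig(max_length=40), kind="ngram"
    )


@pytest.fixture(scope="session")
def mock_evaluator() -> mothra.ObjectiveEvaluator:
    return mothra.ObjectiveEvaluator(
        [
            mothra.ObjectiveSpec("docking", "mock"),
            mothra.ObjectiveSpec("qed", "qed"),
            mothra.ObjectiveSpec("toxicity", "toxicity"),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
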