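"""Rollout policies: the count-based n-gram model against brute-force
frequency oracles, and the NumPy GRU against finite-difference gradients,
plus the shared distribution/rollout contracts."""

import numpy as np
import pytest

import mothra
from mothra.errors import (
    CheckpointError,
    EmptyCorpusError,
    PrefixContainsTerminatorError,
    UnknownTokenError,
)
from mothra.policy import GRUPolicy, NGramPolicy, PolicyConfig, prepare_sequences
from mothra.tokenizer import END_TOKEN, START_TOKEN, Vocabulary, tokenize, wrap

TINY_CFG = PolicyConfig(
    embedding_dim=8, hidden_dim=12, batch_size=8, epochs=5, seed=3, max_length=30
)


def _ngram_oracle(sequences, vocab, context, alpha=1.0):
    """Brute-force add-alpha conditional frequency for one context."""
    counts = {}
    total = 0
    L = len(context)
    for seq in sequences:
        for j in range(1, len(seq)):
            if j - L >= 0 and tuple(seq[j - L : j]) == tuple(context):
                counts[seq[j]] = counts.get(seq[j], 0) + 1
                total += 1
    V = len(vocab)
    return np.array(
        [(counts.get(t, 0) + alpha) / (total + alpha * V) for t in vocab.tokens]
    )


def test_ngram_matches_count_oracle_on_every_seen_context():
    """Distributions equal brute-force conditional frequencies with add-one
    smoothing for every context occurring in a 10-sequence corpus."""
    corpus = ["CC", "CO", "CCO", "OCC", "CN", "NCC", "CCN", "OCO", "NCN", "CCC"]
    vocab = Vocabulary.from_corpus(corpus)
    policy = mothra.train_policy(corpus, PolicyConfig(), kind="ngram")
    sequences = [wrap(tokenize(s, vocab).tokens) for s in corpus]
    checked = 0
    for seq in sequences:
        for j in range(1, len(seq) - 1):  # prefixes without the terminator
            prefix = seq[: j + 1]
            if END_TOKEN in prefix:
                continue
            L = min(policy.order - 1, len(prefix))
            expected = _ngram_oracle(sequences, vocab, prefix[-L:])
            np.testing.assert_allclose(
                policy.next_token_distribution(prefix), expected, atol=1e-12
            )
            checked += 1
    assert checked > 10


def test_ngram_two_sequence_corpus_counts():
    """On corpus {CC, CO} the distribution after '&C' reflects the two
    observed continuations (C once, O once) under add-one smoothing."""
    corpus = ["CC", "CO"]
    vocab = Vocabulary.from_corpus(corpus)
    policy = mothra.train_policy(corpus, PolicyConfig(), kind="ngram")
    p = policy.next_token_distribution([START_TOKEN, "C"])
    sequences = [wrap(tokenize(s, vocab).tokens) for s in corpus]
    expected = _ngram_oracle(sequences, vocab, (START_TOKEN, "C"))
    np.testing.assert_allclose(p, expected, atol=1e-12)
    # both continuations equally likely, everything else smoothing mass only
    assert p[vocab.index_of["C"]] == pytest.approx(p[vocab.index_of["O"]])
    assert p[vocab.index_of["C"]] > p[vocab.index_of[END_TOKEN]]


def test_ngram_unseen_context_is_uniform():
    corpus = ["CC", "CO"]
    vocab = Vocabulary.from_corpus(corpus)
    policy = mothra.train_policy(corpus, PolicyConfig(), kind="ngram")
    p = policy.next_token_distribution([START_TOKEN, "O"])  # '&O' never seen
    np.testing.assert_allclose(p, np.full(len(vocab), 1 / len(vocab)))


def test_ngram_unsmoothed_single_corpus_rollout_is_forced(rng):
    """With no smoothing, a single-sequence corpus admits exactly one path."""
    policy = mothra.train_policy(
        ["CCO"], PolicyConfig(ngram_alpha=0.0), kind="ngram"
    )
    for _ in range(5):
        roll = policy.rollout([START_TOKEN], rng)
        assert mothra.detokenize(roll) == "CCO"
        assert roll.terminated


@pytest.mark.parametrize("kind", ["ngram", "recurrent"])
def test_distributions_normalize_and_repeat(fixture_corpus, kind):
    cfg = TINY_CFG
    policy = mothra.train_policy(fixture_corpus[:20], cfg, kind=kind)
    prefix = [START_TOKEN, "C", "C"]
    p1 = policy.next_token_distribution(prefix)
    p2 = policy.next_token_distribution(prefix)
    assert np.all(p1 >= 0)
    assert abs(p1.sum() - 1.0) < 1e-9
    np.testing.assert_array_equal(p1, p2)


@pytest.mark.parametrize("kind", ["ngram", "recurrent"])
def test_rollout_is_seeded_and_capped(fixture_corpus, kind):
    policy = mothra.train_policy(fixture_corpus[:20], TINY_CFG, kind=kind)
    r1 = policy.rollout([START_TOKEN], np.random.default_rng(7))
    r2 = policy.rollout([START_TOKEN], np.random.default_rng(7))
    assert r1.tokens == r2.tokens
    for seed in range(10):
        roll = policy.rollout([START_TOKEN], np.random.default_rng(seed))
        assert len(roll) <= policy.max_length
        assert list(roll.tokens)[: 1] == [START_TOKEN]


def test_prefix_contract_errors(ngram_policy, rng):
    with pytest.raises(PrefixContainsTerminatorError):
        ngram_policy.next_token_distribution([START_TOKEN, "C", END_TOKEN])
    with pytest.raises(ValueError):
        ngram_policy.next_token_distribution(["C"])  # missing start token
    with pytest.raises(ValueError):
        ngram_policy.rollout([START_TOKEN] + ["C"] * 100, rng)  # too long


def test_empty_corpus_and_unknown_token_errors(default_vocab):
    with pytest.raises(EmptyCorpusError):
        mothra.train_policy([], TINY_CFG)
    with pytest.raises(UnknownTokenError) as exc:
        mothra.train_policy(
            ["CCO", "CClC"], TINY_CFG, vocabulary=default_vocab
        )
    assert exc.value.line == 2


def test_gru_loss_decreases_over_first_epochs(fixture_corpus):
    """Training loss strictly decreases over the first three epochs on the
    fixture corpus at fixed seed."""
    policy = mothra.train_policy(fixture_corpus[:50], TINY_CFG)
    losses = policy.loss_history
    assert len(losses) == TINY_CFG.epochs
    assert losses[0] > losses[1] > losses[2]


def test_gru_gradients_match_finite_differences():
    """BPTT gradients of the masked cross-entropy agree with central
    finite differences on a tiny two-layer model."""
    corpus = ["CC", "CO", "CN", "OCC"]
    vocab = Vocabulary.from_corpus(corpus)
    cfg = PolicyConfig(
        embedding_dim=5, hidden_dim=7, num_recurrent_layers=2,
        batch_size=4, epochs=1, seed=9,
    )
    policy = GRUPolicy(vocab, cfg)
    encoded = prepare_sequences(corpus, vocab)
    T = max(len(s) for s in encoded)
    ids = np.full((len(encoded), T), -1, dtype=int)
    for b, s in enumerate(encoded):
        ids[b, : len(s)] = s
    mask = (ids[:, 1:] >= 0).astype(float)
    ids = np.where(ids >= 0, ids, 0)
    _, grads = policy._loss_and_grads(ids, mask)
    eps = 1e-6
    rng = np.random.default_rng(0)
    for name, param in policy.params.items():
        flat = param.reshape(-1)
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = policy._loss_and_grads(ids, mask)
            flat[idx] = orig - eps
            lm, _ = policy._loss_and_grads(ids, mask)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert abs(numeric - analytic) < 1e-5 * max(1.0, abs(numeric)), name


def test_checkpoint_round_trip_and_vocab_mismatch(tmp_path, fixture_corpus):
    policy = mothra.train_policy(fixture_corpus[:20], TINY_CFG)
    path = tmp_path / "policy.npz"
    policy.save(path)
    loaded = GRUPolicy.load(path)
    prefix = [START_TOKEN, "C"]
    np.testing.assert_array_equal(
        policy.next_token_distribution(prefix),
        loaded.next_token_distribution(prefix),
    )
    other = Vocabulary.from_corpus(["CS", "SS"])
    with pytest.raises(CheckpointError):
        GRUPolicy.load(path, expected_vocabulary=other)
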