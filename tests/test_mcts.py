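"""Tree search: UCB arithmetic, hypervolume-scalarized node values,
selection/expansion/simulation/backpropagation contracts, and whole-run
invariants (determinism, front consistency, visit conservation)."""

import math

import numpy as np
import pytest

import mothra
from mothra.mcts import (
    SearchNode,
    backpropagate,
    expand,
    node_value,
    records_to_dataframe,
    select,
    simulate,
    ucb_vector,
)
from mothra.pareto import ParetoArchive
from mothra.policy import PolicyConfig
from mothra.tokenizer import END_TOKEN, START_TOKEN


def child_with_stats(parent, token, n, mean):
    node = SearchNode(token, parent, len(mean))
    node.n_s = n
    node.mean_reward = np.asarray(mean, dtype=float)
    parent.children.append(node)
    return node


def test_ucb_vector_arithmetic():
    root = SearchNode(START_TOKEN, None, 2)
    node = child_with_stats(root, "C", 2, (0.5, 0.5))
    u = ucb_vector(node, parent_visits=10, c=np.ones(2))
    expected = 0.5 + math.sqrt(2 * math.log(10) / 2)
    np.testing.assert_allclose(u, [expected, expected])
    assert expected == pytest.approx(2.01742, abs=1e-5)
    # pure exploitation limit
    np.testing.assert_allclose(
        ucb_vector(node, 10, np.zeros(2)), node.mean_reward
    )
    # unvisited nodes outrank everything
    fresh = child_with_stats(root, "N", 0, (0.0, 0.0))
    assert np.all(np.isinf(ucb_vector(fresh, 10, np.ones(2))))


def test_ucb_exploration_bonus_decreases_for_only_child():
    root = SearchNode(START_TOKEN, None, 1)
    node = child_with_stats(root, "C", 1, (0.0,))
    bonuses = []
    for n in (3, 10, 50, 200):  # sqrt(2 ln n / n) decreases beyond n = e
        node.n_s = n
        bonuses.append(ucb_vector(node, n, np.ones(1))[0])
    assert all(a > b for a, b in zip(bonuses, bonuses[1:]))


def test_node_value_empty_front_is_box_volume():
    root = SearchNode(START_TOKEN, None, 2)
    node = child_with_stats(root, "C", 4, (0.3, 0.6))
    front = ParetoArchive(dim=2)
    u = np.clip(ucb_vector(node, 4, np.zeros(2)), 0, 1)
    assert node_value(node, front, np.zeros(2), np.zeros(2), 4) == pytest.approx(
        np.prod(u)
    )


def test_node_value_union_box():
    """A UCB point dominating the whole front scores its own box volume."""
    root = SearchNode(START_TOKEN, None, 2)
    node = child_with_stats(root, "C", 100_000, (0.9, 0.9))
    front = ParetoArchive(dim=2)
    front.add((0.5, 0.6))
    front.add((0.6, 0.5))
    w = node_value(node, front, np.zeros(2), np.zeros(2), 100_000)
    assert w == pytest.approx(0.81, abs=1e-9)


def test_node_value_penalizes_dominated_points():
    root = SearchNode(START_TOKEN, None, 2)
    node = child_with_stats(root, "C", 10_000, (0.2, 0.2))
    front = ParetoArchive(dim=2)
    front.add((0.9, 0.9))
    w = node_value(node, front, np.zeros(2), np.zeros(2), 10_000)
    assert w < front.hypervolume(np.zeros(2))


def test_select_fresh_tree_returns_root():
    root = SearchNode(START_TOKEN, None, 2)
    cfg = mothra.SearchConfig(max_iterations=1)
    path = select(root, ParetoArchive(dim=2), cfg, np.random.default_rng(0), 2)
    assert path == [root]


def test_select_prefers_higher_node_value():
    root = SearchNode(START_TOKEN, None, 2)
    root.n_s = 20
    root.expanded = True
    lo = child_with_stats(root, "C", 10, (0.2, 0.2))
    hi = child_with_stats(root, "N", 10, (0.7, 0.7))
    front = ParetoArchive(dim=2)
    front.add((0.5, 0.5))
    cfg = mothra.SearchConfig(max_iterations=1, c=0.1)
    path = select(root, front, cfg, np.random.default_rng(0), 2)
    assert path[-1] is hi


def test_select_tie_break_is_uniform():
    """Identical children are chosen ~50/50 over 1000 seeded selections."""
    counts = {"C": 0, "N": 0}
    rng = np.random.default_rng(99)
    root = SearchNode(START_TOKEN, None, 2)
    root.n_s = 20
    root.expanded = True
    child_with_stats(root, "C", 10, (0.5, 0.5))
    child_with_stats(root, "N", 10, (0.5, 0.5))
    front = ParetoArchive(dim=2)
    front.add((0.4, 0.4))
    cfg = mothra.SearchConfig(max_iterations=1)
    for _ in range(1000):
        path = select(root, front, cfg, rng, 2)
        counts[path[-1].token] += 1
    assert abs(counts["C"] / 1000 - 0.5) < 0.05


def test_expand_follows_policy_argmax():
    policy = mothra.train_policy(["CCO"], PolicyConfig(), kind="ngram")
    cfg = mothra.SearchConfig(max_iterations=1, max_length=20)
    root = SearchNode(START_TOKEN, None, 2)
    child = expand(root, policy, cfg, 2)
    assert child.token == "C"
    second = expand(root, policy, cfg, 2)
    assert second.token != "C"  # no duplicate children


def test_expand_at_length_cap_only_terminator():
    policy = mothra.train_policy(["CCO"], PolicyConfig(), kind="ngram")
    cfg = mothra.SearchConfig(max_iterations=1, max_length=4)
    root = SearchNode(START_TOKEN, None, 2)
    a = expand(root, policy, cfg, 2)          # prefix '&C', length 2
    b = expand(a, policy, cfg, 2)             # prefix '&CC', length 3
    # b sits at max_length - 1: its only possible child closes the string
    c = expand(b, policy, cfg, 2)
    assert c.token == END_TOKEN
    assert b.expanded  # terminator was the only candidate


def test_expand_floor_limits_branching():
    policy = mothra.train_policy(["CCO", "CCN"], PolicyConfig(), kind="ngram")
    cfg = mothra.SearchConfig(
        max_iterations=1, max_length=20, expansion_prob_floor=0.2
    )
    root = SearchNode(START_TOKEN, None, 2)
    tokens = set()
    with pytest.raises(mothra.errors.NoExpandableTokenError):
        for _ in range(10):
            tokens.add(expand(root, policy, cfg, 2).token)
    assert tokens == {"C"}  # only the high-probability continuation
    assert root.expanded


def _terminal_path(tokens):
    """Hand-build a root->leaf path whose tokens spell a complete string."""
    dim = 3
    root = SearchNode(START_TOKEN, None, dim)
    path = [root]
    for tok in tokens:
        node = SearchNode(tok, path[-1], dim)
        path[-1].children.append(node)
        path.append(node)
    return path


def test_simulate_invalid_string_scores_zero(ngram_policy, mock_evaluator, rng):
    path = _terminal_path(["C", "C", "(", END_TOKEN])
    front = ParetoArchive(dim=3)
    record, reward = simulate(
        path, ngram_policy, mock_evaluator, front, rng, {}, 0, 0
    )
    assert record.valid is False and record.passed_filter is False
    np.testing.assert_array_equal(reward, np.zeros(3))
    assert len(front) == 0


def test_simulate_filters_high_sa_molecules(ngram_policy, mock_evaluator, rng):
    tokens = list("CC1(C)CC2CCC1C2") + [END_TOKEN]  # SAscore above 3.5
    path = _terminal_path(tokens)
    front = ParetoArchive(dim=3)
    record, reward = simulate(
        path, ngram_policy, mock_evaluator, front, rng, {}, 0, 0
    )
    assert record.valid is True and record.passed_filter is False
    np.testing.assert_array_equal(reward, np.zeros(3))
    assert len(front) == 0


class CountingEvaluator:
    def __init__(self, inner):
        self.inner = inner
        self.calls = 0

    @property
    def dimension(self):
        return self.inner.dimension

    @property
    def objective_names(self):
        return self.inner.objective_names

    def canonicalize(self, s):
        return self.inner.canonicalize(s)

    def evaluate_smiles(self, s):
        self.calls += 1
        return self.inner.evaluate_smiles(s)


def test_simulate_caches_duplicate_canonical_smiles(
    ngram_policy, mock_evaluator, rng
):
    counting = CountingEvaluator(mock_evaluator)
    front = ParetoArchive(dim=3)
    cache = {}
    path1 = _terminal_path(["C", "C", "O", END_TOKEN])
    path2 = _terminal_path(["O", "C", "C", END_TOKEN])  # same molecule
    rec1, r1 = simulate(path1, ngram_policy, counting, front, rng, cache, 0, 0)
    rec2, r2 = simulate(path2, ngram_policy, counting, front, rng, cache, 1, 1)
    assert counting.calls == 1
    assert rec2.from_cache and not rec1.from_cache
    np.testing.assert_array_equal(r1, r2)
    assert rec1.canonical_smiles == rec2.canonical_smiles


def test_backpropagate_incremental_mean():
    root = SearchNode(START_TOKEN, None, 2)
    node = child_with_stats(root, "C", 1, (0.0, 0.0))
    backpropagate([node], np.array([1.0, 1.0]))
    assert node.n_s == 2
    np.testing.assert_allclose(node.mean_reward, [0.5, 0.5])


def test_backpropagate_conservation(rng):
    """After k updates the stored mean equals the arithmetic mean of the
    routed rewards to 1e-12."""
    root = SearchNode(START_TOKEN, None, 3)
    node = SearchNode("C", root, 3)
    root.children.append(node)
    routed = []
    for _ in range(200):
        r = rng.random(3)
        routed.append(r)
        backpropagate([root, node], r)
    np.testing.assert_allclose(
        node.mean_reward, np.mean(routed, axis=0), atol=1e-12
    )
    np.testing.assert_allclose(
        root.mean_reward, np.mean(routed, axis=0), atol=1e-12
    )
    assert node.n_s == root.n_s == 200


def _small_search(seed=5, iters=150):
    corpus = mothra.generate_fixture_corpus(40, seed=2)
    policy = mothra.train_policy(
        corpus, PolicyConfig(max_length=40), kind="ngram"
    )
    evaluator = mothra.ObjectiveEvaluator(
        [
            mothra.ObjectiveSpec("docking", "mock"),
            mothra.ObjectiveSpec("qed", "qed"),
        ]
    )
    cfg = mothra.SearchConfig(
        max_iterations=iters, max_length=40, seed=seed,
        checkpoint_schedule=(2, 5, 10),
    )
    return mothra.run_search(cfg, policy, evaluator), evaluator


def test_run_search_is_deterministic():
    """Fixed seed + deterministic objectives give byte-identical logs."""
    (res1, ev1) = _small_search()
    (res2, ev2) = _small_search()
    csv1 = records_to_dataframe(res1, ev1.objective_names).to_csv(index=False)
    csv2 = records_to_dataframe(res2, ev2.objective_names).to_csv(index=False)
    assert csv1 == csv2


def test_run_search_front_matches_batch_recomputation():
    res, _ = _small_search()
    rewards = [
        r.reward for r in res.records if r.valid and r.passed_filter
    ]
    assert rewards, "search produced no scored molecules"
    batch = mothra.pareto_front(rewards)
    assert {tuple(p) for p in res.front.points} == {tuple(p) for p in batch}


def test_run_search_snapshots_and_monotone_hypervolume():
    res, _ = _small_search()
    assert res.snapshots, "no snapshots emitted"
    counts = [s.molecule_count for s in res.snapshots]
    assert counts == sorted(counts)
    assert set(counts) <= {2, 5, 10}
    hvs = [s.hypervolume for s in res.snapshots]
    assert all(a <= b + 1e-12 for a, b in zip(hvs, hvs[1:]))


def test_run_search_visit_conservation():
    """Every simulation increments exactly the nodes on its path: for each
    node, n_s >= sum of child visits, and the path-terminations summed over
    the tree equal the iteration count."""
    res, _ = _small_search()
    terminations = 0
    stack = [res.root]
    while stack:
        node = stack.pop()
        child_total = sum(ch.n_s for ch in node.children)
        assert node.n_s >= child_total
        terminations += node.n_s - child_total
        stack.extend(node.children)
    assert res.root.n_s == res.config.max_iterations
    assert terminations == res.config.max_iterations


def test_single_objective_mode_matches_scalar_ucb1_ranking():
    """With one live objective plus a constant, the hypervolume node value
    ranks children exactly as scalar UCB1 on the live component."""
    const = 0.5
    rng = np.random.default_rng(3)
    for _ in range(20):
        root = SearchNode(START_TOKEN, None, 2)
        root.expanded = True
        means = rng.uniform(0.05, 0.45, size=4)
        visits = rng.integers(50, 400, size=4)
        for i, (m, n) in enumerate(zip(means, visits)):
            child_with_stats(root, f"t{i}", int(n), (m, const))
        root.n_s = int(visits.sum())
        front = ParetoArchive(dim=2)
        front.add((float(means.max()), const))
        c = np.array([0.05, 0.0])  # no exploration on the constant dummy
        values = [
            node_value(ch, front, np.zeros(2), c, root.n_s)
            for ch in root.children
        ]
        scalar_ucb1 = [
            m + 0.05 * math.sqrt(2 * math.log(root.n_s) / n)
            for m, n in zip(means, visits)
        ]
        assert np.argsort(values).tolist() == np.argsort(scalar_ucb1).tolist()
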