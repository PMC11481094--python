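"""Pareto multiobjective Monte Carlo tree search over SMILES token trees.

Each tree node holds one vocabulary token; the path from the root (start
token) to a node is a SMILES prefix.  Every iteration runs the four MCTS
steps:

* **selection** — descend by the hypervolume-scalarized node value: the
  component-wise UCB1 vector of a child, clipped to [0, 1]^d, is scored by
  the hypervolume it would add to the current Pareto front; dominated UCB
  points are instead penalized by their projection distance to the front.
* **expansion** — instantiate one new child per visit, candidates ordered by
  rollout-policy probability above a floor.
* **simulation** — the frozen policy completes the prefix; the string is
  sanitized, filtered on synthetic accessibility, evaluated into a reward
  vector, and the front updated.  Invalid or filtered strings earn the zero
  vector, which still counts as a visit so the tree learns to avoid them.
* **backpropagation** — visit counts and running mean reward vectors are
  updated along the path (incremental arithmetic mean).

With one live objective plus a constant second component the node value
orders children exactly as scalar UCB1, so the search degrades gracefully to
standard single-objective MCTS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .errors import NoExpandableTokenError
from .objectives import EvalResult
from .pareto import ParetoArchive, hypervolume, projection_distance
from .policy import Policy
from .tokenizer import END_TOKEN, START_TOKEN, detokenize

logger = logging.getLogger("mothra")


@dataclass
class SearchConfig:
    """Knobs of the tree search.

    ``c`` holds one exploration constant per reward component (a scalar is
    broadcast); ``z`` is the hypervolume reference point, the origin by
    default since rewards are shaped into [0, 1].  ``checkpoint_schedule``
    lists generated-molecule counts at which front snapshots are recorded.
    """

    c: float | Sequence[float] = 1.0
    z: Sequence[float] | None = None
    max_iterations: int = 1000
    max_length: int = 100
    expansion_prob_floor: float = 1e-3
    checkpoint_schedule: tuple[int, ...] = (100, 500, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        carr = np.atleast_1d(np.asarray(self.c, dtype=float))
        if np.any(carr < 0):
            raise ValueError("exploration constants must be non-negative")

    def c_vector(self, dim: int) -> np.ndarray:
        carr = np.atleast_1d(np.asarray(self.c, dtype=float))
        if carr.shape[0] == 1:
            return np.full(dim, carr[0])
        if carr.shape[0] != dim:
            raise ValueError("exploration-constant vector has wrong dimension")
        return carr

    def z_vector(self, dim: int) -> np.ndarray:
        if self.z is None:
            return np.zeros(dim)
        zv = np.asarray(self.z, dtype=float)
        if zv.shape[0] != dim:
            raise ValueError("reference point has wrong dimension")
        return zv


class SearchNode:
    """One tree node: token, children, visit count and running mean reward."""

    __slots__ = ("token", "parent", "children", "n_s", "mean_reward", "expanded")

    def __init__(self, token: str, parent: "SearchNode | None", dim: int):
        self.token = token
        self.parent = parent
        self.children: list[SearchNode] = []
        self.n_s = 0
        self.mean_reward = np.zeros(dim)
        self.expanded = False

    @property
    def is_terminal(self) -> bool:
        return self.token == END_TOKEN

    def prefix(self) -> list[str]:
        toks: list[str] = []
        node: SearchNode | None = self
        while node is not None:
            toks.append(node.token)
            node = node.parent
        return toks[::-1]

    def depth(self) -> int:
        d, node = 0, self.parent
        while node is not None:
            d, node = d + 1, node.parent
        return d


@dataclass
class GenerationRecord:
    """One evaluated rollout: the molecule, its raw objective values and
    shaped reward (present iff valid and filter-passing)."""

    iteration: int
    smiles: str
    canonical_smiles: str | None
    valid: bool
    passed_filter: bool
    raw_objectives: dict[str, float] = field(default_factory=dict)
    reward: np.ndarray | None = None
    from_cache: bool = False


class Evaluator(Protocol):
    """What simulate() needs from the objectives layer."""

    @property
    def dimension(self) -> int: ...
    @property
    def objective_names(self) -> list[str]: ...
    def evaluate_smiles(self, s: str) -> EvalResult: ...
    def canonicalize(self, s: str) -> str | None: ...


# ---------------------------------------------------------------------------
# the four steps
# ---------------------------------------------------------------------------

def ucb_vector(
    node: SearchNode, parent_visits: int, c: np.ndarray
) -> np.ndarray:
    """Component-wise UCB1: mean reward plus ``c_i * sqrt(2 ln N / n_s)``.

    Unvisited nodes get +infinity in every component so they are always
    tried first.
    """
    if node.n_s == 0:
        return np.full(len(c), np.inf)
    bonus = np.sqrt(2.0 * np.log(parent_visits) / node.n_s)
    return node.mean_reward + c * bonus


def node_value(
    node: SearchNode,
    front: ParetoArchive,
    z: np.ndarray,
    c: np.ndarray,
    parent_visits: int,
) -> float:
    """Scalar node score: hypervolume the clipped UCB vector would add to
    the front, or the front hypervolume minus the projection penalty when
    the UCB point is dominated."""
    u = np.clip(ucb_vector(node, parent_visits, c), 0.0, 1.0)
    if len(front) == 0:
        return float(np.prod(u - z))
    pts = front.points
    if not front.is_dominated(u):
        return hypervolume(np.vstack([pts, u]), z)
    return front.hypervolume(z) - projection_distance(u, pts)


def select(
    root: SearchNode,
    front: ParetoArchive,
    cfg: SearchConfig,
    rng: np.random.Generator,
    dim: int,
) -> list[SearchNode]:
    """Descend from the root by argmax node value until reaching a node that
    is not fully expanded or is terminal.  Ties (including among unvisited
    children) are broken by a seeded uniform draw."""
    c = cfg.c_vector(dim)
    z = cfg.z_vector(dim)
    path = [root]
    node = root
    while node.expanded and node.children and not node.is_terminal:
        unvisited = [ch for ch in node.children if ch.n_s == 0]
        if unvisited:
            node = unvisited[int(rng.integers(len(unvisited)))]
        else:
            parent_visits = max(node.n_s, 1)
            values = np.array(
                [node_value(ch, front, z, c, parent_visits) for ch in node.children]
            )
            best = np.flatnonzero(values >= values.max() - 1e-12)
            node = node.children[best[int(rng.integers(len(best)))]]
        path.append(node)
    return path


def expand(
    node: SearchNode, policy: Policy, cfg: SearchConfig, dim: int
) -> SearchNode:
    """Append one child: the highest-probability token not yet instantiated
    with policy probability at or above the floor.  At the length cap only
    the terminator is a candidate.  Marks the node expanded when no further
    candidates remain."""
    if node.is_terminal:
        raise NoExpandableTokenError("terminal nodes cannot be expanded")
    vocab = policy.vocabulary
    existing = {ch.token for ch in node.children}
    prefix_len = node.depth() + 1
    if prefix_len >= cfg.max_length - 1:  # a child may only close the string
        candidates = [] if END_TOKEN in existing else [END_TOKEN]
    else:
        probs = policy.next_token_distribution(node.prefix())
        order = np.argsort(-probs, kind="stable")
        candidates = [
            vocab.tokens[i]
            for i in order
            if probs[i] >= cfg.expansion_prob_floor
            and vocab.tokens[i] not in existing
            and vocab.tokens[i] != START_TOKEN
        ]
    if not candidates:
        node.expanded = True
        raise NoExpandableTokenError(
            f"no expandable token at prefix {detokenize(node.prefix())!r}"
        )
    child = SearchNode(candidates[0], node, dim)
    node.children.append(child)
    if len(candidates) == 1:
        node.expanded = True
    return child


def simulate(
    path: list[SearchNode],
    policy: Policy,
    evaluator: Evaluator,
    front: ParetoArchive,
    rng: np.random.Generator,
    cache: dict[str, EvalResult],
    iteration: int,
    record_id: int,
) -> tuple[GenerationRecord, np.ndarray]:
    """Complete the prefix with a policy rollout and evaluate the molecule.

    Valid, filter-passing molecules yield their reward vector and update the
    front; invalid or filtered rollouts yield the zero vector.  Evaluations
    are cached by canonical SMILES so duplicates never re-invoke the
    objectives; adapter failures are logged and scored as invalid.
    """
    leaf = path[-1]
    prefix = leaf.prefix()
    if leaf.is_terminal:
        completed = prefix
    else:
        completed = list(policy.rollout(prefix, rng).tokens)
    s = detokenize(completed)
    terminated = bool(completed) and completed[-1] == END_TOKEN
    dim = evaluator.dimension
    zero = np.zeros(dim)
    if not terminated and len(completed) >= policy.max_length:
        logger.debug("rollout truncated at max_length: %r", s)

    canonical_probe = evaluator.canonicalize(s)
    from_cache = canonical_probe is not None and canonical_probe in cache
    if from_cache:
        res = cache[canonical_probe]
    else:
        try:
            res = evaluator.evaluate_smiles(s)
        except Exception as exc:
            logger.warning("objective adapter failed for %r: %s", s, exc)
            res = EvalResult(s, None, False, False)
        if res.canonical is not None:
            cache[res.canonical] = res
    record = GenerationRecord(
        iteration=iteration,
        smiles=s,
        canonical_smiles=res.canonical,
        valid=res.valid,
        passed_filter=res.passed_filter,
        raw_objectives=dict(res.raw),
        reward=None if res.reward is None else res.reward.copy(),
        from_cache=from_cache,
    )
    if record.reward is not None:
        front.add(record.reward, record_id)
        return record, record.reward
    return record, zero


def backpropagate(path: list[SearchNode], r: np.ndarray) -> None:
    """Feed the reward vector back along the path: each node's visit count
    increments and its mean reward moves by ``(r - mean) / n``."""
    for node in path:
        node.n_s += 1
        node.mean_reward = node.mean_reward + (r - node.mean_reward) / node.n_s


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class FrontSnapshot:
    molecule_count: int
    iteration: int
    points: np.ndarray
    hypervolume: float


@dataclass
class SearchResult:
    records: list[GenerationRecord]
    front: ParetoArchive
    snapshots: list[FrontSnapshot]
    root: SearchNode
    config: SearchConfig

    @property
    def n_valid(self) -> int:
        return sum(r.valid for r in self.records)


def run_search(
    cfg: SearchConfig, policy: Policy, evaluator: Evaluator
) -> SearchResult:
    """Iterate selection, expansion, simulation and backpropagation.

    Fully reproducible under a fixed seed with deterministic objectives;
    front snapshots are emitted when the valid-molecule count first reaches
    each entry of the checkpoint schedule.  An interrupt stops gracefully
    and returns the partial result.
    """
    dim = evaluator.dimension
    rng = np.random.default_rng(cfg.seed)
    root = SearchNode(START_TOKEN, None, dim)
    front = ParetoArchive(dim=dim)
    cache: dict[str, EvalResult] = {}
    records: list[GenerationRecord] = []
    snapshots: list[FrontSnapshot] = []
    schedule = sorted(set(cfg.checkpoint_schedule))
    next_ckpt = 0
    z = cfg.z_vector(dim)
    n_valid = 0
    try:
        for it in range(cfg.max_iterations):
            path = select(root, front, cfg, rng, dim)
            leaf = path[-1]
            if not leaf.is_terminal:
                try:
                    child = expand(leaf, policy, cfg, dim)
                    path.append(child)
                except NoExpandableTokenError:
                    pass  # simulate from the exhausted node itself
            record, reward = simulate(
                path, policy, evaluator, front, rng, cache, it, len(records)
            )
            records.append(record)
            backpropagate(path, reward)
            if record.valid:
                n_valid += 1
                while next_ckpt < len(schedule) and n_valid >= schedule[next_ckpt]:
                    snapshots.append(
                        FrontSnapshot(
                            molecule_count=schedule[next_ckpt],
                            iteration=it,
                            points=front.points.copy(),
                            hypervolume=front.hypervolume(z),
                        )
                    )
                    next_ckpt += 1
    except KeyboardInterrupt:  # pragma: no cover - interactive use
        logger.warning("search interrupted; returning partial results")
    return SearchResult(records, front, snapshots, root, cfg)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def records_to_dataframe(result: SearchResult, objective_names: Sequence[str]):
    """Tidy generation log: one row per evaluated rollout."""
    import pandas as pd

    front_ids = set()
    for ids in result.front.members.values():
        front_ids.update(ids)
    rows = []
    for i, rec in enumerate(result.records):
        row: dict = {
            "iteration": rec.iteration,
            "smiles": rec.smiles,
            "canonical_smiles": rec.canonical_smiles or "",
            "valid": rec.valid,
            "passed_filter": rec.passed_filter,
            "on_front": i in front_ids,
        }
        for name in objective_names:
            row[f"raw_{name}"] = rec.raw_objectives.get(name, np.nan)
        if "sa_score" in rec.raw_objectives:
            row["raw_sa_score"] = rec.raw_objectives["sa_score"]
        for j, name in enumerate(objective_names):
            row[f"reward_{name}"] = (
                rec.reward[j] if rec.reward is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_run_outputs(
    result: SearchResult,
    evaluator: Evaluator,
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> None:
    """Write the generation log (CSV), front (CSV + JSON) and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = records_to_dataframe(result, evaluator.objective_names)
    df.to_csv(out / "generation_log.csv", index=False)
    result.front.to_csv(out / "front.csv")
    result.front.to_json(out / "front.json")
    manifest = {
        "seed": result.config.seed,
        "max_iterations": result.config.max_iterations,
        "max_length": result.config.max_length,
        "expansion_prob_floor": result.config.expansion_prob_floor,
        "checkpoint_schedule": list(result.config.checkpoint_schedule),
        "objectives": evaluator.objective_names,
        "n_records": len(result.records),
        "n_valid": result.n_valid,
        "front_size": len(result.front),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
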