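"""Offline fixtures: a tiny synthetic SMILES corpus generator and
exhaustively enumerable toy search spaces with analytically known Pareto
fronts.

The corpus generator emulates a drug-like training set at miniature scale —
alkyl chains, ethers, amines, alcohols, carboxylic acids and single
(aromatic or saturated) rings — so the tokenizer, policy and search are
testable without any external data.  The toy spaces replace chemistry
entirely: strings over a small alphabet scored by deterministic objective
maps, so the exact Pareto front is computable by brute force and the search
can be graded against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import SpaceTooLargeError
from .objectives import EvalResult, check_validity
from .pareto import pareto_front
from .tokenizer import END_TOKEN, START_TOKEN

ENUMERATION_CAP = 10**6


# ---------------------------------------------------------------------------
# synthetic SMILES corpus
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = ["C", "C", "C", "N", "O"]  # carbon-rich, as in drug-like sets
_TERMINAL_GROUPS = ["", "O", "N", "C(=O)O", "C(=O)N"]
_RING_CORES = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "C1CCOCC1"]


def _random_chain(rng: np.random.Generator) -> str:
    length = int(rng.integers(2, 7))
    atoms = [str(rng.choice(_CHAIN_ATOMS)) for _ in range(length)]
    # heteroatoms must not be adjacent or the fixture drifts from drug-like
    for i in range(1, length):
        if atoms[i] != "C" and atoms[i - 1] != "C":
            atoms[i] = "C"
    if atoms[-1] != "C":
        atoms[-1] = "C"
    return "".join(atoms) + str(rng.choice(_TERMINAL_GROUPS))


def _random_ring(rng: np.random.Generator) -> str:
    core = str(rng.choice(_RING_CORES))
    sub = "C" * int(rng.integers(1, 4))
    return sub + core


def generate_fixture_corpus(
    n: int, seed: int, path: str | Path | None = None
) -> list[str]:
    """Produce ``n`` valid, sanitizable SMILES strings, deterministically
    under ``seed``.  Roughly three quarters are acyclic chains with simple
    functional groups; the rest carry one ring.  Optionally written one
    molecule per line to ``path``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        s = _random_ring(rng) if rng.random() < 0.25 else _random_chain(rng)
        valid, _ = check_validity(s)
        if valid:
            out.append(s)
    if path is not None:
        Path(path).write_text("\n".join(out) + "\n")
    return out


# ---------------------------------------------------------------------------
# toy search spaces
# ---------------------------------------------------------------------------

@dataclass
class ToySpace:
    """Enumerable string space: all non-empty strings over ``alphabet`` up
    to ``max_length`` characters, scored by deterministic objective maps
    into [0, 1]^d."""

    alphabet: tuple[str, ...]
    max_length: int
    objectives: tuple[Callable[[str], float], ...]

    def __post_init__(self) -> None:
        if START_TOKEN in self.alphabet or END_TOKEN in self.alphabet:
            raise ValueError("alphabet must not contain the sentinels")
        size = sum(len(self.alphabet) ** k for k in range(1, self.max_length + 1))
        if size > ENUMERATION_CAP:
            raise SpaceTooLargeError(f"{size} strings exceed the enumeration cap")

    def enumerate_strings(self) -> list[str]:
        strings: list[str] = []
        frontier = [""]
        for _ in range(self.max_length):
            frontier = [s + a for s in frontier for a in self.alphabet]
            strings.extend(frontier)
        return strings

    def score(self, s: str) -> np.ndarray:
        return np.clip([f(s) for f in self.objectives], 0.0, 1.0)


def enumerate_toy_pareto(space: ToySpace) -> tuple[np.ndarray, list[str]]:
    """Exact Pareto front of a toy space by exhaustive evaluation.

    Returns the front points (distinct, sorted) and every string achieving
    a front point.
    """
    strings = space.enumerate_strings()
    scores = np.array([space.score(s) for s in strings])
    front = pareto_front(scores)
    front_keys = {tuple(p) for p in front}
    members = [s for s, r in zip(strings, scores) if tuple(r) in front_keys]
    return front, members


class ToyObjectives:
    """Evaluator over a toy space with the same protocol the search uses
    for chemistry: every alphabet string is 'valid', its own canonical form,
    and unfiltered."""

    def __init__(self, space: ToySpace, names: Sequence[str] | None = None):
        self.space = space
        self._names = list(names or [f"f{i}" for i in range(len(space.objectives))])

    @property
    def dimension(self) -> int:
        return len(self.space.objectives)

    @property
    def objective_names(self) -> list[str]:
        return self._names

    def canonicalize(self, s: str) -> str | None:
        return s if s else None

    def evaluate_smiles(self, s: str) -> EvalResult:
        if (
            not s
            or len(s) > self.space.max_length
            or any(ch not in self.space.alphabet for ch in s)
        ):
            return EvalResult(s, None, False, False)
        reward = self.space.score(s)
        raw = {n: float(r) for n, r in zip(self._names, reward)}
        return EvalResult(s, s, True, True, raw, reward)


def anticorrelated_toy_space(
    alphabet: tuple[str, ...] = ("C", "N", "O"), max_length: int = 4
) -> ToySpace:
    """Two deterministic anti-correlated objectives sharing one budget:
    the fractions of the first and last alphabet letter in the string.
    Improving one objective at fixed length necessarily costs the other."""
    a, b = alphabet[0], alphabet[-1]

    def f1(s: str) -> float:
        return s.count(a) / max_length

    def f2(s: str) -> float:
        return s.count(b) / max_length

    return ToySpace(tuple(alphabet), max_length, (f1, f2))
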