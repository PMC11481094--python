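"""SMILES tokenization: strings <-> vocabulary tokens <-> integer indices.

Every molecule handled by the search is a sequence of vocabulary tokens
bracketed by a start sentinel ``&`` and an end sentinel ``\\n``.  Bracket
atoms such as ``[C@@H]`` and two-character element symbols such as ``Br``
are single tokens; matching is greedy longest-first at each position so the
tokenization is deterministic and losslessly invertible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import UnknownTokenError

START_TOKEN = "&"
END_TOKEN = "\n"

# Single-token inventory of the default vocabulary: atoms, bond symbols and
# bracket-atom "functional group" tokens, plus ring-closure digits and branch
# parentheses (required by any real SMILES corpus).
_ATOMS = ["C", "c", "o", "O", "N", "F", "n", "S", "s", "Br", "I", "P"]
_BONDS = ["-", "=", "#", "$", ":", "/", "\\"]
_FUNCTIONAL_GROUPS = [
    "[C@@H]", "[O-]", "[C@H]", "[NH+]", "[C@]", "[nH]",
    "[NH2+]", "[C@@]", "[N+]", "[nH+]", "[S@]", "[N-]",
    "[n-]", "[OH+]", "[NH-]", "[P@@H]", "[P@@]", "[PH2]",
    "[o+]", "[CH2-]", "[CH-]", "[SH+]", "[O+]",
    "[S-]", "[S+]", "[S@@+]", "[NH3+]", "[n+]",
    "[S@@]", "[P@]", "[P+]", "[PH]", "[s+]", "[PH+]",
]
_AUXILIARY = ["(", ")"] + [str(d) for d in range(1, 10)]

# Generic SMILES token splitter, used only to discover tokens when building a
# vocabulary from a corpus.  Bracket atoms, %nn ring closures and two-letter
# halogens come first so they win over their single-character prefixes.
_SPLIT_RE = re.compile(r"(\[[^\]]+\]|%\d\d|Br|Cl|.)", re.DOTALL)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered set of distinct SMILES tokens with sentinels.

    ``index_of`` is a bijection onto ``0..len(tokens)-1`` preserving the
    declared order, which the policy relies on for its embedding rows.
    """

    tokens: tuple[str, ...]
    start_token: str = START_TOKEN
    end_token: str = END_TOKEN
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be distinct")
        for sentinel in (self.start_token, self.end_token):
            if sentinel not in self.tokens:
                raise ValueError(f"sentinel {sentinel!r} missing from vocabulary")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )
        # Longest-first match order; ties broken alphabetically for determinism.
        object.__setattr__(
            self,
            "_match_order",
            tuple(sorted(self.tokens, key=lambda t: (-len(t), t))),
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    @classmethod
    def default(cls) -> "Vocabulary":
        """The vocabulary shipped with the package (atoms, bonds, bracket
        atoms, ring digits, parentheses, sentinels)."""
        toks = (
            [START_TOKEN]
            + _ATOMS
            + _BONDS
            + _FUNCTIONAL_GROUPS
            + _AUXILIARY
            + [END_TOKEN]
        )
        return cls(tuple(toks))

    @classmethod
    def from_corpus(cls, lines: Iterable[str]) -> "Vocabulary":
        """Build a vocabulary from every token occurring in a SMILES corpus.

        Token discovery uses a generic SMILES splitter (bracket atoms, %nn
        ring closures and two-letter halogens are single tokens).  Sentinels
        are always included; order is first-occurrence with sentinels pinned
        to the ends.
        """
        seen: dict[str, None] = {}
        for line in lines:
            s = line.split("\t")[0].strip()
            if not s:
                continue
            for tok in _SPLIT_RE.findall(s):
                seen.setdefault(tok, None)
        toks = [START_TOKEN] + [t for t in seen] + [END_TOKEN]
        return cls(tuple(toks))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(list(self.tokens)))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(tuple(json.loads(Path(path).read_text())))


@dataclass(frozen=True)
class TokenSequence:
    """A SMILES string as an ordered list of vocabulary tokens.

    Invariant: concatenating ``tokens`` reproduces ``source`` exactly, and at
    most one end token appears, only in final position.
    """

    tokens: tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        if "".join(self.tokens) != self.source:
            raise ValueError("tokens do not concatenate to source")
        inner = self.tokens[:-1]
        if END_TOKEN in inner:
            raise ValueError("end token may only appear in final position")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def terminated(self) -> bool:
        return bool(self.tokens) and self.tokens[-1] == END_TOKEN


def tokenize(s: str, vocab: Vocabulary) -> TokenSequence:
    """Split a SMILES string into vocabulary tokens, greedy longest-first.

    Bracket atoms ``[...]`` are consumed as single tokens.  Raises
    :class:`UnknownTokenError` naming the offending substring and position.
    """
    if not s:
        raise ValueError("cannot tokenize an empty string")
    tokens: list[str] = []
    i = 0
    n = len(s)
    match_order: tuple[str, ...] = vocab._match_order  # type: ignore[attr-defined]
    while i < n:
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise UnknownTokenError(s[i:], i)
            tok = s[i : j + 1]
            if tok not in vocab:
                raise UnknownTokenError(tok, i)
            tokens.append(tok)
            i = j + 1
            continue
        for tok in match_order:
            if tok and s.startswith(tok, i):
                tokens.append(tok)
                i += len(tok)
                break
        else:
            raise UnknownTokenError(ch, i)
    return TokenSequence(tuple(tokens), s)


def detokenize(t: TokenSequence | Sequence[str]) -> str:
    """Concatenate tokens with start/end sentinels stripped."""
    toks = t.tokens if isinstance(t, TokenSequence) else tuple(t)
    return "".join(tok for tok in toks if tok not in (START_TOKEN, END_TOKEN))


def encode(tokens: TokenSequence | Sequence[str], vocab: Vocabulary) -> list[int]:
    """Map tokens to vocabulary indices; inverse of :func:`decode`."""
    toks = tokens.tokens if isinstance(tokens, TokenSequence) else tokens
    out = []
    for pos, tok in enumerate(toks):
        if tok not in vocab:
            raise UnknownTokenError(tok, pos)
        out.append(vocab.index_of[tok])
    return out

def decode(indices: Sequence[int], vocab: Vocabulary) -> list[str]:
    """Map vocabulary indices back to tokens."""
    return [vocab.tokens[i] for i in indices]


def wrap(tokens: Sequence[str]) -> list[str]:
    """Bracket a bare token list with the start and end sentinels."""
    out = list(tokens)
    if not out or out[0] != START_TOKEN:
        out.insert(0, START_TOKEN)
    if out[-1] != END_TOKEN:
        out.append(END_TOKEN)
    return out


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a SMILES line file (one molecule per line, optional tab-separated
    identifier; blank lines ignored)."""
    lines = []
    for raw in Path(path).read_text().splitlines():
        s = raw.split("\t")[0].strip()
        if s:
            lines.append(s)
    return lines
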