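"""Rollout ("default") policies: a recurrent SMILES language model and a
count-based n-gram fallback.

The recurrent policy is a token-level language model — an embedding layer
feeding stacked GRU cells (tanh candidate activation) and a linear softmax
head — trained by minimizing next-token cross-entropy on start-prefixed,
end-terminated token sequences with Adam.  Once trained it is frozen; the
tree search only samples from it.  The network and its backpropagation
through time are implemented directly on NumPy arrays and validated against
finite differences in the test suite.

The n-gram policy is a deterministic, count-table language model (default
order 3 with add-one smoothing, uniform on unseen contexts).  Its
distributions can be recomputed by hand, which makes it the oracle-checkable
stand-in for the recurrent policy in search tests.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    CheckpointError,
    EmptyCorpusError,
    PrefixContainsTerminatorError,
    UnknownTokenError,
)
from .tokenizer import (
    END_TOKEN,
    START_TOKEN,
    TokenSequence,
    Vocabulary,
    encode,
    read_smiles_file,
    tokenize,
    wrap,
)


@dataclass
class PolicyConfig:
    """Hyperparameters of the recurrent policy.

    Defaults are the full-scale training settings: 81-dimensional embedding,
    two 256-unit GRU layers, Adam with learning rate 0.01, batch size 256,
    100 epochs.  ``max_length`` caps every rollout at 100 tokens, enough for
    ZINC drug-like molecules.
    """

    embedding_dim: int = 81
    hidden_dim: int = 256
    num_recurrent_layers: int = 2
    learning_rate: float = 0.01
    batch_size: int = 256
    epochs: int = 100
    max_length: int = 100
    seed: int = 0
    ngram_order: int = 3
    ngram_alpha: float = 1.0

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.hidden_dim, self.num_recurrent_layers,
               self.batch_size, self.epochs) < 1:
            raise ValueError("all dimensions and counts must be positive")
        if self.max_length < 2:
            raise ValueError("max_length must be at least 2")


def _check_prefix(prefix: Sequence[str]) -> list[str]:
    toks = list(prefix.tokens) if isinstance(prefix, TokenSequence) else list(prefix)
    if not toks or toks[0] != START_TOKEN:
        raise ValueError("prefix must begin with the start token")
    if END_TOKEN in toks:
        raise PrefixContainsTerminatorError("prefix already contains the terminator")
    return toks


class Policy:
    """Common interface: next-token distributions and prefix completion."""

    vocabulary: Vocabulary
    max_length: int

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        raise NotImplementedError

    def rollout(
        self, prefix: Sequence[str], rng: np.random.Generator
    ) -> TokenSequence:
        """Complete a prefix by autoregressive multinomial sampling.

        Terminates at the end token or at ``max_length`` total tokens
        (truncation leaves the sequence unterminated; it is not an error).
        """
        toks = _check_prefix(prefix)
        if len(toks) >= self.max_length:
            raise ValueError("prefix length must be below max_length")
        vocab = self.vocabulary
        while len(toks) < self.max_length:
            p = self.next_token_distribution(toks)
            idx = int(rng.choice(len(vocab), p=p / p.sum()))
            tok = vocab.tokens[idx]
            toks.append(tok)
            if tok == END_TOKEN:
                break
        return TokenSequence(tuple(toks), "".join(toks))


# ---------------------------------------------------------------------------
# n-gram fallback policy
# ---------------------------------------------------------------------------

class NGramPolicy(Policy):
    """Order-``k`` count-based policy with add-``alpha`` smoothing.

    The distribution for a prefix conditions on its last ``k-1`` tokens
    (fewer near the sequence start); contexts never seen in training fall
    back to the uniform distribution over the vocabulary.  With the default
    ``alpha = 1`` this is classic add-one smoothing; ``alpha = 0`` gives the
    unsmoothed conditional frequencies.
    """

    kind = "ngram"

    def __init__(
        self,
        vocabulary: Vocabulary,
        order: int = 3,
        alpha: float = 1.0,
        max_length: int = 100,
    ):
        if order < 2:
            raise ValueError("order must be at least 2")
        self.vocabulary = vocabulary
        self.order = order
        self.alpha = float(alpha)
        self.max_length = max_length
        self._counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)

    def fit(self, sequences: Iterable[Sequence[str]]) -> "NGramPolicy":
        for seq in sequences:
            toks = list(seq)
            for j in range(1, len(toks)):
                for L in range(1, self.order):
                    if j - L < 0:
                        break
                    ctx = tuple(toks[j - L : j])
                    self._counts[ctx][toks[j]] += 1
        return self

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        toks = _check_prefix(prefix)
        vocab = self.vocabulary
        V = len(vocab)
        L = min(self.order - 1, len(toks))
        ctx = tuple(toks[-L:])
        counts = self._counts.get(ctx)
        if not counts:
            return np.full(V, 1.0 / V)
        total = sum(counts.values())
        p = np.full(V, self.alpha, dtype=float)
        for tok, c in counts.items():
            p[vocab.index_of[tok]] += c
        denom = total + self.alpha * V
        if denom <= 0:  # alpha == 0 and empty context cannot occur (counts nonempty)
            return np.full(V, 1.0 / V)
        return p / denom


# ---------------------------------------------------------------------------
# recurrent (GRU) policy
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class GRUPolicy(Policy):
    """Stacked-GRU SMILES language model on plain NumPy arrays.

    Gate equations per layer (update z, reset r, tanh candidate n):

        z = sigma(x Wz + h Uz + bz)
        r = sigma(x Wr + h Ur + br)
        n = tanh(x Wh + (r * h) Uh + bh)
        h' = z * h + (1 - z) * n

    The output head is a linear map of the top hidden state to vocabulary
    logits followed by softmax.
    """

    kind = "recurrent"

    def __init__(self, vocabulary: Vocabulary, config: PolicyConfig):
        self.vocabulary = vocabulary
        self.config = config
        self.max_length = config.max_length
        rng = np.random.default_rng(config.seed)
        V, De, H = len(vocabulary), config.embedding_dim, config.hidden_dim
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.1, (V, De)),
            "Wo": rng.normal(0.0, 1.0 / np.sqrt(H), (H, V)),
            "bo": np.zeros(V),
        }
        for l in range(config.num_recurrent_layers):
            din = De if l == 0 else H
            for g in ("z", "r", "h"):
                self.params[f"W{g}{l}"] = rng.normal(0.0, 1.0 / np.sqrt(din), (din, H))
                self.params[f"U{g}{l}"] = rng.normal(0.0, 1.0 / np.sqrt(H), (H, H))
                self.params[f"b{g}{l}"] = np.zeros(H)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []

    # -- forward ------------------------------------------------------------

    def _step(
        self, x: np.ndarray, hs: list[np.ndarray]
    ) -> tuple[np.ndarray, list[np.ndarray], list[dict]]:
        """One timestep through all layers; returns logits, new hidden
        states and per-layer caches for backpropagation."""
        p = self.params
        caches = []
        inp = x
        new_hs = []
        for l in range(self.config.num_recurrent_layers):
            h = hs[l]
            z = _sigmoid(inp @ p[f"Wz{l}"] + h @ p[f"Uz{l}"] + p[f"bz{l}"])
            r = _sigmoid(inp @ p[f"Wr{l}"] + h @ p[f"Ur{l}"] + p[f"br{l}"])
            rh = r * h
            n = np.tanh(inp @ p[f"Wh{l}"] + rh @ p[f"Uh{l}"] + p[f"bh{l}"])
            h_new = z * h + (1.0 - z) * n
            caches.append({"x": inp, "h": h, "z": z, "r": r, "rh": rh, "n": n})
            new_hs.append(h_new)
            inp = h_new
        logits = inp @ p["Wo"] + p["bo"]
        return logits, new_hs, caches

    def _init_hidden(self, batch: int) -> list[np.ndarray]:
        H = self.config.hidden_dim
        return [np.zeros((batch, H)) for _ in range(self.config.num_recurrent_layers)]

    # -- loss and gradients (BPTT) ------------------------------------------

    def _loss_and_grads(
        self, ids: np.ndarray, mask: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean masked next-token cross-entropy and its parameter gradients.

        ``ids`` is a (B, T) int array of padded token indices; ``mask[b, t]``
        marks positions where ``ids[b, t+1]`` is a real prediction target.
        """
        p = self.params
        nlayers = self.config.num_recurrent_layers
        B, T = ids.shape
        hs = self._init_hidden(B)
        step_caches = []
        probs_list = []
        total = mask.sum()
        loss = 0.0
        for t in range(T - 1):
            x = p["E"][ids[:, t]]
            logits, hs, caches = self._step(x, hs)
            probs = _softmax(logits)
            tgt = ids[:, t + 1]
            m = mask[:, t]
            safe_tgt = np.where(tgt >= 0, tgt, 0)
            ll = -np.log(probs[np.arange(B), safe_tgt] + 1e-300)
            loss += float((ll * m).sum())
            step_caches.append(caches)
            probs_list.append((probs, safe_tgt, m))
        loss /= total

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_carry = self._init_hidden(B)
        for t in reversed(range(T - 1)):
            probs, tgt, m = probs_list[t]
            dlogits = probs.copy()
            dlogits[np.arange(B), tgt] -= 1.0
            dlogits *= (m / total)[:, None]
            caches = step_caches[t]
            h_top = caches[-1]["z"] * caches[-1]["h"] + (1 - caches[-1]["z"]) * caches[-1]["n"]
            grads["Wo"] += h_top.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dh_above = dlogits @ p["Wo"].T
            for l in reversed(range(nlayers)):
                c = caches[l]
                dh_new = dh_above + dh_carry[l]
                dz = dh_new * (c["h"] - c["n"])
                dn = dh_new * (1.0 - c["z"])
                dh = dh_new * c["z"]
                dan = dn * (1.0 - c["n"] ** 2)
                daz = dz * c["z"] * (1.0 - c["z"])
                drh = dan @ p[f"Uh{l}"].T
                dr = drh * c["h"]
                dh += drh * c["r"]
                dar = dr * c["r"] * (1.0 - c["r"])
                dx = daz @ p[f"Wz{l}"].T + dar @ p[f"Wr{l}"].T + dan @ p[f"Wh{l}"].T
                dh += daz @ p[f"Uz{l}"].T + dar @ p[f"Ur{l}"].T
                grads[f"Wz{l}"] += c["x"].T @ daz
                grads[f"Wr{l}"] += c["x"].T @ dar
                grads[f"Wh{l}"] += c["x"].T @ dan
                grads[f"Uz{l}"] += c["h"].T @ daz
                grads[f"Ur{l}"] += c["h"].T @ dar
                grads[f"Uh{l}"] += c["rh"].T @ dan
                grads[f"bz{l}"] += daz.sum(axis=0)
                grads[f"br{l}"] += dar.sum(axis=0)
                grads[f"bh{l}"] += dan.sum(axis=0)
                dh_carry[l] = dh
                dh_above = dx
            np.add.at(grads["E"], ids[:, t], dh_above)
        return loss, grads

    def _adam_update(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, encoded: list[list[int]]) -> "GRUPolicy":
        """Train on encoded, sentinel-wrapped sequences; records the mean
        epoch loss in ``loss_history``."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(encoded)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            nbatches = 0
            for start in range(0, n, cfg.batch_size):
                batch = [encoded[i] for i in order[start : start + cfg.batch_size]]
                T = max(len(s) for s in batch)
                ids = np.full((len(batch), T), -1, dtype=int)
                for b, s in enumerate(batch):
                    ids[b, : len(s)] = s
                mask = (ids[:, 1:] >= 0).astype(float)
                ids = np.where(ids >= 0, ids, 0)
                loss, grads = self._loss_and_grads(ids, mask)
                self._adam_update(grads)
                epoch_loss += loss
                nbatches += 1
            self.loss_history.append(epoch_loss / nbatches)
        return self

    # -- inference ----------------------------------------------------------

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        toks = _check_prefix(prefix)
        ids = encode(toks, self.vocabulary)
        hs = self._init_hidden(1)
        logits = None
        for i in ids:
            x = self.params["E"][np.array([i])]
            logits, hs, _ = self._step(x, hs)
        return _softmax(logits)[0]

    def rollout(
        self, prefix: Sequence[str], rng: np.random.Generator
    ) -> TokenSequence:
        # incremental hidden state; same contract as Policy.rollout
        toks = _check_prefix(prefix)
        if len(toks) >= self.max_length:
            raise ValueError("prefix length must be below max_length")
        vocab = self.vocabulary
        hs = self._init_hidden(1)
        logits = None
        for i in encode(toks, vocab):
            logits, hs, _ = self._step(self.params["E"][np.array([i])], hs)
        while len(toks) < self.max_length:
            p = _softmax(logits)[0]
            idx = int(rng.choice(len(vocab), p=p / p.sum()))
            toks.append(vocab.tokens[idx])
            if toks[-1] == END_TOKEN:
                break
            logits, hs, _ = self._step(self.params["E"][np.array([idx])], hs)
        return TokenSequence(tuple(toks), "".join(toks))

    # -- persistence --------------------------------------------------------

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: weights, vocabulary and config."""
        meta = {
            "vocabulary": list(self.vocabulary.tokens),
            "config": asdict(self.config),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(
        cls, path: str | Path, expected_vocabulary: Vocabulary | None = None
    ) -> "GRUPolicy":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            vocab = Vocabulary(tuple(meta["vocabulary"]))
            cfg = PolicyConfig(**meta["config"])
            policy = cls(vocab, cfg)
            for k in policy.params:
                if k not in data:
                    raise CheckpointError(f"missing parameter {k!r} in checkpoint")
                policy.params[k] = data[k]
        if policy.params["E"].shape[0] != len(vocab):
            raise CheckpointError("embedding rows do not match vocabulary size")
        if expected_vocabulary is not None and (
            tuple(expected_vocabulary.tokens) != tuple(vocab.tokens)
        ):
            raise CheckpointError("checkpoint vocabulary mismatch")
        return policy


# ---------------------------------------------------------------------------
# training entry point
# ---------------------------------------------------------------------------

def _load_corpus(corpus: str | Path | Sequence[str]) -> list[str]:
    if isinstance(corpus, (str, Path)):
        return read_smiles_file(corpus)
    return [s.strip() for s in corpus if s.strip()]


def prepare_sequences(
    lines: Sequence[str], vocab: Vocabulary
) -> list[list[int]]:
    """Tokenize, sentinel-wrap and encode corpus lines; token errors carry
    the 1-based line number."""
    encoded = []
    for lineno, s in enumerate(lines, start=1):
        try:
            seq = tokenize(s, vocab)
        except UnknownTokenError as exc:
            raise UnknownTokenError(exc.substring, exc.position, line=lineno) from exc
        encoded.append(encode(wrap(seq.tokens), vocab))
    return encoded


def train_policy(
    corpus: str | Path | Sequence[str],
    cfg: PolicyConfig | None = None,
    vocabulary: Vocabulary | None = None,
    kind: str = "recurrent",
) -> Policy:
    """Train a rollout policy on a SMILES corpus.

    The vocabulary is rebuilt from the corpus unless one is supplied, and is
    persisted with the model.  ``kind='ngram'`` trains the deterministic
    count-based policy with the same interface.  The returned model is
    frozen: the search never updates it.
    """
    cfg = cfg or PolicyConfig()
    lines = _load_corpus(corpus)
    if not lines:
        raise EmptyCorpusError("training corpus contains no SMILES")
    vocab = vocabulary or Vocabulary.from_corpus(lines)
    if kind == "ngram":
        policy = NGramPolicy(
            vocab, order=cfg.ngram_order, alpha=cfg.ngram_alpha,
            max_length=cfg.max_length,
        )
        seqs = [wrap(tokenize(s, vocab).tokens) for s in lines]
        return policy.fit(seqs)
    if kind != "recurrent":
        raise ValueError(f"unknown policy kind {kind!r}")
    encoded = prepare_sequences(lines, vocab)
    return GRUPolicy(vocab, cfg).fit(encoded)
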