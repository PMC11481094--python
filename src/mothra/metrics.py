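"""Generation-quality metrics over a run log.

Standard generative-model metrics, all computed on canonical SMILES so that
different string spellings of one molecule count as duplicates:

* validity — valid molecules / generated strings
* uniqueness — distinct valid molecules / valid molecules
* duplication ratio — 1 - uniqueness
* novelty — distinct valid molecules absent from the training set /
  distinct valid molecules
* internal diversity — 1 - mean pairwise Tanimoto similarity of Morgan
  fingerprints (radius 2, 2048 bits) over the distinct valid molecules
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .errors import EmptyLogError
from .mcts import GenerationRecord

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class MetricsReport:
    n_generated: int
    n_valid: int
    n_unique: int
    validity: float
    uniqueness: float
    duplication_ratio: float
    novelty: float
    internal_diversity: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def __str__(self) -> str:
        return (
            f"generated {self.n_generated}  valid {self.n_valid}  "
            f"unique {self.n_unique}\n"
            f"validity            {self.validity:.4f}\n"
            f"uniqueness          {self.uniqueness:.4f}\n"
            f"duplication ratio   {self.duplication_ratio:.4f}\n"
            f"novelty             {self.novelty:.4f}\n"
            f"internal diversity  {self.internal_diversity:.4f}"
        )


def internal_diversity(smiles: Sequence[str]) -> float:
    """1 - mean Tanimoto over unordered fingerprint pairs (self-pairs
    excluded); 0 for fewer than two molecules."""
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    fps = [_FPGEN.GetFingerprint(m) for m in mols if m is not None]
    n = len(fps)
    if n < 2:
        return 0.0
    total = 0.0
    pairs = 0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        total += sum(sims)
        pairs += len(sims)
    return 1.0 - total / pairs


def compute_metrics(
    log: Sequence[GenerationRecord] | Sequence[dict],
    training_corpus: Iterable[str] = (),
) -> MetricsReport:
    """Compute the report from generation records (or equivalent dicts).

    The training corpus is canonicalized before the novelty comparison.
    Records that never produced a valid molecule contribute only to the
    validity denominator.
    """
    records = list(log)
    if not records:
        raise EmptyLogError("generation log is empty")

    def get(rec, name):
        return rec[name] if isinstance(rec, dict) else getattr(rec, name)

    n_generated = len(records)
    valid_canonical = [
        get(r, "canonical_smiles") for r in records if get(r, "valid")
    ]
    n_valid = len(valid_canonical)
    unique = sorted(set(valid_canonical))
    n_unique = len(unique)

    train_set = set()
    for s in training_corpus:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            train_set.add(Chem.MolToSmiles(mol))

    uniqueness = n_unique / n_valid if n_valid else 0.0
    novelty = (
        len([s for s in unique if s not in train_set]) / n_unique
        if n_unique
        else 0.0
    )
    return MetricsReport(
        n_generated=n_generated,
        n_valid=n_valid,
        n_unique=n_unique,
        validity=n_valid / n_generated,
        uniqueness=uniqueness,
        duplication_ratio=1.0 - uniqueness if n_valid else 0.0,
        novelty=novelty,
        internal_diversity=internal_diversity(unique),
    )


def metrics_from_log_file(path, training_corpus: Iterable[str] = ()) -> MetricsReport:
    """Compute the report from a generation-log CSV written by the search."""
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    records = [
        {
            "valid": bool(row["valid"]) if not isinstance(row["valid"], str)
            else row["valid"] == "True",
            "canonical_smiles": row["canonical_smiles"] or None,
        }
        for _, row in df.iterrows()
    ]
    return compute_metrics(records, training_corpus)
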