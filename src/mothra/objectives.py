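"""Objective functions and reward shaping for the molecular search.

Three shipped objectives mirror a typical structure-based campaign:

* **docking** — estimated binding free energy in kcal/mol from AutoDock
  Vina (lower is better), mapped to a reward in [0, 1] by
  ``r = max(0, x / (1 + x))`` with ``x = baseline - DS``; the baseline
  defaults to 0, so any negative score earns reward and the transform is
  monotone (it preserves the order of docking scores without rescaling them).
* **qed** — the quantitative estimate of drug-likeness, already a [0, 1]
  desirability, used as-is.
* **toxicity** — a predicted toxicity probability p in [0, 1], rewarded as
  ``1 - p`` so that safer molecules score higher.

Synthetic accessibility (SAscore, 1 = easy to 10 = infeasible) is a hard
filter, not an objective: molecules with SAscore above 3.5 are discarded
before any objective is evaluated.

Deterministic mock adapters (docking surrogate, toxicity surrogate) make the
whole pipeline testable offline; the Vina subprocess adapter is substituted
by the mock, with a warning, when the binary is unavailable.
"""

from __future__ import annotations

import logging
import os
import re
import shutil
import subprocess
import sys
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig, rdMolDescriptors

from .errors import AdapterError, DomainError

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contributed fragment-based SAscore)

logger = logging.getLogger("mothra")

SA_THRESHOLD = 3.5


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def check_validity(s: str) -> tuple[bool, str | None]:
    """Sanitization-based validity check; returns the canonical SMILES when
    the string parses.  Invalidity is a result, never an exception."""
    if not s:
        return False, None
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        return False, None
    return True, Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# reward transforms
# ---------------------------------------------------------------------------

def reward_docking(ds: float, baseline: float = 0.0) -> float:
    """Map a docking score (kcal/mol, lower = better) to [0, 1].

    Strictly decreasing in ``ds`` below the baseline; scores at or above the
    baseline earn zero reward.
    """
    if not np.isfinite(ds):
        raise DomainError("docking score must be finite")
    x = baseline - ds
    return float(x / (1.0 + x)) if x > 0 else 0.0


def reward_qed(mol: Chem.Mol) -> float:
    """Drug-likeness reward: the QED desirability itself (already in [0,1])."""
    return float(QED.qed(mol))


def reward_toxicity(p: float) -> float:
    """Toxicity reward ``1 - p``: harmless (p=0) maps to 1, toxic to 0."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"toxicity probability {p} outside [0, 1]")
    return 1.0 - p


def sa_score(mol: Chem.Mol) -> float:
    """Synthetic accessibility score on [1, 10] (fragment-contribution method)."""
    return float(sascorer.calculateScore(mol))


def sa_filter(sascore: float, threshold: float = SA_THRESHOLD) -> bool:
    """Pass iff the molecule is no harder to synthesize than the threshold
    (inclusive boundary)."""
    if not 1.0 - 1e-9 <= sascore <= 10.0 + 1e-9:
        raise DomainError(f"SAscore {sascore} outside [1, 10]")
    return sascore <= threshold


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------

class ToxicityPredictor(Protocol):
    def predict_toxicity(self, mol: Chem.Mol) -> float: ...


class MockToxicityPredictor:
    """Deterministic toxicity surrogate: a logistic function of fixed
    descriptors (logP, aromatic ring count, molecular weight).

    Stands in for an externally trained classifier so the search and its
    tests run offline and reproducibly.
    """

    def predict_toxicity(self, mol: Chem.Mol) -> float:
        logp = Crippen.MolLogP(mol)
        arom = rdMolDescriptors.CalcNumAromaticRings(mol)
        mw = Descriptors.MolWt(mol)
        t = 0.45 * logp + 0.6 * arom + 0.004 * (mw - 250.0) - 1.2
        return float(1.0 / (1.0 + np.exp(-t)))


def mock_docking_score(mol: Chem.Mol) -> float:
    """Deterministic docking surrogate in kcal/mol.

    A simple additive model of heavy-atom and ring counts (larger, more
    cyclic molecules bind more strongly), clipped to a plausible Vina range.
    """
    heavy = mol.GetNumHeavyAtoms()
    rings = rdMolDescriptors.CalcNumRings(mol)
    ds = -(0.35 * heavy + 0.9 * rings) + 1.0
    return float(np.clip(ds, -14.0, 0.0))


_VINA_AFFINITY_RE = re.compile(r"^\s*1\s+(-?\d+\.\d+)", re.MULTILINE)


def parse_vina_log(text: str) -> float:
    """Extract the top-ranked (mode 1) affinity in kcal/mol from Vina output."""
    m = _VINA_AFFINITY_RE.search(text)
    if m is None:
        raise AdapterError("no affinity table found in docking output")
    return float(m.group(1))


@dataclass
class DockingConfig:
    """Receptor and search-box definition for the docking adapter."""

    receptor: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    exhaustiveness: int = 1  # one pose search per generated molecule
    vina_binary: str = "vina"
    obabel_binary: str = "obabel"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("box extents must be positive")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


class VinaDocking:
    """Subprocess adapter around AutoDock Vina.

    The ligand is embedded as a single lowest-energy 3-D conformer by Open
    Babel, converted to PDBQT, docked against the prepared receptor, and the
    best-mode affinity parsed from the engine log.  Receptor preparation
    itself (hydrogens, charges) is out of scope and documented elsewhere.
    """

    def __init__(self, config: DockingConfig):
        self.config = config
        if shutil.which(config.vina_binary) is None:
            raise AdapterError(f"docking binary {config.vina_binary!r} not found")
        if shutil.which(config.obabel_binary) is None:
            raise AdapterError(f"converter {config.obabel_binary!r} not found")

    def dock(self, mol: Chem.Mol) -> float:
        smi = Chem.MolToSmiles(mol)
        cfg = self.config
        with tempfile.TemporaryDirectory() as tmp:
            lig = os.path.join(tmp, "ligand.pdbqt")
            out = os.path.join(tmp, "out.pdbqt")
            conv = subprocess.run(
                [cfg.obabel_binary, f"-:{smi}", "-opdbqt", "-O", lig,
                 "--gen3d", "--best"],
                capture_output=True, text=True,
            )
            if conv.returncode != 0 or not os.path.exists(lig):
                raise AdapterError(f"conformer generation failed: {conv.stderr}")
            run = subprocess.run(
                [cfg.vina_binary,
                 "--receptor", cfg.receptor, "--ligand", lig, "--out", out,
                 "--center_x", str(cfg.center[0]),
                 "--center_y", str(cfg.center[1]),
                 "--center_z", str(cfg.center[2]),
                 "--size_x", str(cfg.size[0]),
                 "--size_y", str(cfg.size[1]),
                 "--size_z", str(cfg.size[2]),
                 "--exhaustiveness", str(cfg.exhaustiveness)],
                capture_output=True, text=True,
            )
            if run.returncode != 0:
                raise AdapterError(f"docking engine failed: {run.stderr}")
            return parse_vina_log(run.stdout)


def make_docking_backend(config: DockingConfig | None) -> Callable[[Chem.Mol], float]:
    """Return a callable mol -> docking score.

    Uses the Vina subprocess adapter when a config is given and the binary is
    present; otherwise falls back to the deterministic surrogate with a
    logged warning.
    """
    if config is not None:
        try:
            engine = VinaDocking(config)
            return engine.dock
        except AdapterError as exc:
            logger.warning("docking adapter unavailable (%s); using surrogate", exc)
    return mock_docking_score


# ---------------------------------------------------------------------------
# objective specs and evaluation
# ---------------------------------------------------------------------------

_KINDS = {"docking", "qed", "toxicity", "constant", "mock"}


@dataclass
class ObjectiveSpec:
    """One reward component: its kind, adapter configuration and transform
    parameters.  ``kind='mock'`` is the deterministic docking surrogate;
    ``kind='constant'`` yields a fixed reward (used for the single-objective
    mode, where the search degrades to scalar UCB1)."""

    name: str
    kind: str
    ds_baseline: float = 0.0
    value: float = 0.5          # constant objective only
    docking: DockingConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "constant" and not 0.0 <= self.value <= 1.0:
            raise ValueError("constant objective value must lie in [0, 1]")


@dataclass
class EvalResult:
    """Outcome of evaluating one generated string."""

    smiles: str
    canonical: str | None
    valid: bool
    passed_filter: bool
    raw: dict[str, float] = field(default_factory=dict)
    reward: np.ndarray | None = None


class ObjectiveEvaluator:
    """Evaluate molecules against an ordered list of objective specs.

    Deterministic for deterministic adapters: the reward vector is a pure
    function of the molecule and the specs.  Components are clipped to
    [0, 1] so the Pareto machinery's origin reference point always applies.
    """

    def __init__(
        self,
        specs: Sequence[ObjectiveSpec],
        toxicity_predictor: ToxicityPredictor | None = None,
        sa_threshold: float = SA_THRESHOLD,
        apply_sa_filter: bool = True,
    ):
        if not specs:
            raise ValueError("at least one objective spec is required")
        self.specs = list(specs)
        self.toxicity_predictor = toxicity_predictor or MockToxicityPredictor()
        self.sa_threshold = sa_threshold
        self.apply_sa_filter = apply_sa_filter
        self._docking_backends: dict[int, Callable[[Chem.Mol], float]] = {}
        for i, spec in enumerate(self.specs):
            if spec.kind == "docking":
                self._docking_backends[i] = make_docking_backend(spec.docking)
            elif spec.kind == "mock":
                self._docking_backends[i] = mock_docking_score

    @property
    def dimension(self) -> int:
        return len(self.specs)

    @property
    def objective_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def canonicalize(self, s: str) -> str | None:
        """Canonical SMILES for caching, or None when the string is invalid."""
        return check_validity(s)[1]

    def evaluate_smiles(self, s: str) -> EvalResult:
        valid, canonical = check_validity(s)
        if not valid:
            return EvalResult(s, None, False, False)
        mol = Chem.MolFromSmiles(canonical)
        raw: dict[str, float] = {}
        if self.apply_sa_filter:
            sas = sa_score(mol)
            raw["sa_score"] = sas
            if not sa_filter(sas, self.sa_threshold):
                return EvalResult(s, canonical, True, False, raw)
        reward, obj_raw = self.evaluate(mol)
        raw.update(obj_raw)
        return EvalResult(s, canonical, True, True, raw, reward)

    def evaluate(self, mol: Chem.Mol) -> tuple[np.ndarray, dict[str, float]]:
        """Reward vector (one component per spec, declared order) plus the
        raw objective values behind it."""
        rewards = np.zeros(len(self.specs))
        raw: dict[str, float] = {}
        for i, spec in enumerate(self.specs):
            if spec.kind in ("docking", "mock"):
                ds = self._docking_backends[i](mol)
                raw[spec.name] = ds
                rewards[i] = reward_docking(ds, spec.ds_baseline)
            elif spec.kind == "qed":
                q = reward_qed(mol)
                raw[spec.name] = q
                rewards[i] = q
            elif spec.kind == "toxicity":
                p = self.toxicity_predictor.predict_toxicity(mol)
                raw[spec.name] = p
                rewards[i] = reward_toxicity(p)
            elif spec.kind == "constant":
                raw[spec.name] = spec.value
                rewards[i] = spec.value
        return np.clip(rewards, 0.0, 1.0), raw
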