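"""Run configuration: a flat, commented YAML key tree that round-trips
losslessly.  Unknown keys are errors (fail-fast); the top-level seed fixes
every stochastic component of a run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .mcts import SearchConfig
from .objectives import DockingConfig, ObjectiveSpec
from .policy import PolicyConfig


@dataclass
class RunConfig:
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    objectives: list[ObjectiveSpec] = field(
        default_factory=lambda: [
            ObjectiveSpec("docking", "mock"),
            ObjectiveSpec("qed", "qed"),
            ObjectiveSpec("toxicity", "toxicity"),
        ]
    )
    output_dir: str = "mothra_out"
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed drives training, search and every sampler
        self.policy.seed = self.seed
        self.search = dataclasses.replace(self.search, seed=self.seed)


def _build(cls, block: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {"policy", "search", "objectives", "output_dir", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    policy = _build(PolicyConfig, raw.get("policy", {}), "policy block")
    search_block = dict(raw.get("search", {}))
    if "c" in search_block and isinstance(search_block["c"], list):
        search_block["c"] = tuple(search_block["c"])
    if "checkpoint_schedule" in search_block:
        search_block["checkpoint_schedule"] = tuple(
            search_block["checkpoint_schedule"]
        )
    search = _build(SearchConfig, search_block, "search block")

    specs = []
    for i, block in enumerate(raw.get("objectives", [])):
        block = dict(block)
        if "docking" in block and block["docking"] is not None:
            dblock = dict(block["docking"])
            for k in ("center", "size"):
                if k in dblock:
                    dblock[k] = tuple(dblock[k])
            block["docking"] = _build(
                DockingConfig, dblock, f"objectives[{i}].docking"
            )
        specs.append(_build(ObjectiveSpec, block, f"objectives[{i}]"))

    cfg = RunConfig(
        policy=policy,
        search=search,
        output_dir=raw.get("output_dir", "mothra_out"),
        seed=int(raw.get("seed", 0)),
    )
    if specs:
        cfg.objectives = specs
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    raw = {
        "policy": dataclasses.asdict(cfg.policy),
        "search": dataclasses.asdict(cfg.search),
        "objectives": [dataclasses.asdict(s) for s in cfg.objectives],
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
    }
    for block in raw["objectives"]:
        if block["docking"] is not None:
            block["docking"]["center"] = list(block["docking"]["center"])
            block["docking"]["size"] = list(block["docking"]["size"])
    raw["search"]["checkpoint_schedule"] = list(cfg.search.checkpoint_schedule)
    if isinstance(raw["search"]["c"], tuple):
        raw["search"]["c"] = list(raw["search"]["c"])
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
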