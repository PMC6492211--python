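"""Scenario configuration: schema validation, defaults, YAML/JSON I/O."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["ScenarioConfig", "load_config", "save_config"]

_VALID_METHODS = ("FULL", "TrueC", "BBeF", "BLaF", "SepAv", "SepAvF", "Stack", "StackW")
_VALID_RULES = ("1se", "optimal")
_VALID_RECALS = ("none", "score", "refit")


@dataclass
class ScenarioConfig:
    """Configuration of one simulation scenario.

    Defaults mirror the study design: m = 10 imputations, inclusion
    threshold 0.5, B = 100 bootstrap resamples per completion, external
    validation on 5000 fully observed subjects.
    """

    mechanism: str
    n: int
    miss: float
    m: int = 10
    reps: int = 1
    B: int = 100
    threshold: float = 0.5
    cycles: int = 5
    n_val: int = 5000
    seed: int = 0
    methods: list[str] = field(default_factory=lambda: list(_VALID_METHODS))
    penalties: list[str] = field(default_factory=lambda: list(_VALID_RULES))
    recalibrations: list[str] = field(default_factory=lambda: list(_VALID_RECALS))

    def __post_init__(self):
        if self.mechanism not in ("one", "two"):
            raise ValueError(f"mechanism must be 'one' or 'two', got {self.mechanism!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.miss < 1.0:
            raise ValueError("miss must lie strictly between 0 and 1")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        for m_ in self.methods:
            if m_ not in _VALID_METHODS:
                raise ValueError(f"unknown method {m_!r}")
        for r in self.penalties:
            if r not in _VALID_RULES:
                raise ValueError(f"unknown penalty rule {r!r}")
        for r in self.recalibrations:
            if r not in _VALID_RECALS:
                raise ValueError(f"unknown recalibration {r!r}")

    def variant_tuples(self) -> list[tuple[str, str, str]]:
        """Expand to (method, penalty_rule, recalibration) triples.

        FULL/TrueC/BBeF carry no penalty rule; recalibration applies only
        to 1-se lasso variants of the separate and stacked methods.
        """
        out: list[tuple[str, str, str]] = []
        for meth in self.methods:
            if meth in ("FULL", "TrueC", "BBeF"):
                out.append((meth, "none", "none"))
                continue
            for rule in self.penalties:
                if rule == "optimal":
                    out.append((meth, rule, "none"))
                    continue
                recals = (
                    self.recalibrations
                    if meth in ("SepAv", "SepAvF", "Stack", "StackW")
                    else ["none"]
                )
                for recal in recals:
                    out.append((meth, rule, recal))
        return out

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario configuration.

    Unknown keys are rejected with a field-level message.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {f.name for f in fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return ScenarioConfig(**data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
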