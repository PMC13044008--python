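"""YAML run configuration: one file drives generate/train/eval/audit.

Sections: ``data`` (either an inline generator ``spec`` or a corpus
``path``, plus split fractions), ``model``, ``objective``, ``train``,
``audit``, and a global ``seed`` from which every component seed is derived
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import CorpusSpec
from .encoder import ModelConfig
from .losses import LossWeights
from .train import TrainConfig

__all__ = ["RunConfig", "AuditConfig", "load_run_config", "derive_seeds"]


class RunConfigError(ValueError):
    pass


def derive_seeds(root_seed: int, n: int = 4) -> list[int]:
    """Deterministic per-component seeds below 2**31 from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass(frozen=True)
class AuditConfig:
    methods: tuple[str, ...] = ("gradient_input",)
    k_list: tuple[int, ...] = (1, 3)
    rho: float = 0.1
    repeats: int = 5
    n_examples: int = 16


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    corpus_spec: CorpusSpec | None = None
    corpus_path: str | None = None
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    model: ModelConfig = field(default_factory=ModelConfig)
    objective: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    audit: AuditConfig = field(default_factory=AuditConfig)


def load_run_config(path, seed_override: int | None = None,
                    output_override: str | None = None) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise RunConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise RunConfigError(f"invalid YAML in {path}: {exc}") from exc

    seed = int(seed_override if seed_override is not None
               else raw.get("seed", 0))
    data_seed, model_seed, train_seed, audit_seed = derive_seeds(seed)
    out_dir = str(output_override or raw.get("output_dir", "runs/out"))

    data = raw.get("data", {}) or {}
    spec_raw, corpus_path = data.get("spec"), data.get("path")
    if (spec_raw is None) == (corpus_path is None):
        raise RunConfigError(
            "data section must contain exactly one of 'spec' or 'path'")
    spec = None
    if spec_raw is not None:
        spec_raw = dict(spec_raw)
        if "sentence_length_range" in spec_raw:
            spec_raw["sentence_length_range"] = tuple(
                spec_raw["sentence_length_range"])
        spec_raw.setdefault("seed", data_seed)
        try:
            spec = CorpusSpec(**spec_raw)
        except (TypeError, ValueError) as exc:
            raise RunConfigError(f"data.spec: {exc}") from exc

    try:
        model = ModelConfig(**{**(raw.get("model") or {}), "seed": model_seed})
        objective = LossWeights(**(raw.get("objective") or {}))
        train = TrainConfig(**{**(raw.get("train") or {}), "seed": train_seed})
    except (TypeError, ValueError) as exc:
        raise RunConfigError(str(exc)) from exc

    audit_raw = dict(raw.get("audit") or {})
    if "methods" in audit_raw:
        audit_raw["methods"] = tuple(audit_raw["methods"])
    if "k_list" in audit_raw:
        audit_raw["k_list"] = tuple(int(k) for k in audit_raw["k_list"])
    try:
        audit = AuditConfig(**audit_raw)
    except TypeError as exc:
        raise RunConfigError(f"audit section: {exc}") from exc

    fractions = tuple(data.get("split_fractions", (0.8, 0.1, 0.1)))
    return RunConfig(seed=seed, output_dir=out_dir, corpus_spec=spec,
                     corpus_path=corpus_path, split_fractions=fractions,
                     model=model, objective=objective, train=train, audit=audit)
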