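"""Pipeline configuration: one dataclass, loadable from a YAML file.

A config fixes everything a run needs — chunking limits, masking
strategy, filler backend, post-processing switches and paths — so that
any artifact can be reproduced from its manifest (config hash + seed)
alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import AdapterBundle
from .masking import MaskStrategy

__all__ = ["PipelineConfig", "make_filler"]


@dataclass
class PipelineConfig:
    max_lines: int = 20
    max_tokens: int = 256
    strategy: MaskStrategy = field(default_factory=lambda: MaskStrategy(kind="random", ratio=0.3))
    adapters: AdapterBundle = field(default_factory=AdapterBundle)
    counter: object = None
    segmenter: object = None
    filler_spec: dict = field(default_factory=lambda: {"name": "lexicon"})
    fill_placeholders: bool = True
    correct_spelling: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)
    ratios_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    max_lines_grid: tuple[int, ...] = (1, 2, 5, 10, 20, 40)
    fixtures: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        strategy_raw = dict(raw.get("strategy", {"kind": "random", "ratio": 0.3}))
        components = tuple(tuple(c) for c in strategy_raw.pop("components", ()))
        strategy = MaskStrategy(components=components, **strategy_raw)
        chunking = raw.get("chunking", {})
        return cls(
            max_lines=int(chunking.get("max_lines", 20)),
            max_tokens=int(chunking.get("max_tokens", 256)),
            strategy=strategy,
            filler_spec=dict(raw.get("filler", {"name": "lexicon"})),
            fill_placeholders=bool(raw.get("postprocess", {}).get("fill_placeholders", True)),
            correct_spelling=bool(raw.get("postprocess", {}).get("correct_spelling", False)),
            seed=int(raw.get("seed", 0)),
            paths={k: str(v) for k, v in raw.get("paths", {}).items()},
            ratios_grid=tuple(raw.get("ratios_grid", (0.0, 0.2, 0.4, 0.6, 0.8, 1.0))),
            max_lines_grid=tuple(raw.get("max_lines_grid", (1, 2, 5, 10, 20, 40))),
            fixtures=dict(raw.get("fixtures", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def canonical(self) -> dict:
        return {
            "chunking": {"max_lines": self.max_lines, "max_tokens": self.max_tokens},
            "strategy": {
                "kind": self.strategy.kind,
                "ratio": self.strategy.ratio,
                "components": [list(c) for c in self.strategy.components],
                "deidentify": self.strategy.deidentify,
            },
            "filler": self.filler_spec,
            "postprocess": {
                "fill_placeholders": self.fill_placeholders,
                "correct_spelling": self.correct_spelling,
            },
            "seed": self.seed,
            "ratios_grid": list(self.ratios_grid),
            "max_lines_grid": list(self.max_lines_grid),
            "fixtures": self.fixtures,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def make_filler(spec: dict, seed: int = 0):
    """Build a filler backend from its config spec.

    Names: ``identity``, ``constant`` (takes ``word``), ``lexicon``
    (seeded mock LM), ``noisy`` (wraps ``base`` with ``invalid_rate``).
    """
    from . import adapters

    name = spec.get("name", "lexicon")
    dialect = spec.get("dialect", "encoder_mask")
    if name == "identity":
        return adapters.IdentityFiller(dialect=dialect)
    if name == "constant":
        return adapters.ConstantFiller(word=spec.get("word", "patient"), dialect=dialect)
    if name == "lexicon":
        return adapters.LexiconFiller(seed=int(spec.get("seed", seed)), dialect=dialect)
    if name == "noisy":
        base = make_filler(dict(spec.get("base", {"name": "lexicon"})), seed=seed)
        return adapters.NoisyFiller(
            base, invalid_rate=float(spec.get("invalid_rate", 0.1)), seed=int(spec.get("seed", seed))
        )
    raise ValueError(f"unknown filler {name!r}")
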