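"""Run configuration for scans and domain calling (YAML-loadable)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence, TextIO

import yaml

from .domain_caller import CallerConfig, ScoreWeights
from .motif_engine import (
    AnchorAlphabet,
    MotifClassSpec,
    MotifConfigError,
    get_alphabet,
    get_class,
)


@dataclass(frozen=True)
class ScanConfig:
    """Everything a scan/call run needs; unknown names rejected at load."""

    alphabet: str = "strict"
    classes: tuple[str, ...] = ("1-10", "1-12", "1-14", "1-16", "1-5-10", "1-5-8-14")
    iq: bool = True
    min_length: int = 15
    max_length: int = 27
    threshold: float = 2.0
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    output_format: str = "tsv"
    seed: int = 0

    def __post_init__(self) -> None:
        self.resolve_alphabet()  # validates the name
        self.resolve_classes()
        if self.output_format not in ("tsv", "json"):
            raise MotifConfigError(f"unknown output format {self.output_format!r}")

    def resolve_alphabet(self) -> AnchorAlphabet:
        return get_alphabet(self.alphabet)

    def resolve_classes(self) -> tuple[MotifClassSpec, ...]:
        return tuple(get_class(name) for name in self.classes)

    def caller_config(self) -> CallerConfig:
        return CallerConfig(
            min_length=self.min_length,
            max_length=self.max_length,
            threshold=self.threshold,
            weights=self.weights,
            classes=self.resolve_classes(),
            alphabet=self.resolve_alphabet(),
        )


def load_config(handle: TextIO | str) -> ScanConfig:
    """Load a :class:`ScanConfig` from YAML text or an open handle."""
    raw = yaml.safe_load(handle if isinstance(handle, str) else handle.read()) or {}
    known = {f.name for f in fields(ScanConfig)}
    unknown = set(raw) - known
    if unknown:
        raise MotifConfigError(f"unknown config keys: {sorted(unknown)}")
    if "classes" in raw:
        raw["classes"] = tuple(raw["classes"])
    if "weights" in raw:
        raw["weights"] = ScoreWeights(**raw["weights"])
    return ScanConfig(**raw)
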