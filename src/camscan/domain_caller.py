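"""Heuristic calmodulin-binding-domain window caller.

Canonical calcium-dependent CaM-binding domains are short (~14-27 residue)
basic amphipathic helices. This module proposes candidate windows in a
full-length protein by sliding windows over the sequence and scoring four
properties that characterise such helices:

* anchor-motif density — hits of the canonical spacing classes per residue;
* net positive charge — +1 per R/K, -1 per D/E, floored at zero in the
  composite (CaM-binding helices are basic; acidity is merely not rewarded);
* mean hydropathy (Eisenberg consensus scale);
* hydrophobic moment — the magnitude of the helical-wheel vector sum of
  mean-centred hydropathies at 100 degrees per residue, the standard
  measure of amphipathicity. Mean-centring makes the moment measure
  *periodic variation* of hydropathy, so a compositionally uniform window
  (e.g. poly-glycine) scores exactly zero.

Prolines break helices, so each P in the window subtracts a penalty.

This caller is an explicitly heuristic stand-in for profile-HMM web
predictors of CaM binding; it is not trained on their output and makes no
attempt to reproduce their boundaries. Corpus reproduction elsewhere in
this package scans literature-reported domains directly and does not route
through this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .motif_engine import (
    DEFAULT_CLASSES,
    STRICT,
    AnchorAlphabet,
    MotifClassSpec,
    MotifHit,
    scan_all_classes,
)
from .sequence_io import ProteinRecord

#: Eisenberg consensus hydropathy scale (unitless, roughly -2.5 .. +1.4).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    "X": 0.0,
}

#: degrees of helical rotation per residue in an ideal alpha helix
HELIX_ANGLE = 100.0


class CallerConfigError(ValueError):
    """Nonsensical caller configuration."""


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite window score.

    Defaults put most weight on motif density (the most specific signal):
    a 20-mer with five canonical motif hits contributes 10 * 5/20 = 2.5 on
    its own, clearing the default threshold of 2.0, while typical
    background windows do not.
    """

    motif_density: float = 10.0
    net_charge: float = 0.2
    mean_hydropathy: float = 0.5
    hydrophobic_moment: float = 1.0
    proline_penalty: float = 0.5


@dataclass(frozen=True)
class CallerConfig:
    min_length: int = 15
    max_length: int = 27
    threshold: float = 2.0
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    classes: tuple[MotifClassSpec, ...] = DEFAULT_CLASSES
    alphabet: AnchorAlphabet = STRICT

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_length > self.max_length:
            raise CallerConfigError(
                f"invalid window-length range {self.min_length}..{self.max_length}"
            )


@dataclass(frozen=True)
class WindowScore:
    start: int  # 1-based inclusive
    end: int
    motif_density: float
    net_charge: int
    mean_hydropathy: float
    hydrophobic_moment: float
    proline_count: int
    composite: float


@dataclass(frozen=True)
class DomainCandidate:
    protein_id: str
    start: int
    end: int
    score: float
    motif_hits: tuple[MotifHit, ...]


def hydrophobic_moment(window: str, angle: float = HELIX_ANGLE) -> float:
    """Helical hydrophobic moment of *window*, on mean-centred hydropathies.

    mu_H = | sum_k (h_k - h_bar) * exp(i * angle * k) |, angle in degrees.
    Mean-centring measures amphipathic periodicity rather than bulk
    hydrophobicity; a uniform-composition window scores exactly 0.
    """
    values = [EISENBERG[res] for res in window]
    if not values:
        return 0.0
    mean = sum(values) / len(values)
    step = math.radians(angle)
    sin_sum = sum((h - mean) * math.sin(step * k) for k, h in enumerate(values))
    cos_sum = sum((h - mean) * math.cos(step * k) for k, h in enumerate(values))
    return math.hypot(sin_sum, cos_sum)


def score_window(
    sequence: str,
    start: int,
    end: int,
    weights: ScoreWeights | None = None,
    alphabet: AnchorAlphabet = STRICT,
    classes: Sequence[MotifClassSpec] = DEFAULT_CLASSES,
) -> WindowScore:
    """Score the window [start, end] (1-based inclusive) of *sequence*."""
    if weights is None:
        weights = ScoreWeights()
    if start < 1 or end > len(sequence) or start > end:
        raise IndexError(
            f"window {start}..{end} out of bounds for sequence of length {len(sequence)}"
        )
    window = sequence[start - 1 : end].upper()
    n = len(window)
    hits = [h for hit_list in scan_all_classes(window, classes, alphabet).values() for h in hit_list]
    density = len(hits) / n
    charge = sum(+1 for r in window if r in "RK") - sum(1 for r in window if r in "DE")
    hydropathy = sum(EISENBERG[r] for r in window) / n
    moment = hydrophobic_moment(window)
    prolines = window.count("P")
    composite = (
        weights.motif_density * density
        + weights.net_charge * max(charge, 0)
        + weights.mean_hydropathy * hydropathy
        + weights.hydrophobic_moment * moment
        - weights.proline_penalty * prolines
    )
    return WindowScore(
        start=start,
        end=end,
        motif_density=density,
        net_charge=charge,
        mean_hydropathy=hydropathy,
        hydrophobic_moment=moment,
        proline_count=prolines,
        composite=composite,
    )


def call_domains(record: ProteinRecord, config: CallerConfig | None = None) -> list[DomainCandidate]:
    """Propose non-overlapping candidate CaMBD windows in one protein.

    All window lengths in the configured range are slid over the sequence;
    windows scoring at least the threshold are retained and overlaps are
    resolved greedily by descending composite score, ties broken by smaller
    start then shorter window. Deterministic for a fixed configuration.
    """
    if config is None:
        config = CallerConfig()
    scored: list[tuple[WindowScore, list[MotifHit]]] = []
    seq = record.sequence
    for length in range(config.min_length, config.max_length + 1):
        for start in range(1, len(seq) - length + 2):
            ws = score_window(
                seq, start, start + length - 1,
                weights=config.weights, alphabet=config.alphabet, classes=config.classes,
            )
            if ws.composite >= config.threshold:
                window = seq[start - 1 : start + length - 1]
                hits = [
                    h
                    for hit_list in scan_all_classes(window, config.classes, config.alphabet).values()
                    for h in hit_list
                ]
                scored.append((ws, hits))
    scored.sort(key=lambda item: (-item[0].composite, item[0].start, item[0].end))
    chosen: list[DomainCandidate] = []
    for ws, hits in scored:
        if any(not (ws.end < c.start or ws.start > c.end) for c in chosen):
            continue
        chosen.append(
            DomainCandidate(
                protein_id=record.id,
                start=ws.start,
                end=ws.end,
                score=ws.composite,
                motif_hits=tuple(hits),
            )
        )
    chosen.sort(key=lambda c: c.start)
    return chosen


def candidates_to_bed(candidates: Sequence[DomainCandidate]) -> str:
    """BED-like TSV: protein id, 0-based half-open start, end, score."""
    lines = [
        f"{c.protein_id}\t{c.start - 1}\t{c.end}\t{c.score:.4f}"
        for c in candidates
    ]
    return "\n".join(lines) + ("\n" if lines else "")
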