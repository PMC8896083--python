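"""Synthetic protein backgrounds and planted-motif benchmarks.

Real evaluation of a motif scanner needs sequences with known ground truth.
This module generates i.i.d. random protein backgrounds of a configurable
residue composition and plants anchor-spacing motifs (or whole domain
templates) at known coordinates, recording a truth table, so that scanner
sensitivity and background hit rates can be measured without any external
sequence database.

Planting overwrites residues in place rather than inserting, so sequence
length and all downstream coordinates stay stable. Within the planted
span, anchor offsets receive residues drawn from the anchor alphabet and
every other position receives a non-anchor residue, which guarantees the
planted occurrence is detectable at exactly its planted start (chance hits
elsewhere in the background remain possible and are part of the null).

For an i.i.d. background with per-residue anchor probability ``p``, a
two-anchor class of span ``s`` has expected hit count ``p**2 * (L - s + 1)``
per length-``L`` sequence; :func:`expected_background_hits` provides this
closed form as the analytic check for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .motif_engine import STRICT, AnchorAlphabet, MotifClassSpec, get_class
from .sequence_io import ProteinRecord, write_fasta

AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

#: simplest null: every residue equally likely
UNIFORM_COMPOSITION: dict[str, float] = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}

#: average human proteome residue frequencies (percent scale, normalised on use)
HUMAN_COMPOSITION: dict[str, float] = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}

COMPOSITIONS: dict[str, Mapping[str, float]] = {
    "uniform": UNIFORM_COMPOSITION,
    "human": HUMAN_COMPOSITION,
}


class SyntheticSpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class Planted:
    """One planting instruction, applied to every generated sequence.

    ``kind`` is a motif class name (``"1-10"`` ...) or ``template:<RESIDUES>``
    for a literal domain template. ``position`` is the 1-based start, or
    None to draw a uniform random valid start per sequence.
    """

    kind: str
    position: int | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    n_sequences: int = 100
    length: int = 50
    composition: Mapping[str, float] | str = "uniform"
    planted: tuple[Planted, ...] = ()
    seed: int = 0
    alphabet: AnchorAlphabet = STRICT
    id_prefix: str = "syn"


def _resolve_composition(composition: Mapping[str, float] | str) -> np.ndarray:
    if isinstance(composition, str):
        try:
            composition = COMPOSITIONS[composition]
        except KeyError:
            raise SyntheticSpecError(
                f"unknown composition preset {composition!r}; "
                f"choose from {sorted(COMPOSITIONS)}"
            ) from None
    probs = np.array([float(composition.get(aa, 0.0)) for aa in AMINO_ACIDS])
    if np.any(probs < 0) or probs.sum() <= 0:
        raise SyntheticSpecError("composition must be non-negative with positive sum")
    unknown = set(composition) - set(AMINO_ACIDS)
    if unknown:
        raise SyntheticSpecError(f"composition names non-standard residues {sorted(unknown)}")
    return probs / probs.sum()


def anchor_probability(
    composition: Mapping[str, float] | str, alphabet: AnchorAlphabet = STRICT
) -> float:
    """Probability that one background residue is an anchor."""
    probs = _resolve_composition(composition)
    return float(sum(p for aa, p in zip(AMINO_ACIDS, probs) if aa in alphabet))


def expected_background_hits(
    spec_class: MotifClassSpec,
    length: int,
    composition: Mapping[str, float] | str = "uniform",
    alphabet: AnchorAlphabet = STRICT,
) -> float:
    """Closed-form expected chance hits per i.i.d. sequence of *length*.

    Each of the ``L - span + 1`` start positions is a hit independently
    with probability ``p ** k`` (k anchors, anchor probability p), so the
    expectation is ``p**k * (L - span + 1)``; zero when the sequence is
    shorter than the span.
    """
    n_starts = max(length - spec_class.span + 1, 0)
    p = anchor_probability(composition, alphabet)
    return p ** len(spec_class.offsets) * n_starts


def generate_background(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Generate i.i.d. background sequences, deterministic under the seed."""
    if spec.n_sequences < 0 or spec.length < 1:
        raise SyntheticSpecError("need n_sequences >= 0 and length >= 1")
    probs = _resolve_composition(spec.composition)
    rng = np.random.default_rng(spec.seed)
    letters = np.array(AMINO_ACIDS)
    records = []
    for i in range(spec.n_sequences):
        seq = "".join(rng.choice(letters, size=spec.length, p=probs))
        records.append(ProteinRecord(id=f"{spec.id_prefix}{i:04d}", sequence=seq))
    return records


def plant_motif(
    record: ProteinRecord,
    spec_class: MotifClassSpec,
    position: int,
    alphabet: AnchorAlphabet = STRICT,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinRecord, dict]:
    """Overwrite a window of *record* so one occurrence of *spec_class*
    starts at *position* (1-based).

    Anchor offsets get residues sampled from *alphabet*; the remaining
    positions inside the span get residues sampled outside it. Returns the
    modified record and a ground-truth row (id, kind, start, end).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    span = spec_class.span
    if position < 1 or position + span - 1 > record.length:
        raise SyntheticSpecError(
            f"{record.id}: class {spec_class.name} (span {span}) at position "
            f"{position} overflows length {record.length}"
        )
    anchors = sorted(alphabet.residues)
    non_anchors = sorted(set(AMINO_ACIDS) - alphabet.residues)
    if not non_anchors:
        raise SyntheticSpecError("alphabet covers all residues; cannot build filler")
    seq = list(record.sequence)
    offset_set = set(spec_class.offsets)
    for off in range(span):
        pool = anchors if off in offset_set else non_anchors
        seq[position - 1 + off] = pool[int(rng.integers(len(pool)))]
    truth = {
        "sequence_id": record.id,
        "kind": spec_class.name,
        "start": position,
        "end": position + span - 1,
    }
    return replace(record, sequence="".join(seq)), truth


def plant_template(
    record: ProteinRecord, template: str, position: int
) -> tuple[ProteinRecord, dict]:
    """Overwrite a window with a literal domain template."""
    if position < 1 or position + len(template) - 1 > record.length:
        raise SyntheticSpecError(
            f"{record.id}: template of length {len(template)} at position "
            f"{position} overflows length {record.length}"
        )
    seq = list(record.sequence)
    seq[position - 1 : position - 1 + len(template)] = list(template.upper())
    truth = {
        "sequence_id": record.id,
        "kind": "template",
        "start": position,
        "end": position + len(template) - 1,
    }
    return replace(record, sequence="".join(seq)), truth


@dataclass(frozen=True)
class Benchmark:
    """Generated sequences plus the ground-truth table of planted features."""

    records: tuple[ProteinRecord, ...]
    truth: pd.DataFrame = field(repr=False)

    def write(self, fasta_handle: TextIO, truth_handle: TextIO) -> None:
        write_fasta(self.records, fasta_handle)
        self.truth.to_csv(truth_handle, sep="\t", index=False)


def make_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Generate a planted-motif benchmark with its truth table.

    Each planting instruction is applied to every sequence; instructions
    with ``position=None`` get an independent uniform random valid start
    per sequence. Fully deterministic under ``spec.seed``.
    """
    records = generate_background(spec)
    rng = np.random.default_rng(spec.seed + 1)  # separate stream from background
    truth_rows: list[dict] = []
    planted_records: list[ProteinRecord] = []
    for record in records:
        for instruction in spec.planted:
            if instruction.kind.startswith("template:"):
                template = instruction.kind.split(":", 1)[1]
                span = len(template)
            else:
                template = None
                span = get_class(instruction.kind).span
            if instruction.position is None:
                max_start = record.length - span + 1
                if max_start < 1:
                    raise SyntheticSpecError(
                        f"span {span} does not fit in length {record.length}"
                    )
                position = int(rng.integers(1, max_start + 1))
            else:
                position = instruction.position
            if template is not None:
                record, row = plant_template(record, template, position)
            else:
                record, row = plant_motif(
                    record, get_class(instruction.kind), position, spec.alphabet, rng
                )
            truth_rows.append(row)
        planted_records.append(record)
    truth = pd.DataFrame(truth_rows, columns=["sequence_id", "kind", "start", "end"])
    return Benchmark(records=tuple(planted_records), truth=truth)
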