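"""Enumeration of calmodulin-binding motifs in protein sequences.

Calcium-dependent calmodulin binding is mediated by short basic amphipathic
helices in which two to four bulky hydrophobic "anchor" residues sit at
characteristic spacings. The canonical classes are named by the 1-based
anchor positions within the motif window: 1-10, 1-12, 1-14, 1-16 (two
anchors) and 1-5-10, 1-5-8-14 (three / four anchors). Calcium-independent
binding is mediated by IQ motifs, canonically
``[FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]``.

The scan is exhaustive and overlap-tolerant: every start position whose
anchor offsets all carry an anchor residue yields a hit, overlapping hits
are all reported, and no deduplication is performed across classes (a
1-5-10 occurrence always implies a 1-10 occurrence at the same outer
anchors, and both are counted). This mirrors how motif tallies are reported
in the calmodulin literature, where shared anchors are counted once per
class.

The default anchor alphabet is the strict hydrophobic set {F, I, L, V, W};
M, A and Y extensions are available because some published tallies can only
be reached by admitting them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import STANDARD_AA

IQ_CANONICAL = "IQ"
IQ_LIKE = "IQ-like"


class MotifConfigError(ValueError):
    """Invalid motif-scan configuration (unknown/duplicate class or alphabet)."""


@dataclass(frozen=True)
class AnchorAlphabet:
    """A named set of residues treated as hydrophobic anchors."""

    name: str
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise MotifConfigError(f"alphabet {self.name!r} has no residues")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise MotifConfigError(
                f"alphabet {self.name!r} contains non-standard residues {sorted(bad)}"
            )

    def __contains__(self, letter: str) -> bool:
        return letter in self.residues


STRICT = AnchorAlphabet("strict", frozenset("FILVW"))

ALPHABETS: dict[str, AnchorAlphabet] = {
    "strict": STRICT,
    "strict+M": AnchorAlphabet("strict+M", frozenset("FILVWM")),
    "strict+A": AnchorAlphabet("strict+A", frozenset("FILVWA")),
    "strict+Y": AnchorAlphabet("strict+Y", frozenset("FILVWY")),
}


def get_alphabet(name: str) -> AnchorAlphabet:
    """Resolve an alphabet by registry name or ``custom:<letters>``."""
    if name in ALPHABETS:
        return ALPHABETS[name]
    if name.startswith("custom:"):
        letters = name.split(":", 1)[1].upper()
        return AnchorAlphabet(name, frozenset(letters))
    raise MotifConfigError(
        f"unknown alphabet {name!r}; choose one of {sorted(ALPHABETS)} or custom:<letters>"
    )


@dataclass(frozen=True)
class MotifClassSpec:
    """A motif class defined by its relative anchor offsets (first = 0)."""

    name: str
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.offsets or self.offsets[0] != 0:
            raise MotifConfigError(f"class {self.name!r}: offsets must start at 0")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise MotifConfigError(
                f"class {self.name!r}: offsets must be strictly increasing"
            )

    @property
    def span(self) -> int:
        """Nominal motif length (last anchor offset + 1)."""
        return self.offsets[-1] + 1


DEFAULT_CLASSES: tuple[MotifClassSpec, ...] = (
    MotifClassSpec("1-10", (0, 9)),
    MotifClassSpec("1-12", (0, 11)),
    MotifClassSpec("1-14", (0, 13)),
    MotifClassSpec("1-16", (0, 15)),
    MotifClassSpec("1-5-10", (0, 4, 9)),
    MotifClassSpec("1-5-8-14", (0, 4, 7, 13)),
)

CLASS_REGISTRY: dict[str, MotifClassSpec] = {c.name: c for c in DEFAULT_CLASSES}


def get_class(name: str) -> MotifClassSpec:
    try:
        return CLASS_REGISTRY[name]
    except KeyError:
        raise MotifConfigError(
            f"unknown motif class {name!r}; known classes: {sorted(CLASS_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of an anchor-spacing class within a scanned sequence."""

    class_name: str
    anchor_positions: tuple[int, ...]  # 1-based within the scanned sequence
    anchor_residues: tuple[str, ...]

    @property
    def span_start(self) -> int:
        return self.anchor_positions[0]

    @property
    def span_end(self) -> int:
        return self.anchor_positions[-1]


@dataclass(frozen=True)
class IQHit:
    """An IQ (canonical) or IQ-like (relaxed head) occurrence."""

    variant: str  # IQ or IQ-like
    start: int  # 1-based position of the first pattern residue
    matched_text: str


def enumerate_anchor_motifs(
    sequence: str,
    spec: MotifClassSpec,
    alphabet: AnchorAlphabet = STRICT,
) -> list[MotifHit]:
    """Exhaustively enumerate occurrences of one anchor-spacing class.

    A hit is any 1-based start position ``i`` such that the residue at
    ``i + offset`` is in the anchor alphabet for every offset of the class.
    Sequences shorter than the class span yield the empty list. Hits are
    returned sorted by start position.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    last_start = len(seq) - spec.span  # 0-based
    for i in range(last_start + 1):
        residues = tuple(seq[i + off] for off in spec.offsets)
        if all(res in alphabet for res in residues):
            hits.append(
                MotifHit(
                    class_name=spec.name,
                    anchor_positions=tuple(i + 1 + off for off in spec.offsets),
                    anchor_residues=residues,
                )
            )
    return hits


def scan_all_classes(
    sequence: str,
    classes: Sequence[MotifClassSpec] = DEFAULT_CLASSES,
    alphabet: AnchorAlphabet = STRICT,
) -> dict[str, list[MotifHit]]:
    """Scan one sequence against a roster of classes.

    Every class appears in the result, including classes with zero hits.
    Duplicate class names are a configuration error.
    """
    if not classes:
        raise MotifConfigError("class roster is empty")
    names = [c.name for c in classes]
    if len(set(names)) != len(names):
        raise MotifConfigError(f"duplicate class names in roster: {names}")
    return {c.name: enumerate_anchor_motifs(sequence, c, alphabet) for c in classes}


# Canonical IQ: [FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]  (14 residues).
# IQ-like: the relaxed head [FILVWY]Qxxx[RK]G (7 residues) — accepts
# incomplete variants whose tail degenerates.
_IQ_CANONICAL_RE = re.compile(r"(?=([FILV]Q[A-Z]{3}[RK]G[A-Z]{3}[RK][A-Z]{2}[FILVWY]))")
_IQ_RELAXED_RE = re.compile(r"(?=([FILVWY]Q[A-Z]{3}[RK]G))")


def scan_iq(sequence: str) -> list[IQHit]:
    """Find calcium-independent IQ and IQ-like motifs (overlaps reported).

    Positions matching the full canonical pattern are reported as ``IQ``;
    positions matching only the relaxed head pattern are ``IQ-like``.
    """
    seq = sequence.upper()
    canonical = {m.start(): m.group(1) for m in _IQ_CANONICAL_RE.finditer(seq)}
    hits = [
        IQHit(IQ_CANONICAL, start=pos + 1, matched_text=text)
        for pos, text in canonical.items()
    ]
    for m in _IQ_RELAXED_RE.finditer(seq):
        if m.start() not in canonical:
            hits.append(IQHit(IQ_LIKE, start=m.start() + 1, matched_text=m.group(1)))
    return sorted(hits, key=lambda h: (h.start, h.variant))


def count_by_class(
    hits: Mapping[str, Sequence[MotifHit]] | Iterable[MotifHit],
    classes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Tally hits per class.

    Accepts either the mapping returned by :func:`scan_all_classes` or a
    flat iterable of hits. ``classes`` forces zero entries for classes with
    no hits (all keys of a mapping input are always included).
    """
    counts: dict[str, int] = {name: 0 for name in (classes or ())}
    if isinstance(hits, Mapping):
        for name, class_hits in hits.items():
            counts[name] = counts.get(name, 0) + len(class_hits)
    else:
        for hit in hits:
            counts[hit.class_name] = counts.get(hit.class_name, 0) + 1
    return counts


def hits_to_table(results: Mapping[str, Mapping[str, Sequence[MotifHit]]]) -> pd.DataFrame:
    """Flatten per-protein scan results to a table, one row per hit.

    *results* maps sequence id -> class name -> hits.
    """
    rows = []
    for seq_id, by_class in results.items():
        for class_name, hits in by_class.items():
            for hit in hits:
                rows.append(
                    {
                        "sequence_id": seq_id,
                        "class": class_name,
                        "anchor_positions": ",".join(map(str, hit.anchor_positions)),
                        "anchor_residues": "".join(hit.anchor_residues),
                    }
                )
    return pd.DataFrame(rows, columns=["sequence_id", "class", "anchor_positions", "anchor_residues"])


def report_to_json(
    results: Mapping[str, Mapping[str, Sequence[MotifHit]]],
    iq_results: Mapping[str, Sequence[IQHit]] | None = None,
) -> str:
    """Render per-protein scan results as a nested JSON report."""
    report: dict[str, dict] = {}
    for seq_id, by_class in results.items():
        report[seq_id] = {
            "counts": count_by_class(by_class),
            "hits": {
                name: [
                    {
                        "anchor_positions": list(h.anchor_positions),
                        "anchor_residues": list(h.anchor_residues),
                    }
                    for h in hits
                ]
                for name, hits in by_class.items()
            },
        }
        if iq_results is not None:
            report[seq_id]["iq"] = [
                {"variant": h.variant, "start": h.start, "matched_text": h.matched_text}
                for h in iq_results.get(seq_id, ())
            ]
    return json.dumps(report, indent=2)
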