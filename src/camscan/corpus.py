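"""Curated corpus of literature-reported CaMBDs and the CaMBP inventory.

The corpus packages, as plain-text fixtures, the calmodulin-binding domains
reported for 11 human neuroinflammation-linked proteins (13 printed domain
sequences plus a counts-only CD33 entry), each with its reported per-class
motif tally; the 13 previously established neuroinflammation CaMBPs; and
the protein-disease links stated in the source review's running text.

Its central operation, :func:`reproduce_counts`, re-derives every reported
motif tally by systematic enumeration under a chosen anchor alphabet and
reports agreement domain-by-domain and class-by-class. The original tallies
came from a visual scan, and several of them are not reproducible under any
single uniform anchor alphabet; the concordance report surfaces those as
explicit mismatches instead of forcing agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .motif_engine import (
    DEFAULT_CLASSES,
    STRICT,
    AnchorAlphabet,
    MotifClassSpec,
    enumerate_anchor_motifs,
)
from .sequence_io import DomainAnnotation, parse_domain_string

DISEASES = ("AD", "ALS", "FTD", "HD", "LBD", "PD", "MS", "BD/NCL")


class CorpusIntegrityError(RuntimeError):
    """Packaged fixtures are corrupted or internally inconsistent."""


@dataclass(frozen=True)
class CorpusEntry:
    """One reported CaMBD: protein, printed notation, reported tallies."""

    protein: str
    domain_label: str
    domain_string: str | None
    printed_counts: Mapping[str, int]
    notes: str
    annotation: DomainAnnotation | None

    @property
    def has_sequence(self) -> bool:
        return self.annotation is not None

    @property
    def name(self) -> str:
        return f"{self.protein} {self.domain_label}"


@dataclass(frozen=True)
class DiseaseLink:
    protein: str
    diseases: tuple[str, ...]
    source: str


def _load_yaml(filename: str) -> dict:
    path = resources.files("camscan").joinpath("data", filename)
    with path.open("r", encoding="utf-8") as handle:
        return yaml.safe_load(handle)


def load_corpus() -> list[CorpusEntry]:
    """Load and validate the packaged CaMBD corpus.

    Returns 14 entries: 13 with printed domain sequences across 10 proteins
    plus the counts-only CD33 entry (11 proteins in total). Every domain
    string must parse; coordinate inconsistencies are flagged on the
    annotation, never corrected.
    """
    raw = _load_yaml("corpus.yaml")
    entries: list[CorpusEntry] = []
    for item in raw["entries"]:
        domain_string = item["domain_string"]
        annotation = (
            parse_domain_string(domain_string, protein_id=item["protein"])
            if domain_string is not None
            else None
        )
        entries.append(
            CorpusEntry(
                protein=item["protein"],
                domain_label=item["label"],
                domain_string=domain_string,
                printed_counts=dict(item["printed_counts"]),
                notes=item.get("notes") or "",
                annotation=annotation,
            )
        )
    with_seq = [e for e in entries if e.has_sequence]
    if len(with_seq) != 13 or len({e.protein for e in entries}) != 11:
        raise CorpusIntegrityError(
            f"corpus fixture corrupted: {len(with_seq)} sequence entries, "
            f"{len({e.protein for e in entries})} proteins"
        )
    return entries


def load_iq_regions() -> list[DomainAnnotation]:
    """The reported calcium-independent (IQ-family) regions, as annotations."""
    raw = _load_yaml("corpus.yaml")
    return [
        parse_domain_string(item["domain_string"], protein_id=item["protein"])
        for item in raw["iq_regions"]
    ]


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-domain, per-class comparison of reported vs enumerated counts."""

    table: pd.DataFrame  # columns: protein, domain, class, printed, computed, match
    skipped: tuple[str, ...]  # entries without sequence
    alphabet: str

    @property
    def n_match(self) -> int:
        return int(self.table["match"].sum())

    @property
    def n_mismatch(self) -> int:
        return int((~self.table["match"]).sum())

    @property
    def mismatches(self) -> pd.DataFrame:
        return self.table[~self.table["match"]].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Concordance of reported vs enumerated motif counts "
            f"(alphabet: {self.alphabet})",
            f"  compared: {len(self.table)} (domain, class) pairs across "
            f"{self.table['protein'].nunique()} proteins",
            f"  matches: {self.n_match}   mismatches: {self.n_mismatch}",
        ]
        if self.skipped:
            lines.append(f"  skipped (no printed sequence): {', '.join(self.skipped)}")
        if self.n_mismatch:
            lines.append("  mismatching tallies (reported != enumerated):")
            for _, row in self.mismatches.iterrows():
                lines.append(
                    f"    {row['protein']} {row['domain']} {row['class']}: "
                    f"reported {row['printed']}, enumerated {row['computed']}"
                )
        return "\n".join(lines)


def reproduce_counts(
    alphabet: AnchorAlphabet = STRICT,
    classes: Sequence[MotifClassSpec] = DEFAULT_CLASSES,
    entries: Sequence[CorpusEntry] | None = None,
) -> ConcordanceReport:
    """Re-derive every reported motif tally by exhaustive enumeration.

    For each corpus entry with a sequence and each class for which the
    source text reports a count, the enumerated count under *alphabet* is
    compared with the reported one. Entries without a sequence are skipped
    and listed in the report. Disagreements are reported, never suppressed.
    """
    if entries is None:
        entries = load_corpus()
    class_by_name = {c.name: c for c in classes}
    rows = []
    skipped = []
    for entry in entries:
        if not entry.has_sequence:
            skipped.append(entry.name)
            continue
        for class_name, printed in entry.printed_counts.items():
            spec = class_by_name.get(class_name)
            if spec is None:
                raise CorpusIntegrityError(
                    f"{entry.name}: reported count for unknown class {class_name!r}"
                )
            computed = len(
                enumerate_anchor_motifs(entry.annotation.sequence, spec, alphabet)
            )
            rows.append(
                {
                    "protein": entry.protein,
                    "domain": entry.domain_label,
                    "class": class_name,
                    "printed": printed,
                    "computed": computed,
                    "match": printed == computed,
                }
            )
    table = pd.DataFrame(rows, columns=["protein", "domain", "class", "printed", "computed", "match"])
    return ConcordanceReport(table=table, skipped=tuple(skipped), alphabet=alphabet.name)


@dataclass(frozen=True)
class Inventory:
    """The scanned-here / previously-identified CaMBP union."""

    scanned: frozenset[str]
    prior: frozenset[str]
    overlap: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.scanned | self.prior

    @property
    def n_union(self) -> int:
        return len(self.union)

    def provenance(self) -> dict[str, str]:
        out = {}
        for protein in sorted(self.union):
            if protein in self.overlap:
                out[protein] = "scanned-here+previously-identified"
            elif protein in self.scanned:
                out[protein] = "scanned-here"
            else:
                out[protein] = "previously-identified"
        return out


def inventory_union() -> Inventory:
    """Union of the 11 scanned proteins with the 13 prior CaMBPs.

    A protein appearing in both lists is flagged as overlap and counted
    once. Idempotent and order-independent (set semantics).
    """
    raw = _load_yaml("inventory.yaml")
    scanned = frozenset(raw["scanned"])
    prior = frozenset(raw["prior"])
    if len(scanned) != len(raw["scanned"]) or len(prior) != len(raw["prior"]):
        raise CorpusIntegrityError("duplicate protein within an inventory list")
    return Inventory(scanned=scanned, prior=prior, overlap=scanned & prior)


def load_disease_links() -> list[DiseaseLink]:
    raw = _load_yaml("inventory.yaml")
    links = []
    for item in raw["disease_links"]:
        bad = set(item["diseases"]) - set(DISEASES)
        if bad:
            raise CorpusIntegrityError(
                f"{item['protein']}: unknown disease code(s) {sorted(bad)}"
            )
        links.append(
            DiseaseLink(
                protein=item["protein"],
                diseases=tuple(item["diseases"]),
                source=item["source"],
            )
        )
    return links


def disease_matrix() -> pd.DataFrame:
    """Binary protein x disease incidence matrix of text-stated links only.

    Rows are proteins with at least one stated link, columns the disease
    codes in :data:`DISEASES`. Row/column marginals are available via
    ``matrix.sum(axis=1)`` / ``matrix.sum(axis=0)``.
    """
    links = load_disease_links()
    proteins = [link.protein for link in links]
    matrix = pd.DataFrame(0, index=proteins, columns=list(DISEASES), dtype=int)
    for link in links:
        for disease in link.diseases:
            matrix.loc[link.protein, disease] = 1
    matrix.index.name = "protein"
    return matrix
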