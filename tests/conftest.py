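"""Shared fixtures and the independent brute-force motif oracle.

The oracle deliberately uses a different mechanism from the scanner under
test: it compiles each anchor-spacing class to a regular expression with a
zero-width lookahead (so overlapping occurrences are all found) instead of
iterating offsets, and IQ patterns are checked position-by-position by
hand-written predicates.
"""

from __future__ import annotations

import re

import pytest
from hypothesis import settings

from camscan import load_corpus

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from camscan.motif_engine import AnchorAlphabet, MotifClassSpec


def regex_oracle_starts(
    sequence: str, spec: MotifClassSpec, alphabet: AnchorAlphabet
) -> list[int]:
    """1-based start positions of all class occurrences, via lookahead regex."""
    letters = "".join(sorted(alphabet.residues))
    parts = []
    prev = None
    for off in spec.offsets:
        if prev is not None:
            gap = off - prev - 1
            parts.append(".{%d}" % gap if gap else "")
        parts.append(f"[{letters}]")
        prev = off
    pattern = re.compile(r"(?=%s)" % "".join(parts))
    return [m.start() + 1 for m in pattern.finditer(sequence.upper())]


@pytest.fixture(scope="session")
def corpus():
    return load_corpus()


@pytest.fixture(scope="session")
def corpus_by_name(corpus):
    return {entry.name: entry for entry in corpus}
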