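"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's scanning code paths: site
finding is re-done by expanding every degenerate pattern and comparing raw
windows; digestion is re-done by naive splitting at independently computed
cut points.
"""

from __future__ import annotations

import random

import pytest

from capskit.enzymes import RestrictionEnzyme
from capskit.fixtures import generate_reference_system
from capskit.seqcore import expand_degenerate, revcomp

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"


@pytest.fixture(scope="session")
def truth():
    """The packaged synthetic reference system at seed 1."""
    return generate_reference_system(1)


@pytest.fixture(scope="session")
def library():
    from capskit.enzymes import default_enzyme_library

    return default_enzyme_library()


def random_pattern(rng: random.Random, min_len: int = 4, max_len: int = 6) -> str:
    """A random IUPAC recognition pattern biased toward concrete bases."""
    n = rng.randint(min_len, max_len)
    out = []
    for _ in range(n):
        if rng.random() < 0.25:
            out.append(rng.choice("RYSWKMN"))
        else:
            out.append(rng.choice("ACGT"))
    return "".join(out)


def random_enzyme(rng: random.Random, name: str) -> RestrictionEnzyme:
    pat = random_pattern(rng)
    return RestrictionEnzyme(
        name=name,
        recognition=pat,
        cut_top=rng.randint(0, len(pat) + 6),
        cut_bottom=rng.randint(0, len(pat) + 6),
    )


def brute_force_sites(seq: str, enzyme: RestrictionEnzyme) -> set[tuple[int, str]]:
    """Oracle: scan every window against the full degenerate expansion of
    the recognition pattern on both strands.  Returns {(1-based pos, strand)}
    with palindromic duplicates collapsed to '+'."""
    plus = expand_degenerate(enzyme.recognition)
    minus = {revcomp(p) for p in plus}
    L = len(enzyme.recognition)
    hits: set[tuple[int, str]] = set()
    for s in range(len(seq) - L + 1):
        win = seq[s : s + L]
        if win in plus:
            hits.add((s + 1, "+"))
        if win in minus and win not in plus:
            hits.add((s + 1, "-"))
        elif win in minus and win in plus and enzyme.recognition != revcomp(
            enzyme.recognition
        ):
            # degenerate-pattern strands can both match even when the
            # pattern itself is not strictly palindromic
            hits.add((s + 1, "-"))
    return hits


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
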