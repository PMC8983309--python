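"""Core sequence types, IUPAC nucleotide algebra, and FASTA I/O.

Everything downstream (enzyme-site scanning, primer binding, marker design)
is built on three primitives defined here: reverse complementation over the
full IUPAC alphabet, degenerate-pattern matching against concrete sequence,
and cartesian expansion of degenerate strings (the brute-force oracle used
throughout the test suite).

Coordinate conventions: internal computation is 0-based half-open; every
coordinate that crosses a public API boundary (``SiteHit``, ``VariantSpec``,
amplicon start/end) is 1-based inclusive, matching how biologists report
positions ("position 178 from the start codon" means the A of ATG is 1).
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "COMPLEMENT",
    "AlleleRecord",
    "VariantSpec",
    "SequenceError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "iupac_match",
    "expand_degenerate",
    "is_concrete",
]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement of every IUPAC code (R<->Y, K<->M, S/W/N self-complementary,
#: B<->V, D<->H).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_CONCRETE = frozenset("ACGT")


class SequenceError(ValueError):
    """A sequence violates the IUPAC alphabet or a structural invariant."""


class FastaParseError(SequenceError):
    """FASTA input that cannot be parsed; carries the offending line number."""


def _validate_alphabet(seq: str, *, context: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise SequenceError(
                f"illegal character {ch!r} at position {i + 1} in {context} "
                f"(not an IUPAC nucleotide code)"
            )


def normalize(seq: str) -> str:
    """Uppercase a raw sequence and map RNA U to T. Does not validate."""
    return seq.upper().replace("U", "T")


def is_concrete(seq: str) -> bool:
    """True iff every character is a plain A/C/G/T."""
    return all(ch in _CONCRETE for ch in seq)


@dataclass
class AlleleRecord:
    """A named allele sequence — the unit of marker design and genotyping.

    Parameters
    ----------
    id : str
        Allele name, e.g. ``"Rht-B1b"``.
    sequence : str
        Nucleotide sequence over the IUPAC alphabet (normalized to upper
        case, U mapped to T on construction).
    start_codon_pos : int, optional
        1-based position of the A of the ATG start codon.  When set, coding
        coordinates ("position 178 from the start codon") can be reported.
    locus : str, optional
        Locus label shared by allelic variants, e.g. ``"Rht-B1"``.
    """

    id: str
    sequence: str
    start_codon_pos: Optional[int] = None
    locus: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if not self.sequence:
            raise SequenceError(f"allele {self.id!r}: sequence is empty")
        _validate_alphabet(self.sequence, context=f"allele {self.id!r}")
        if self.start_codon_pos is not None:
            p = self.start_codon_pos
            if not (1 <= p <= len(self.sequence) - 2):
                raise SequenceError(
                    f"allele {self.id!r}: start_codon_pos {p} out of range"
                )
            codon = self.sequence[p - 1 : p + 2]
            if codon != "ATG":
                raise SequenceError(
                    f"allele {self.id!r}: 3-mer at start_codon_pos {p} is "
                    f"{codon!r}, expected ATG"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_to_seq(self, cds_pos: int) -> int:
        """Convert a 1-based coding coordinate to a 1-based sequence coordinate."""
        if self.start_codon_pos is None:
            raise SequenceError(f"allele {self.id!r} has no start codon anchor")
        return self.start_codon_pos + cds_pos - 1

    def seq_to_cds(self, seq_pos: int) -> int:
        """Convert a 1-based sequence coordinate to a 1-based coding coordinate."""
        if self.start_codon_pos is None:
            raise SequenceError(f"allele {self.id!r} has no start codon anchor")
        return seq_pos - self.start_codon_pos + 1


@dataclass
class VariantSpec:
    """A single difference between a target allele and its references.

    ``position`` is 1-based from the sequence start; ``cds_position`` (when
    the allele has a start-codon anchor) is 1-based from the A of ATG.
    """

    target_allele: str
    position: int
    kind: str  # "snp" | "insertion"
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    insert_length: Optional[int] = None
    cds_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.kind == "snp":
            if self.ref_base is None or self.alt_base is None:
                raise ValueError("snp requires ref_base and alt_base")
            for b in (self.ref_base, self.alt_base):
                if len(b) != 1 or b not in _CONCRETE:
                    raise ValueError(f"snp bases must be concrete, got {b!r}")
            if self.ref_base == self.alt_base:
                raise ValueError("snp ref_base equals alt_base")
        else:
            if not self.insert_length or self.insert_length < 1:
                raise ValueError("insertion requires insert_length >= 1")


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet.

    >>> revcomp("GATTC")
    'GAATC'
    """
    try:
        return "".join(COMPLEMENT[ch] for ch in reversed(seq))
    except KeyError as exc:
        raise SequenceError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def iupac_match(pattern: str, text: str) -> bool:
    """True iff ``text`` (concrete A/C/G/T) is one realization of ``pattern``.

    Raises on length mismatch; a non-concrete ``text`` base never matches
    (conservative: ambiguous template positions do not support a site call).
    """
    if len(pattern) != len(text):
        raise SequenceError(
            f"length mismatch: pattern {len(pattern)} vs text {len(text)}"
        )
    _validate_alphabet(pattern, context="pattern")
    for p, t in zip(pattern, text):
        if t not in _CONCRETE or t not in IUPAC_CODES[p]:
            return False
    return True


def expand_degenerate(pattern: str) -> set[str]:
    """Cartesian expansion of a degenerate pattern into concrete strings.

    The result size is the product of per-position code cardinalities
    (``CTRYAG`` -> 4 strings, ``NN`` -> 16).
    """
    _validate_alphabet(pattern, context="pattern")
    if pattern == "":
        return {""}
    return {"".join(t) for t in product(*(sorted(IUPAC_CODES[c]) for c in pattern))}


def read_fasta(path: str | Path) -> list[AlleleRecord]:
    """Read a (multi-)FASTA file into :class:`AlleleRecord` objects.

    Ids are taken from headers up to the first whitespace; sequences are
    upper-cased with U mapped to T.  Malformed input raises
    :class:`FastaParseError` naming the offending line; an empty file is an
    error.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(AlleleRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[AlleleRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            fh.write(textwrap.fill(rec.sequence, 60))
            fh.write("\n")
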