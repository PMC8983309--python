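"""Restriction-enzyme library, degenerate site scanning, virtual digestion.

An enzyme is described by its IUPAC recognition sequence plus top/bottom
cut offsets measured from the 5' end of the recognition site along the
strand that carries it.  Type IIS enzymes (BstV1I, Acc36I) have offsets
exceeding the site length — they cut downstream of the recognition site,
and a site close to a molecule's end can therefore produce no cut at all.

Fragment boundaries reported by :func:`digest` are top-strand cut indices:
a plus-strand site starting at 0-based ``s`` cuts at ``s + cut_top``; a
minus-strand site spanning ``[s, s+L)`` cuts the top strand at
``s + L - cut_bottom``.  Palindromic sites are reported once, on the plus
strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .seqcore import (
    SequenceError,
    expand_degenerate,
    iupac_match,
    is_concrete,
    revcomp,
)

__all__ = [
    "RestrictionEnzyme",
    "SiteHit",
    "FragmentProfile",
    "EnzymeError",
    "read_enzyme_table",
    "default_enzyme_library",
    "resolve_enzyme",
    "find_sites",
    "digest",
]


class EnzymeError(ValueError):
    """Bad enzyme table, unknown enzyme name, or ambiguous isoschizomer."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition pattern, cut offsets, isoschizomers."""

    name: str
    recognition: str
    cut_top: int = 0
    cut_bottom: int = 0
    isoschizomers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise EnzymeError(
                f"enzyme {self.name}: recognition shorter than 4 bp"
            )
        for ch in self.recognition:
            from .seqcore import IUPAC_CODES

            if ch not in IUPAC_CODES:
                raise EnzymeError(
                    f"enzyme {self.name}: non-IUPAC character {ch!r} "
                    f"in recognition sequence"
                )
        if self.cut_top < 0 or self.cut_bottom < 0:
            raise EnzymeError(f"enzyme {self.name}: negative cut offset")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition

    @property
    def site_length(self) -> int:
        return len(self.recognition)


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site match; ``position`` is the 1-based start of the
    matched window on the plus strand of the scanned sequence."""

    position: int
    strand: str  # "+" | "-"
    enzyme: str


@dataclass
class FragmentProfile:
    """Result of a virtual digestion: the gel-resolvable fragment lengths.

    ``fragment_lengths`` is kept in molecule order (left to right), so it is
    both a multiset and a partition of the source; ``cut_positions`` are
    1-based top-strand boundaries (a cut at position c separates bases c and
    c+1).  ``approximate`` flags profiles computed from an enzyme table with
    omitted (zero) cut offsets, where presence/absence of cutting is reliable
    but sub-fragment sizes are nominal.
    """

    source: str
    fragment_lengths: tuple[int, ...]
    cut_positions: tuple[int, ...]
    approximate: bool = False

    @property
    def is_cut(self) -> bool:
        return len(self.fragment_lengths) > 1

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


def read_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Parse a TSV enzyme table.

    Expected header: ``name  recognition  cut_top  cut_bottom  isoschizomers``
    (isoschizomers semicolon-separated, may be empty).  Duplicate names and
    malformed rows are rejected.
    """
    path = Path(path)
    enzymes: list[RestrictionEnzyme] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "recognition", "cut_top", "cut_bottom"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise EnzymeError(f"{path}: missing columns {missing}")
        for row in reader:
            name = (row["name"] or "").strip()
            if not name:
                continue
            if name in seen:
                raise EnzymeError(f"{path}: duplicate enzyme name {name!r}")
            seen.add(name)
            iso_raw = (row.get("isoschizomers") or "").strip()
            isos = tuple(s.strip() for s in iso_raw.split(";") if s.strip())
            try:
                enz = RestrictionEnzyme(
                    name=name,
                    recognition=(row["recognition"] or "").strip().upper(),
                    cut_top=int(row["cut_top"] or 0),
                    cut_bottom=int(row["cut_bottom"] or 0),
                    isoschizomers=isos,
                )
            except (EnzymeError, ValueError) as exc:
                raise EnzymeError(f"{path}: bad row for {name!r}: {exc}") from exc
            enzymes.append(enz)
    if not enzymes:
        raise EnzymeError(f"{path}: no enzymes parsed")
    return enzymes


def default_enzyme_library() -> list[RestrictionEnzyme]:
    """The packaged default library (BstV1I, Acc36I, BstHHI, HinfI, BstSFI
    with their catalogue isoschizomers)."""
    ref = resources.files("capskit.data").joinpath("default_enzymes.tsv")
    with resources.as_file(ref) as path:
        return read_enzyme_table(path)


def resolve_enzyme(
    name: str, library: Sequence[RestrictionEnzyme]
) -> RestrictionEnzyme:
    """Look up an enzyme by canonical name or isoschizomer, case-insensitive.

    An isoschizomer claimed by two canonical entries is ambiguous and raises.
    """
    q = name.strip().lower()
    direct = [e for e in library if e.name.lower() == q]
    if len(direct) == 1:
        return direct[0]
    via_iso = [
        e for e in library if q in (i.lower() for i in e.isoschizomers)
    ]
    if len(via_iso) == 1:
        return via_iso[0]
    if len(via_iso) > 1:
        names = ", ".join(e.name for e in via_iso)
        raise EnzymeError(
            f"enzyme name {name!r} is ambiguous (isoschizomer of {names})"
        )
    raise EnzymeError(f"unknown enzyme {name!r}")


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[SiteHit]:
    """All recognition-site matches on both strands of a concrete sequence.

    Minus-strand sites are matches of ``revcomp(recognition)`` on the plus
    strand, reported at their plus-strand start.  Palindromic recognition
    sequences yield one hit per locus.  Windows containing ambiguity codes
    (e.g. N) in the template never match.
    """
    pat = enzyme.recognition
    L = len(pat)
    rc = revcomp(pat)
    palindromic = pat == rc
    hits: list[SiteHit] = []
    for s in range(len(seq) - L + 1):
        win = seq[s : s + L]
        if not is_concrete(win):
            continue
        if iupac_match(pat, win):
            hits.append(SiteHit(position=s + 1, strand="+", enzyme=enzyme.name))
        if not palindromic and iupac_match(rc, win):
            hits.append(SiteHit(position=s + 1, strand="-", enzyme=enzyme.name))
    return hits


def digest(amplicon, enzyme: RestrictionEnzyme) -> FragmentProfile:
    """Virtually digest a molecule into a :class:`FragmentProfile`.

    ``amplicon`` is anything with ``.sequence`` and ``.id`` (an
    :class:`~capskit.ispcr.Amplicon` or :class:`~capskit.seqcore.AlleleRecord`)
    or a plain string.  Cuts falling on or outside the molecule boundaries
    are discarded — a Type IIS site near the end whose cut position exceeds
    the molecule produces no cut.  Complete digestion is assumed: every site
    cuts.
    """
    if isinstance(amplicon, str):
        seq, source = amplicon, "sequence"
    else:
        seq, source = amplicon.sequence, amplicon.id
    n = len(seq)
    if n < 1:
        raise SequenceError("cannot digest an empty molecule")
    L = enzyme.site_length
    cuts: set[int] = set()
    for hit in find_sites(seq, enzyme):
        s0 = hit.position - 1
        if hit.strand == "+":
            c = s0 + enzyme.cut_top
        else:
            c = s0 + L - enzyme.cut_bottom
        if 0 < c < n:
            cuts.add(c)
    ordered = tuple(sorted(cuts))
    bounds = (0,) + ordered + (n,)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentProfile(
        source=source,
        fragment_lengths=fragments,
        cut_positions=ordered,
        approximate=(enzyme.cut_top == 0 and enzyme.cut_bottom == 0),
    )
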