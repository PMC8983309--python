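"""In-silico PCR: primer binding, amplicon extraction, nested and
allele-specific modes.

The binding model is the standard e-PCR compromise: a primer binds where
(a) the number of mismatches outside a 3'-terminal clamp does not exceed
``max_mismatches`` and (b) every base of the clamp matches exactly
(IUPAC-aware on the primer side).  Allele-specific PCR falls out of the
clamp: a primer whose 3'-terminal base sits on the diagnostic SNP extends
only on the matching allele, so with ``clamp_length >= 1`` exactly one of
two templates differing at that base yields a product.

Amplicon sequences are built with the primer sequences substituted over the
template at both footprints.  This substitution is the entire mechanism of
dCAPS: the engineered restriction site exists only in the PCR product, never
in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqcore import (
    IUPAC_CODES,
    AlleleRecord,
    SequenceError,
    expand_degenerate,
    revcomp,
)

__all__ = [
    "Primer",
    "BindingModel",
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "amplify",
    "nested_amplify",
    "estimate_tm",
]

_CONCRETE = frozenset("ACGT")


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide, written 5'->3'.  Minimum length 10; IUPAC codes
    are permitted (degenerate primers)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if len(self.sequence) < 10:
            raise SequenceError(f"primer {self.name!r}: shorter than 10 nt")
        for ch in self.sequence:
            if ch not in IUPAC_CODES:
                raise SequenceError(
                    f"primer {self.name!r}: non-IUPAC character {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingModel:
    """Tunable primer-binding stringency.

    max_mismatches : mismatches tolerated outside the clamp (default 1)
    clamp_length   : 3'-terminal bases that must match exactly (default 3)
    min_product / max_product : product-length window in bp; spans outside
        it yield no amplicon (default 50 / 2000 — the ceiling is what makes
        a primer pair straddling a ~2 kb insertion fail to amplify).
    """

    max_mismatches: int = 1
    clamp_length: int = 3
    min_product: int = 50
    max_product: int = 2000

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.clamp_length < 0:
            raise ValueError("negative binding-model parameter")
        if not self.min_product < self.max_product:
            raise ValueError("min_product must be < max_product")


@dataclass(frozen=True)
class BindingSite:
    """One primer placement.  ``position`` is the 1-based plus-strand start
    of the primer footprint on the template; ``mismatch_positions`` are
    1-based template coordinates of non-clamp mismatches."""

    position: int
    strand: str  # "+" | "-"
    primer: str
    mismatch_positions: tuple[int, ...] = ()

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``sequence`` carries the forward primer verbatim at its 5' end and the
    reverse complement of the reverse primer at its 3' end (primer bases
    overwrite the template at both footprints).  ``start``/``end`` are
    1-based inclusive template coordinates of the whole product.
    """

    id: str
    template_id: str
    sequence: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str

    def __len__(self) -> int:
        return len(self.sequence)


def _base_matches(primer_code: str, template_base: str) -> bool:
    # IUPAC-aware on the primer side only; an ambiguous template base is
    # always a mismatch (conservative).
    return template_base in _CONCRETE and template_base in IUPAC_CODES[primer_code]


def _scan(template: str, oligo: str, model: BindingModel) -> list[tuple[int, tuple[int, ...]]]:
    """All placements of ``oligo`` (aligned 5'->3' with the template plus
    strand, 3' end rightmost) satisfying the binding model.  Returns
    (0-based start, 0-based template mismatch positions)."""
    k = len(oligo)
    clamp = min(model.clamp_length, k)
    hits: list[tuple[int, tuple[int, ...]]] = []
    for p in range(len(template) - k + 1):
        ok = True
        for j in range(k - clamp, k):  # exact-match clamp at the 3' end
            if not _base_matches(oligo[j], template[p + j]):
                ok = False
                break
        if not ok:
            continue
        mismatches = []
        for j in range(k - clamp):
            if not _base_matches(oligo[j], template[p + j]):
                mismatches.append(p + j)
                if len(mismatches) > model.max_mismatches:
                    ok = False
                    break
        if ok:
            hits.append((p, tuple(mismatches)))
    return hits


def find_binding_sites(
    template: AlleleRecord | str,
    primer: Primer,
    model: BindingModel,
    strand: str = "+",
) -> list[BindingSite]:
    """Every placement of ``primer`` on the given strand of ``template``.

    Plus-strand sites point the primer's 3' end rightward (forward primer);
    minus-strand sites are evaluated against the reverse complement and
    reported at their plus-strand footprint start (reverse primer).
    """
    seq = template.sequence if isinstance(template, AlleleRecord) else template
    k = len(primer)
    n = len(seq)
    if strand == "+":
        return [
            BindingSite(p + 1, "+", primer.name, tuple(m + 1 for m in mm))
            for p, mm in _scan(seq, primer.sequence, model)
        ]
    if strand == "-":
        hits = []
        for q, mm in _scan(revcomp(seq), primer.sequence, model):
            p = n - q - k  # plus-strand footprint start, 0-based
            plus_mm = tuple(sorted(n - m for m in mm))
            hits.append(BindingSite(p + 1, "-", primer.name, plus_mm))
        return sorted(hits, key=lambda h: h.position)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def amplify(
    template: AlleleRecord,
    fwd: Primer,
    rev: Primer,
    model: BindingModel | None = None,
) -> list[Amplicon]:
    """Predict all PCR products of a primer pair on one template.

    One amplicon per (forward plus-strand site, reverse minus-strand site)
    pair whose span lies within ``[min_product, max_product]`` and whose
    footprints do not overlap.  All products are reported; no "strongest
    band" selection is applied, so nonspecific larger products are
    representable.  Returns an empty list when no compatible pair exists.
    """
    model = model or BindingModel()
    fhits = find_binding_sites(template, fwd, model, "+")
    rhits = find_binding_sites(template, rev, model, "-")
    seq = template.sequence
    out: list[Amplicon] = []
    for fh in fhits:
        f0 = fh.position - 1
        for rh in rhits:
            r0 = rh.position - 1
            end0 = r0 + len(rev)  # exclusive
            span = end0 - f0
            if span < model.min_product or span > model.max_product:
                continue
            if f0 + len(fwd) > r0:
                continue  # overlapping primer footprints
            product = fwd.sequence + seq[f0 + len(fwd) : r0] + revcomp(rev.sequence)
            out.append(
                Amplicon(
                    id=f"{template.id}:{f0 + 1}-{end0}:{fwd.name}+{rev.name}",
                    template_id=template.id,
                    sequence=product,
                    start=f0 + 1,
                    end=end0,
                    fwd_primer=fwd.name,
                    rev_primer=rev.name,
                )
            )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def nested_amplify(
    template: AlleleRecord,
    outer: tuple[Primer, Primer],
    inner: tuple[Primer, Primer],
    model: BindingModel | None = None,
) -> list[Amplicon]:
    """Two-round nested PCR: the outer pair's products become templates for
    the inner pair.  If the first round yields nothing (e.g. the outer span
    straddles a large insertion), the nested result is empty.  Inner
    amplicon coordinates are reported on the original template."""
    model = model or BindingModel()
    inner_products: list[Amplicon] = []
    for outer_amp in amplify(template, outer[0], outer[1], model):
        stage = AlleleRecord(id=outer_amp.id, sequence=outer_amp.sequence)
        for amp in amplify(stage, inner[0], inner[1], model):
            inner_products.append(
                Amplicon(
                    id=f"{template.id}:{outer_amp.start + amp.start - 1}-"
                    f"{outer_amp.start + amp.end - 1}:{amp.fwd_primer}+{amp.rev_primer}",
                    template_id=template.id,
                    sequence=amp.sequence,
                    start=outer_amp.start + amp.start - 1,
                    end=outer_amp.start + amp.end - 1,
                    fwd_primer=amp.fwd_primer,
                    rev_primer=amp.rev_primer,
                )
            )
    inner_products.sort(key=lambda a: (a.start, a.end))
    return inner_products


def estimate_tm(primer: Primer) -> float:
    """Advisory melting-temperature estimate, °C to 0.1.

    Uses the GC-fraction formula Tm = 64.9 + 41*(nGC - 16.4)/N with
    degenerate codes contributing their expected G+C content (so the value
    equals the mean over the primer's degenerate expansion).  Advisory only:
    never used to gate amplification.
    """
    n = len(primer)
    gc = 0.0
    for code in primer.sequence:
        bases = IUPAC_CODES[code]
        gc += sum(1 for b in bases if b in "GC") / len(bases)
    return round(64.9 + 41.0 * (gc - 16.4) / n, 1)
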