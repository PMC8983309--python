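"""Seeded synthetic allele systems with known ground truth.

This module generates, from a single integer seed, a two-locus allele set
that structurally emulates a wheat semi-dwarfing marker system: a long
wild-type gene sequence per locus, nonsense-class SNP alleles whose local
contexts realize the classic CAPS discrimination hexamers/pentamers
(GCAGC -> GTAGC loss of a BstV1I site; GCGC -> GCGT loss of a BstHHI site;
a CTGTAG-gaining SNP for BstSFI whose wild-type context CCGTAG differs at
the pattern-invariant T), one SNP allele deliberately lacking any natural
discriminating site (forcing the dCAPS path, where the engineered product
site is the literal GATTC), and three insertion alleles of 197, 160 and
2026 bp whose STS assays yield 247 bp and 330 bp diagnostic products and a
first-round nested-PCR dropout, respectively.

All sequences are synthetic: generated, not downloaded.  Regenerating with
the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .enzymes import RestrictionEnzyme, default_enzyme_library, find_sites
from .genotyper import (
    ExpectedOutcome,
    GelResolution,
    MarkerDefinition,
    MarkerPanel,
    validate_panel,
)
from .ispcr import BindingModel, Primer
from .marker_design import design_dcaps, find_caps_enzymes, locate_variants
from .seqcore import AlleleRecord, SequenceError, VariantSpec, revcomp

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "FixtureError",
    "generate_wildtype",
    "apply_snp",
    "apply_insertion",
    "generate_reference_system",
]

_BASES = np.array(list("ACGT"))
#: GC fraction 0.45, uniform within the AT / GC pools
_BASE_P = np.array([0.275, 0.225, 0.225, 0.275])
_STOPS = {"TAA", "TAG", "TGA"}


class FixtureError(RuntimeError):
    """Fixture construction failed a structural guarantee."""


@dataclass
class FixtureConfig:
    """Recipe for one synthetic wild-type sequence.

    ``orf_start`` is 1-based (the A of ATG); ``planted_motifs`` are
    (1-based position, motif string) pairs installed verbatim; downstream
    SNP/insertion specs describe the mutant alleles derived from it.
    """

    seed: int
    base_length: int = 1500
    orf_start: int = 401
    snp_specs: list[tuple[int, str, str, str]] = field(default_factory=list)
    insertion_specs: list[tuple[int, int, str]] = field(default_factory=list)
    planted_motifs: list[tuple[int, str]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n, p=_BASE_P))


def generate_wildtype(config: FixtureConfig, *, name: str = "wildtype") -> AlleleRecord:
    """Seeded random wild-type sequence with an ATG at ``orf_start``, no
    in-frame stop codon for at least 600 bp downstream, and the requested
    motifs planted.  Overlapping planted motifs raise."""
    if config.orf_start < 1 or config.orf_start + 600 > config.base_length:
        raise FixtureError("orf_start leaves fewer than 600 bp of ORF")
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.base_length)
    orf0 = config.orf_start - 1
    seq[orf0 : orf0 + 3] = list("ATG")

    protected = set(range(orf0, orf0 + 3))
    for pos1, motif in sorted(config.planted_motifs):
        span = range(pos1 - 1, pos1 - 1 + len(motif))
        if span.stop > config.base_length:
            raise FixtureError(f"motif at {pos1} extends past the sequence")
        if protected.intersection(span):
            raise FixtureError(f"planted motif at {pos1} collides with another")
        for i, ch in zip(span, motif):
            seq[i] = ch
        protected.update(span)

    _fix_stops(seq, orf0, protected)
    return AlleleRecord(
        id=name, sequence="".join(seq), start_codon_pos=config.orf_start
    )


def _fix_stops(seq: list[str], orf0: int, protected: set[int], n_codons: int = 200) -> None:
    """Remove premature stops from the first ``n_codons`` codons by setting
    a mutable codon base to C (no stop codon contains C)."""
    for c in range(n_codons):
        a = orf0 + 3 * c
        if a + 3 > len(seq):
            break
        if "".join(seq[a : a + 3]) in _STOPS:
            for off in (2, 1, 0):
                if a + off not in protected:
                    seq[a + off] = "C"
                    break
            else:
                raise FixtureError(
                    f"stop codon at ORF codon {c + 1} is fully protected"
                )


def apply_snp(
    wildtype: AlleleRecord,
    position_from_start_codon: int,
    ref: str,
    alt: str,
    name: str,
) -> AlleleRecord:
    """Single-base substituted copy of the wild type; the existing base must
    equal ``ref`` (1-based coding coordinate, A of ATG = 1)."""
    i0 = wildtype.cds_to_seq(position_from_start_codon) - 1
    if not (0 <= i0 < len(wildtype.sequence)):
        raise FixtureError(f"coding position {position_from_start_codon} out of range")
    have = wildtype.sequence[i0]
    if have != ref:
        raise FixtureError(
            f"ref mismatch at coding position {position_from_start_codon}: "
            f"sequence has {have!r}, expected {ref!r}"
        )
    seq = wildtype.sequence[:i0] + alt + wildtype.sequence[i0 + 1 :]
    return AlleleRecord(
        id=name, sequence=seq,
        start_codon_pos=wildtype.start_codon_pos, locus=wildtype.locus,
    )


def apply_insertion(
    wildtype: AlleleRecord,
    position: int,
    length: int,
    seed: int,
    name: str,
    insert: Optional[str] = None,
) -> AlleleRecord:
    """Copy of the wild type with a seeded random insert of exactly
    ``length`` bp placed after 1-based ``position``; both flanks unchanged.
    Pass ``insert`` to reuse an existing insert sequence (alleles sharing an
    insertion)."""
    if length < 1:
        raise FixtureError("insertion length must be >= 1")
    if not (1 <= position <= len(wildtype.sequence)):
        raise FixtureError(f"insertion position {position} outside the sequence")
    if insert is None:
        rng = np.random.default_rng(seed)
        insert = "".join(_random_seq(rng, length))
    if len(insert) != length:
        raise FixtureError("explicit insert does not have the requested length")
    seq = wildtype.sequence[:position] + insert + wildtype.sequence[position:]
    start = wildtype.start_codon_pos
    if start is not None and position < start:
        start += length
    return AlleleRecord(id=name, sequence=seq, start_codon_pos=start, locus=wildtype.locus)


# ---------------------------------------------------------------------------
# reference system layout (0-based wild-type coordinates)

_B1_LEN = 2600
_B1_ORF0 = 700  # 0-based index of the A of ATG

# coding-coordinate helper: cds 1-based -> 0-based sequence index
def _cds(p: int) -> int:
    return _B1_ORF0 + p - 1


_D1_LEN = 1400
_D1_ORF0 = 500

_INS_H_POS = 300   # 197 bp 5'-flank insertion (B1h, shared by B1c)
_INS_I_POS = 520   # 160 bp promoter insertion (B1i)
_INS_C_POS = 1100  # 2026 bp retroelement inside the ORF (B1c)
_INS_H_LEN = 197
_INS_I_LEN = 160
_INS_C_LEN = 2026


def _scrub(
    seq: list[str],
    library: Sequence[RestrictionEnzyme],
    intended: set[tuple[str, int, str]],
    protected: set[int],
    rng: np.random.Generator,
    orf0: int,
) -> None:
    """Destroy every library recognition site that is not on the intended
    list, keeping protected positions, the ATG, and a stop-free ORF intact.
    Iterates because a repair can create a new site or stop."""
    from .seqcore import IUPAC_CODES

    for _ in range(400):
        changed = False
        _fix_stops(seq, orf0, protected)
        s = "".join(seq)
        for enz in library:
            for hit in find_sites(s, enz):
                if (enz.name, hit.position, hit.strand) in intended:
                    continue
                span = [
                    p
                    for p in range(hit.position - 1, hit.position - 1 + enz.site_length)
                    if p not in protected
                ]
                if not span:
                    raise FixtureError(
                        f"stray {enz.name} site at {hit.position} is fully protected"
                    )
                pat = enz.recognition if hit.strand == "+" else revcomp(enz.recognition)
                # mutate the most constrained mutable column: changing a base
                # under an N can never destroy the match
                p = min(span, key=lambda q: len(IUPAC_CODES[pat[q - hit.position + 1]]))
                col = p - (hit.position - 1)
                allowed = sorted(set("ACGT") - IUPAC_CODES[pat[col]] - {seq[p]})
                if not allowed:
                    raise FixtureError(
                        f"stray {enz.name} site at {hit.position} cannot be destroyed"
                    )
                seq[p] = allowed[int(rng.integers(len(allowed)))]
                changed = True
                s = "".join(seq)
        if not changed:
            # one clean pass with no repairs: re-verify stops and finish
            return
    raise FixtureError("site scrubbing did not converge")


@dataclass
class FixtureTruth:
    """A complete synthetic reference system with its ground truth."""

    seed: int
    alleles: list[AlleleRecord]
    variant_table: dict[str, list[VariantSpec]]
    panel: MarkerPanel
    inserts: dict[str, str]

    def allele(self, name: str) -> AlleleRecord:
        for a in self.alleles:
            if a.id == name:
                return a
        raise KeyError(name)


def _build_b1_wildtype(seed: int) -> AlleleRecord:
    # planted contexts (1-based positions):
    #  - AATAA + TCAG + GCAGC at cds 93..106: the BstV1I CAPS site whose
    #    C->T SNP at cds 103 yields mutant GTAGC, and the one-mismatch
    #    Acc36I dCAPS context TCAGG(C/T) upstream of it
    #  - GCGC + AG at cds 175..180: BstHHI site; C->T at cds 178 yields GCGT
    #    and an in-frame premature TAG
    #  - ACCATCCAA at cds 248..256: the forced-dCAPS locus; C->T at cds 253
    #    matches no library site naturally, while a primer-introduced G
    #    completes GATTC (HinfI) in the product
    # the AATAA pad pins the bases a primer-introduced G could otherwise
    # combine with into an accidental constitutive site
    motifs = [
        (_cds(93) + 1, "AATAATCAGGCAGC"),
        (_cds(175) + 1, "GCGCAG"),
        (_cds(248) + 1, "ACCATCCAA"),
    ]
    cfg = FixtureConfig(
        seed=seed,
        base_length=_B1_LEN,
        orf_start=_B1_ORF0 + 1,
        planted_motifs=motifs,
    )
    wt = generate_wildtype(cfg, name="B1a")
    wt.locus = "B1"
    return wt


def _build_d1_wildtype(seed: int) -> AlleleRecord:
    # CCGTAG at cds 191..196: differs from the BstSFI pattern CTRYAG at the
    # invariant T, so the wild type is never cut; C->T at cds 192 creates
    # the mutant CTGTAG site.  Planted at a frame where the embedded TAG is
    # split across codons, keeping the wild ORF stop-free.
    cfg = FixtureConfig(
        seed=seed,
        base_length=_D1_LEN,
        orf_start=_D1_ORF0 + 1,
        planted_motifs=[(_D1_ORF0 + 191, "CCGTAG")],
    )
    wt = generate_wildtype(cfg, name="D1a")
    wt.locus = "D1"
    return wt


def generate_reference_system(seed: int) -> FixtureTruth:
    """Build the packaged two-locus synthetic system.

    Returns nine alleles (7 at locus B1, 2 at D1), the per-allele variant
    truth, and a validated marker panel of 4 CAPS/dCAPS and 5 STS markers
    plus one standard-PCR CAPS marker at the second locus.  The forced-dCAPS
    allele is checked at generation time to have no natural CAPS enzyme in
    the default library.
    """
    library = default_enzyme_library()
    rng = np.random.default_rng((seed * 7919 + 13) % 2**31)

    # --- wild types, scrubbed of stray library sites -----------------------
    b1 = _build_b1_wildtype((seed * 7919 + 1) % 2**31)
    b1_seq = list(b1.sequence)
    b1_protected = set(range(_cds(93), _cds(93) + 14)) | set(
        range(_cds(175), _cds(175) + 6)
    ) | set(range(_cds(248), _cds(248) + 9)) | set(range(_B1_ORF0, _B1_ORF0 + 3))
    b1_intended = {
        ("BstV1I", _cds(102) + 1, "+"),  # planted GCAGC
        ("BstHHI", _cds(175) + 1, "+"),  # planted GCGC (palindromic)
    }
    _scrub(b1_seq, library, b1_intended, b1_protected, rng, _B1_ORF0)
    b1 = AlleleRecord(id="B1a", sequence="".join(b1_seq),
                      start_codon_pos=_B1_ORF0 + 1, locus="B1")

    d1 = _build_d1_wildtype((seed * 7919 + 2) % 2**31)
    d1_seq = list(d1.sequence)
    d1_protected = set(range(_D1_ORF0 + 190, _D1_ORF0 + 196)) | set(
        range(_D1_ORF0, _D1_ORF0 + 3)
    )
    _scrub(d1_seq, library, set(), d1_protected, rng, _D1_ORF0)
    d1 = AlleleRecord(id="D1a", sequence="".join(d1_seq),
                      start_codon_pos=_D1_ORF0 + 1, locus="D1")

    # --- mutant alleles ----------------------------------------------------
    b1b = apply_snp(b1, 103, "C", "T", "B1b")   # GCAGC -> GTAGC (in-frame TAG)
    b1p = apply_snp(b1, 178, "C", "T", "B1p")   # GCGC  -> GCGT  (in-frame TAG)
    b1e = apply_snp(b1, 253, "C", "T", "B1e")   # forced-dCAPS locus
    d1b = apply_snp(d1, 192, "C", "T", "D1b")   # CCGTAG -> CTGTAG

    ins_h_seed = (seed * 7919 + 3) % 2**31
    ins_i_seed = (seed * 7919 + 4) % 2**31
    ins_c_seed = (seed * 7919 + 5) % 2**31
    b1h = apply_insertion(b1, _INS_H_POS, _INS_H_LEN, ins_h_seed, "B1h")
    ins_h = b1h.sequence[_INS_H_POS : _INS_H_POS + _INS_H_LEN]
    b1i = apply_insertion(b1, _INS_I_POS, _INS_I_LEN, ins_i_seed, "B1i")
    ins_i = b1i.sequence[_INS_I_POS : _INS_I_POS + _INS_I_LEN]
    # B1c shares the 5'-flank insertion with B1h and additionally carries
    # the large retroelement inside the ORF.
    b1c = apply_insertion(b1, _INS_H_POS, _INS_H_LEN, ins_h_seed, "B1c", insert=ins_h)
    b1c = apply_insertion(
        b1c, _INS_C_POS + _INS_H_LEN, _INS_C_LEN, ins_c_seed, "B1c"
    )
    ins_c = b1c.sequence[
        _INS_C_POS + _INS_H_LEN : _INS_C_POS + _INS_H_LEN + _INS_C_LEN
    ]

    alleles = [b1, b1b, b1e, b1p, b1h, b1i, b1c, d1, d1b]

    # --- variant truth -----------------------------------------------------
    snp_set = [b1, b1b, b1e, b1p]

    def _snp(target: AlleleRecord, cds_pos: int) -> VariantSpec:
        return VariantSpec(
            target_allele=target.id,
            position=target.cds_to_seq(cds_pos),
            kind="snp",
            ref_base="C",
            alt_base="T",
            cds_position=cds_pos,
        )

    variant_table: dict[str, list[VariantSpec]] = {
        "B1a": [], "D1a": [],
        "B1b": [_snp(b1b, 103)],
        "B1p": [_snp(b1p, 178)],
        "B1e": [_snp(b1e, 253)],
        "D1b": [VariantSpec(target_allele="D1b", position=d1b.cds_to_seq(192),
                            kind="snp", ref_base="C", alt_base="T", cds_position=192)],
        "B1h": [VariantSpec(target_allele="B1h", position=_INS_H_POS + 1,
                            kind="insertion", insert_length=_INS_H_LEN)],
        "B1i": [VariantSpec(target_allele="B1i", position=_INS_I_POS + 1,
                            kind="insertion", insert_length=_INS_I_LEN)],
        "B1c": [VariantSpec(target_allele="B1c", position=_INS_H_POS + 1,
                            kind="insertion", insert_length=_INS_H_LEN),
                VariantSpec(target_allele="B1c", position=_INS_C_POS + _INS_H_LEN + 1,
                            kind="insertion", insert_length=_INS_C_LEN)],
    }

    # the forced-dCAPS guarantee, checked at generation time
    if find_caps_enzymes(snp_set, variant_table["B1e"][0], library):
        raise FixtureError("forced-dCAPS locus unexpectedly has a natural CAPS enzyme")

    # --- dCAPS markers designed by the pipeline itself ---------------------
    dcaps_e = [
        c for c in design_dcaps(snp_set, variant_table["B1e"][0], library)
        if c.enzyme == "HinfI"
    ]
    if not dcaps_e:
        raise FixtureError("no HinfI dCAPS candidate for the forced locus")
    dcaps_b = [
        c for c in design_dcaps(snp_set, variant_table["B1b"][0], library)
        if c.enzyme == "Acc36I"
    ]
    if not dcaps_b:
        raise FixtureError("no Acc36I dCAPS candidate for the B1b-class SNP")

    # --- primers and markers ----------------------------------------------
    wt = b1.sequence

    def fragment(lo: int, hi: int) -> str:
        return wt[lo:hi]

    outer = (
        Primer("BF", fragment(640, 660)),
        Primer("B1R", revcomp(fragment(1480, 1500))),
    )
    model = BindingModel(max_mismatches=1, clamp_length=1,
                         min_product=50, max_product=2000)

    def nested_caps(name: str, fwd_lo: int, rev_lo: int, enzyme: str) -> MarkerDefinition:
        return MarkerDefinition(
            name=name, marker_type="CAPS",
            fwd=Primer(f"{name}-F", fragment(fwd_lo, fwd_lo + 20)),
            rev=Primer(f"{name}-R", revcomp(fragment(rev_lo, rev_lo + 20))),
            enzyme=enzyme, outer_pair=outer,
        )

    def dcaps_marker(name: str, cand, enzyme: str) -> MarkerDefinition:
        if cand.orientation == "forward":
            fwd, rev = cand.modified_primer, cand.companion_primer
        else:
            fwd, rev = cand.companion_primer, cand.modified_primer
        return MarkerDefinition(
            name=name, marker_type="dCAPS",
            fwd=Primer(f"{name}-F", fwd.sequence),
            rev=Primer(f"{name}-R", rev.sequence),
            enzyme=enzyme, outer_pair=outer,
        )

    def sts(name: str, fwd_seq: str, rev_seq: str) -> MarkerDefinition:
        return MarkerDefinition(
            name=name, marker_type="STS",
            fwd=Primer(f"{name}-F", fwd_seq),
            rev=Primer(f"{name}-R", rev_seq),
        )

    cand_b = dcaps_b[0]
    cand_e = dcaps_e[0]
    markers = [
        nested_caps("CB1b/BstV1I", 745, 860, "BstV1I"),
        dcaps_marker("dCB1b/Acc36I", cand_b, "Acc36I"),
        dcaps_marker("dCB1e/HinfI", cand_e, "HinfI"),
        nested_caps("CB1p/BstHHI", 820, 920, "BstHHI"),
        sts("B1c-F1/R1", ins_c[200:220], revcomp(ins_c[480:500])),
        sts("B1h-F/R1", fragment(250, 270), revcomp(ins_h[177:197])),
        sts("B1h-F/R2", fragment(230, 250), revcomp(fragment(350, 370))),
        sts("B1i-MF1/MR1", fragment(350, 370), revcomp(ins_i[140:160])),
        sts("B1i-MF2/MR2", fragment(400, 420), revcomp(fragment(560, 580))),
        MarkerDefinition(
            name="CD1b/BstSFI", marker_type="CAPS",
            fwd=Primer("CD1b-F", d1.sequence[630:650]),
            rev=Primer("CD1b-R", revcomp(d1.sequence[740:760])),
            enzyme="BstSFI",
        ),
    ]

    # --- expected profile table -------------------------------------------
    def caps_cell(cut: bool) -> ExpectedOutcome:
        return ExpectedOutcome(product=True, cut=cut)

    def sts_cell(length: Optional[int]) -> ExpectedOutcome:
        if length is None:
            return ExpectedOutcome(product=False)
        return ExpectedOutcome(product=True, product_length=length)

    no_amp = ExpectedOutcome(product=False)
    cut_b = cand_b.cut_in == "target"
    cut_e = cand_e.cut_in == "target"

    def b1_row(
        *, b_cut: bool, db_cut: bool, e_cut: bool, p_cut: bool,
        nested_ok: bool = True,
        c_sts: Optional[int] = None, h1: Optional[int] = None,
        h2: Optional[int] = None, i1: Optional[int] = None,
        i2: Optional[int] = None,
    ) -> dict[str, ExpectedOutcome]:
        row = {
            "CB1b/BstV1I": caps_cell(b_cut) if nested_ok else no_amp,
            "dCB1b/Acc36I": caps_cell(db_cut) if nested_ok else no_amp,
            "dCB1e/HinfI": caps_cell(e_cut) if nested_ok else no_amp,
            "CB1p/BstHHI": caps_cell(p_cut) if nested_ok else no_amp,
            "B1c-F1/R1": sts_cell(c_sts),
            "B1h-F/R1": sts_cell(h1),
            "B1h-F/R2": sts_cell(h2),
            "B1i-MF1/MR1": sts_cell(i1),
            "B1i-MF2/MR2": sts_cell(i2),
            "CD1b/BstSFI": no_amp,
        }
        return row

    h2_wt, h2_ins = 140, 140 + _INS_H_LEN
    i2_wt, i2_ins = 180, 180 + _INS_I_LEN
    profiles: dict[str, dict[str, ExpectedOutcome]] = {
        "B1a": b1_row(b_cut=True, db_cut=not cut_b, e_cut=not cut_e, p_cut=True,
                      h2=h2_wt, i2=i2_wt),
        "B1b": b1_row(b_cut=False, db_cut=cut_b, e_cut=not cut_e, p_cut=True,
                      h2=h2_wt, i2=i2_wt),
        "B1e": b1_row(b_cut=True, db_cut=not cut_b, e_cut=cut_e, p_cut=True,
                      h2=h2_wt, i2=i2_wt),
        "B1p": b1_row(b_cut=True, db_cut=not cut_b, e_cut=not cut_e, p_cut=False,
                      h2=h2_wt, i2=i2_wt),
        "B1h": b1_row(b_cut=True, db_cut=not cut_b, e_cut=not cut_e, p_cut=True,
                      h1=247, h2=h2_ins, i2=i2_wt),
        "B1i": b1_row(b_cut=True, db_cut=not cut_b, e_cut=not cut_e, p_cut=True,
                      h2=h2_wt, i1=330, i2=i2_ins),
        "B1c": b1_row(b_cut=False, db_cut=False, e_cut=False, p_cut=False,
                      nested_ok=False, c_sts=300, h1=247, h2=h2_ins, i2=i2_wt),
        "D1a": {m.name: no_amp for m in markers[:-1]}
        | {"CD1b/BstSFI": caps_cell(False)},
        "D1b": {m.name: no_amp for m in markers[:-1]}
        | {"CD1b/BstSFI": caps_cell(True)},
    }

    panel = MarkerPanel(
        markers=markers,
        profile_table=profiles,
        model=model,
        gel_resolution=GelResolution(),
        enzyme_library=library,
    )
    report = validate_panel(panel)
    if not report.ok:
        raise FixtureError(f"generated panel invalid: {report.defects}")

    return FixtureTruth(
        seed=seed,
        alleles=alleles,
        variant_table=variant_table,
        panel=panel,
        inserts={"197bp": ins_h, "160bp": ins_i, "2026bp": ins_c},
    )
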