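"""CAPS enzyme search and dCAPS primer engineering.

Given an allele set and a target SNP, this module answers two questions:

* **CAPS** — is there an enzyme whose recognition site, at the SNP locus,
  is present in the target allele and absent in every other allele (gain of
  site), or vice versa (loss of site)?  Such an enzyme turns the SNP into a
  plain digest-the-product assay.

* **dCAPS** — when no natural site discriminates, can a primer ending just
  short of the SNP carry one or two deliberate mismatches so that, in the
  PCR product (where primer bases overwrite the template), a recognition
  site is completed by the SNP base of exactly one allele group?  The
  engineered site then exists only in the target (or only in the non-target)
  products.

Every emitted dCAPS candidate is validated end-to-end inside the design
routine: each supplied allele is amplified with the candidate primer pair
and digested with the candidate enzyme, and the cut/uncut partition must be
exactly {target} vs {all others}.  Candidates that fail this simulation are
never returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .enzymes import RestrictionEnzyme, EnzymeError, digest, find_sites
from .ispcr import Amplicon, BindingModel, Primer, amplify
from .seqcore import (
    IUPAC_CODES,
    AlleleRecord,
    SequenceError,
    VariantSpec,
    iupac_match,
    is_concrete,
    revcomp,
)

__all__ = [
    "CAPSCandidate",
    "DCAPSCandidate",
    "DesignError",
    "locate_variants",
    "find_caps_enzymes",
    "design_dcaps",
    "site_overlapping",
]

_CONCRETE = frozenset("ACGT")


class DesignError(ValueError):
    """Un-anchorable alleles or an invalid design request."""


@dataclass
class CAPSCandidate:
    """An enzyme that discriminates the target allele at the SNP locus.

    mode is ``gain_of_site`` (site present in the target only) or
    ``loss_of_site`` (site present in every non-target allele only).
    ``extra_sites_in_amplicon`` counts constitutive sites of the same enzyme
    near the SNP that would cut every allele (fewer is better — they blur
    the gel read-out).
    """

    enzyme: str
    snp: VariantSpec
    mode: str  # "gain_of_site" | "loss_of_site"
    window_sequences: dict[str, str]
    extra_sites_in_amplicon: int


@dataclass
class DCAPSCandidate:
    """A primer engineered to complete a recognition site over the SNP.

    ``introduced_mismatch_positions`` are 1-based positions within the
    modified primer (5'->3').  ``cut_in`` says which allele group's product
    the enzyme digests.  The candidate has passed amplify->digest simulation
    on every supplied allele.
    """

    enzyme: str
    modified_primer: Primer
    introduced_mismatch_positions: tuple[int, ...]
    orientation: str  # "forward" | "reverse"
    cut_in: str  # "target" | "others"
    companion_primer: Primer
    snp: VariantSpec
    product_length: int


# ---------------------------------------------------------------------------
# variant discovery


def _split_indel(target: str, ref: str) -> tuple[int, int]:
    """Longest common prefix/suffix split for a clean single indel."""
    n = min(len(target), len(ref))
    p = 0
    while p < n and target[p] == ref[p]:
        p += 1
    s = 0
    while s < n - p and target[-1 - s] == ref[-1 - s]:
        s += 1
    return p, s


def locate_variants(
    alleles: Sequence[AlleleRecord], target: str
) -> list[VariantSpec]:
    """Differences between the target allele and all reference alleles.

    Alleles must be alignable by exact flank anchoring: equal-length
    sequences are compared column-wise (each column where the target differs
    from every reference, with all references agreeing, becomes a SNP);
    length differences must reduce to one clean insertion under longest
    common prefix/suffix splitting, otherwise the user is instructed to
    pre-align.  A sequence compared against itself yields no variants.
    """
    by_id = {a.id: a for a in alleles}
    if target not in by_id:
        raise DesignError(f"target allele {target!r} not in input set")
    tgt = by_id[target]
    refs = [a for a in alleles if a.id != target]
    if not refs:
        raise DesignError("need at least one reference allele")

    variants: list[VariantSpec] = []

    # Insertions: pairwise vs. each shorter reference.
    ins_seen: set[tuple[int, int]] = set()
    snp_refs: list[AlleleRecord] = []
    for ref in refs:
        if len(ref.sequence) == len(tgt.sequence):
            snp_refs.append(ref)
            continue
        p, s = _split_indel(tgt.sequence, ref.sequence)
        d = len(tgt.sequence) - len(ref.sequence)
        if d > 0 and p + s >= len(ref.sequence):
            key = (p, d)
            if key not in ins_seen:
                ins_seen.add(key)
                variants.append(
                    VariantSpec(
                        target_allele=target,
                        position=p + 1,
                        kind="insertion",
                        insert_length=d,
                    )
                )
        elif d < 0 and p + s >= len(tgt.sequence):
            # target is the shorter sequence: the reference carries the
            # insertion; no variant of the supported kinds on the target.
            continue
        else:
            raise DesignError(
                f"alleles {target!r} and {ref.id!r} differ by more than a "
                f"clean single insertion; pre-align them externally"
            )

    # SNPs: column-wise against equal-length references.
    if snp_refs:
        for i, tb in enumerate(tgt.sequence):
            ref_bases = {r.sequence[i] for r in snp_refs}
            if len(ref_bases) != 1:
                continue
            rb = next(iter(ref_bases))
            if tb != rb and tb in _CONCRETE and rb in _CONCRETE:
                cds = None
                if tgt.start_codon_pos is not None:
                    cds = i + 1 - tgt.start_codon_pos + 1
                variants.append(
                    VariantSpec(
                        target_allele=target,
                        position=i + 1,
                        kind="snp",
                        ref_base=rb,
                        alt_base=tb,
                        cds_position=cds,
                    )
                )
    variants.sort(key=lambda v: v.position)
    return variants


# ---------------------------------------------------------------------------
# CAPS search


def _locus_index(ref: AlleleRecord, tgt: AlleleRecord, i0: int) -> Optional[int]:
    """Map 0-based target index ``i0`` onto a reference by exact left-flank
    anchoring; falls back to the same index for equal-length sequences.
    Returns None when the locus cannot be anchored uniquely."""
    f = min(20, i0)
    flank = tgt.sequence[i0 - f : i0]
    if f >= 12:
        first = ref.sequence.find(flank)
        if first != -1 and ref.sequence.find(flank, first + 1) == -1:
            return first + f
    if len(ref.sequence) == len(tgt.sequence):
        return i0
    return None


def site_overlapping(seq: str, idx0: int, enzyme: RestrictionEnzyme) -> bool:
    """True iff some recognition-site placement (either strand) covers the
    0-based position ``idx0``."""
    L = enzyme.site_length
    pats = {enzyme.recognition, revcomp(enzyme.recognition)}
    for s in range(max(0, idx0 - L + 1), min(idx0, len(seq) - L) + 1):
        win = seq[s : s + L]
        if not is_concrete(win):
            continue
        if any(iupac_match(p, win) for p in pats):
            return True
    return False


def find_caps_enzymes(
    alleles: Sequence[AlleleRecord],
    snp: VariantSpec,
    library: Sequence[RestrictionEnzyme],
    window: int = 20,
) -> list[CAPSCandidate]:
    """Enzymes whose site presence at the SNP locus separates the target
    allele from ALL references.

    For every enzyme, every recognition placement overlapping the SNP column
    is tested in the target and in each reference context.  Candidates are
    sorted by (extra constitutive sites within +/-window, recognition length,
    name) so identical inputs yield identical output order.
    """
    if not library:
        raise EnzymeError("empty enzyme library")
    if snp.kind != "snp":
        raise DesignError("find_caps_enzymes requires a snp variant")
    by_id = {a.id: a for a in alleles}
    tgt = by_id[snp.target_allele]
    i0 = snp.position - 1
    refs = [a for a in alleles if a.id != snp.target_allele]

    out: list[CAPSCandidate] = []
    for enz in library:
        t_has = site_overlapping(tgt.sequence, i0, enz)
        ref_flags = []
        ok = True
        for ref in refs:
            j0 = _locus_index(ref, tgt, i0)
            if j0 is None or j0 >= len(ref.sequence):
                ok = False
                break
            ref_flags.append(site_overlapping(ref.sequence, j0, enz))
        if not ok:
            continue
        if t_has and not any(ref_flags):
            mode = "gain_of_site"
        elif not t_has and all(ref_flags):
            mode = "loss_of_site"
        else:
            continue
        lo = max(0, i0 - window)
        hi = min(len(tgt.sequence), i0 + window + 1)
        ctx = tgt.sequence[lo:hi]
        extra = sum(
            1
            for h in find_sites(ctx, enz)
            if not (h.position - 1 <= i0 - lo <= h.position - 2 + enz.site_length)
        )
        windows = {tgt.id: ctx}
        for ref in refs:
            j0 = _locus_index(ref, tgt, i0)
            rlo = max(0, j0 - window)
            windows[ref.id] = ref.sequence[rlo : j0 + window + 1]
        out.append(
            CAPSCandidate(
                enzyme=enz.name,
                snp=snp,
                mode=mode,
                window_sequences=windows,
                extra_sites_in_amplicon=extra,
            )
        )
    out.sort(key=lambda c: (c.extra_sites_in_amplicon, len(_rec(library, c.enzyme)), c.enzyme))
    return out


def _rec(library: Sequence[RestrictionEnzyme], name: str) -> str:
    for e in library:
        if e.name == name:
            return e.recognition
    return ""


# ---------------------------------------------------------------------------
# dCAPS design


def _choose_companion(
    tgt: AlleleRecord,
    refs: Sequence[AlleleRecord],
    i0: int,
    side: str,
    distance: int = 150,
    length: int = 20,
) -> Optional[Primer]:
    """A naive companion primer: an exact 20-mer taken from the target
    outside the variable region, on the opposite side of the SNP, shared
    verbatim by every reference (the alleles' flanks are conserved)."""
    seq = tgt.sequence

    def usable(s: int) -> bool:
        if s < 0 or s + length > len(seq):
            return False
        win = seq[s : s + length]
        # the companion must sit outside the variable region and be shared
        # verbatim by every reference
        return is_concrete(win) and all(win in r.sequence for r in refs)

    if side == "right":
        base = i0 + distance
        order = [base - k for k in range(121)] + [base + k for k in range(1, 121)]
        for s in order:
            if s < i0 + 30:
                continue
            if usable(s):
                return Primer(
                    name=f"{tgt.id}-companionR",
                    sequence=revcomp(seq[s : s + length]),
                )
    else:
        base = i0 - distance - length
        order = [base + k for k in range(121)] + [base - k for k in range(1, 121)]
        for s in order:
            if s + length > i0 - 30:
                continue
            if usable(s):
                return Primer(
                    name=f"{tgt.id}-companionF", sequence=seq[s : s + length]
                )
    return None


def design_dcaps(
    alleles: Sequence[AlleleRecord],
    snp: VariantSpec,
    library: Sequence[RestrictionEnzyme],
    primer_lengths: range = range(18, 31),
    max_introduced: int = 1,
    model: BindingModel | None = None,
) -> list[DCAPSCandidate]:
    """Engineer dCAPS primers for a target SNP.

    For each enzyme, strand orientation of its recognition pattern, and
    placement covering the SNP column, the primer bases forced by the
    pattern are computed over the primer footprint; a placement is viable
    when the SNP column itself lies outside the footprint (the diagnostic
    base must come from the template), the target base matches the pattern
    there while every reference base does not, at most ``max_introduced``
    template mismatches are introduced, and neither the 3'-terminal base nor
    the SNP column is modified.  Each surviving construct is then simulated
    (amplify every allele with the modified primer plus an automatically
    chosen companion, digest with the enzyme) and kept only if the cut/uncut
    partition is exactly {target} vs {all others}.

    With ``max_introduced=0`` the output degenerates to the natural-site
    placements coverable by a primer (the CAPS limiting case).

    The validation binding model defaults to
    ``BindingModel(max_mismatches=max_introduced, clamp_length=1)`` — the
    engineered mismatches must be tolerated for the assay to work at all,
    while the exact 3'-terminal clamp is preserved.
    """
    if snp.kind != "snp":
        raise DesignError("design_dcaps requires a snp variant")
    if primer_lengths.start > primer_lengths.stop - 1 or len(primer_lengths) == 0:
        raise DesignError("invalid primer length range")
    by_id = {a.id: a for a in alleles}
    tgt = by_id[snp.target_allele]
    refs = [a for a in alleles if a.id != snp.target_allele]
    i0 = snp.position - 1
    seq = tgt.sequence
    sim_model = model or BindingModel(
        max_mismatches=max(1, max_introduced), clamp_length=1
    )

    candidates: list[DCAPSCandidate] = []
    seen: set[tuple[str, str, str]] = set()

    for enz in library:
        for pat in dict.fromkeys([enz.recognition, revcomp(enz.recognition)]):
            L = len(pat)
            for s in range(max(0, i0 - L + 1), min(i0, len(seq) - L) + 1):
                j = i0 - s  # SNP column within the pattern
                code = pat[j]
                # the SNP base must realize the pattern in the target only
                if seq[i0] not in IUPAC_CODES[code]:
                    continue
                ref_ok = True
                for ref in refs:
                    k0 = _locus_index(ref, tgt, i0)
                    if k0 is None or k0 >= len(ref.sequence):
                        ref_ok = False
                        break
                    if ref.sequence[k0] in IUPAC_CODES[code]:
                        ref_ok = False
                        break
                if not ref_ok:
                    continue
                for orientation in ("forward", "reverse"):
                    cand = _build_dcaps(
                        tgt, refs, snp, enz, pat, s, i0, orientation,
                        primer_lengths, max_introduced, sim_model,
                    )
                    if cand is None:
                        continue
                    key = (cand.enzyme, cand.modified_primer.sequence,
                           cand.companion_primer.sequence)
                    if key in seen:
                        continue
                    seen.add(key)
                    candidates.append(cand)
    candidates.sort(
        key=lambda c: (
            c.enzyme,
            c.orientation,
            len(c.introduced_mismatch_positions),
            c.modified_primer.sequence,
        )
    )
    return candidates


def _build_dcaps(
    tgt: AlleleRecord,
    refs: Sequence[AlleleRecord],
    snp: VariantSpec,
    enz: RestrictionEnzyme,
    pat: str,
    s: int,
    i0: int,
    orientation: str,
    primer_lengths: range,
    max_introduced: int,
    model: BindingModel,
) -> Optional[DCAPSCandidate]:
    """Try every viable primer end for one (enzyme, pattern, placement);
    return the first construct that survives end-to-end simulation."""
    seq = tgt.sequence
    L = len(pat)

    if orientation == "forward":
        # primer on the plus strand, 3' end at e, footprint [e-len+1, e]
        ends = range(max(s - 1, 0), i0)  # e < i0: SNP stays template-side
        for e in sorted(ends, reverse=True):
            forced, introduced = _force_bases(seq, pat, s, cover_lo=s, cover_hi=e)
            if forced is None or len(introduced) > max_introduced:
                continue
            if e in introduced:  # 3'-terminal base must be unmodified
                continue
            # template-side site columns must match the pattern in the target
            if not _template_side_ok(seq, pat, s, lo=e + 1, hi=s + L - 1):
                continue
            for plen in primer_lengths:
                f0 = e - plen + 1
                if f0 < 0:
                    continue
                bases = list(seq[f0 : e + 1])
                for pos, b in forced.items():
                    if f0 <= pos <= e:
                        bases[pos - f0] = b
                primer_seq = "".join(bases)
                if not is_concrete(primer_seq):
                    continue
                primer = Primer(
                    name=f"d{tgt.id}-{enz.name}-F", sequence=primer_seq
                )
                companion = _choose_companion(tgt, refs, i0, "right")
                if companion is None:
                    return None
                cand = _simulate(
                    tgt, refs, snp, enz, primer, companion, "forward",
                    tuple(sorted(p - f0 + 1 for p in introduced)), model,
                )
                if cand is not None:
                    return cand
            return None
        return None

    # reverse orientation: primer on the minus strand, 3' end at plus
    # position b (leftmost footprint base), footprint [b, b+len-1]
    starts = range(i0 + 1, min(s + L, len(seq)) + 1)
    for b in starts:
        forced, introduced = _force_bases(seq, pat, s, cover_lo=b, cover_hi=s + L - 1)
        if forced is None or len(introduced) > max_introduced:
            continue
        if b in introduced:
            continue
        if not _template_side_ok(seq, pat, s, lo=s, hi=b - 1):
            continue
        for plen in primer_lengths:
            hi0 = b + plen - 1
            if hi0 >= len(seq):
                continue
            bases = list(seq[b : hi0 + 1])
            for pos, v in forced.items():
                if b <= pos <= hi0:
                    bases[pos - b] = v
            primer_seq = revcomp("".join(bases))
            if not is_concrete(primer_seq):
                continue
            primer = Primer(name=f"d{tgt.id}-{enz.name}-R", sequence=primer_seq)
            companion = _choose_companion(tgt, refs, i0, "left")
            if companion is None:
                return None
            cand = _simulate(
                tgt, refs, snp, enz, primer, companion, "reverse",
                tuple(sorted(hi0 - p + 1 for p in introduced)), model,
            )
            if cand is not None:
                return cand
        return None
    return None


def _force_bases(
    seq: str, pat: str, s: int, cover_lo: int, cover_hi: int
) -> tuple[Optional[dict[int, str]], set[int]]:
    """Concrete bases a primer covering site columns [cover_lo, cover_hi]
    must carry to satisfy the pattern; returns (forced map, introduced
    mismatch positions), or (None, _) when the window is unusable."""
    forced: dict[int, str] = {}
    introduced: set[int] = set()
    for c in range(max(cover_lo, s), min(cover_hi, s + len(pat) - 1) + 1):
        code = pat[c - s]
        t = seq[c]
        if t not in _CONCRETE:
            return None, set()
        if t in IUPAC_CODES[code]:
            forced[c] = t
        else:
            forced[c] = sorted(IUPAC_CODES[code])[0]
            introduced.add(c)
    return forced, introduced


def _template_side_ok(seq: str, pat: str, s: int, lo: int, hi: int) -> bool:
    """Site columns left to the template (not under the primer) must match
    the pattern in the target allele without help."""
    for c in range(max(lo, s), min(hi, s + len(pat) - 1) + 1):
        t = seq[c]
        if t not in _CONCRETE or t not in IUPAC_CODES[pat[c - s]]:
            return False
    return True


def _simulate(
    tgt: AlleleRecord,
    refs: Sequence[AlleleRecord],
    snp: VariantSpec,
    enz: RestrictionEnzyme,
    primer: Primer,
    companion: Primer,
    orientation: str,
    introduced: tuple[int, ...],
    model: BindingModel,
) -> Optional[DCAPSCandidate]:
    """End-to-end self-oracle: amplify every allele, digest, and require the
    cut/uncut partition to equal {target} vs {all others}."""
    if orientation == "forward":
        fwd, rev = primer, companion
    else:
        fwd, rev = companion, primer
    cut: dict[str, bool] = {}
    product_len = 0
    for allele in [tgt, *refs]:
        amps = amplify(allele, fwd, rev, model)
        if len(amps) != 1:
            return None
        profile = digest(amps[0], enz)
        cut[allele.id] = profile.is_cut
        if allele.id == tgt.id:
            product_len = len(amps[0])
    others = [a.id for a in refs]
    if cut[tgt.id] and not any(cut[o] for o in others):
        cut_in = "target"
    elif not cut[tgt.id] and all(cut[o] for o in others):
        cut_in = "others"
    else:
        return None
    return DCAPSCandidate(
        enzyme=enz.name,
        modified_primer=primer,
        introduced_mismatch_positions=introduced,
        orientation=orientation,
        cut_in=cut_in,
        companion_primer=companion,
        snp=snp,
        product_length=product_len,
    )
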