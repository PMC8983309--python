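"""Variant discovery, CAPS enzyme search, and dCAPS primer engineering."""

import random

import pytest

from capskit.enzymes import default_enzyme_library, digest
from capskit.ispcr import BindingModel, amplify
from capskit.marker_design import (
    DesignError,
    design_dcaps,
    find_caps_enzymes,
    locate_variants,
    site_overlapping,
)
from capskit.seqcore import AlleleRecord, VariantSpec, expand_degenerate, revcomp

from conftest import random_dna, random_enzyme


class TestLocateVariants:
    def test_single_snp(self):
        ref = AlleleRecord(id="wt", sequence="ACGTACGTACGT")
        tgt = AlleleRecord(id="mut", sequence="ACGTATGTACGT")
        (v,) = locate_variants([ref, tgt], "mut")
        assert (v.kind, v.position, v.ref_base, v.alt_base) == ("snp", 6, "C", "T")

    def test_self_comparison_is_empty(self):
        a = AlleleRecord(id="a", sequence="ACGTACGT" * 5)
        b = AlleleRecord(id="b", sequence="ACGTACGT" * 5)
        assert locate_variants([a, b], "a") == []

    def test_insertion_detected_with_length(self):
        rng = random.Random(3)
        base = random_dna(rng, 300)
        ins = random_dna(rng, 160)
        ref = AlleleRecord(id="wt", sequence=base)
        tgt = AlleleRecord(id="mut", sequence=base[:100] + ins + base[100:])
        (v,) = locate_variants([ref, tgt], "mut")
        assert v.kind == "insertion"
        assert v.insert_length == 160

    def test_cds_coordinate_reported(self, truth):
        # the reference system's third-SNP allele carries C->T at coding
        # position 178
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        variants = locate_variants(snp_set, "B1p")
        assert len(variants) == 1
        assert variants[0].cds_position == 178
        assert (variants[0].ref_base, variants[0].alt_base) == ("C", "T")

    def test_fixture_truth_roundtrip(self, truth):
        # planted variants == recovered variants, exactly
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        for name in ("B1b", "B1e", "B1p"):
            got = locate_variants(snp_set, name)
            want = truth.variant_table[name]
            assert [(v.kind, v.position, v.ref_base, v.alt_base) for v in got] == [
                (v.kind, v.position, v.ref_base, v.alt_base) for v in want
            ]

    def test_unanchorable_raises(self):
        a = AlleleRecord(id="a", sequence=random_dna(random.Random(1), 100))
        b = AlleleRecord(id="b", sequence=random_dna(random.Random(2), 130))
        with pytest.raises(DesignError, match="pre-align"):
            locate_variants([a, b], "b")


def brute_force_caps(alleles, snp, library, window=20):
    """Independent oracle: full degenerate expansion, every window of every
    allele, site-overlap decided by raw string membership."""
    tgt = next(a for a in alleles if a.id == snp.target_allele)
    refs = [a for a in alleles if a.id != snp.target_allele]
    i0 = snp.position - 1

    def has_site(seq, idx, enz):
        pats = expand_degenerate(enz.recognition) | {
            revcomp(x) for x in expand_degenerate(enz.recognition)
        }
        L = enz.site_length
        for s in range(max(0, idx - L + 1), min(idx, len(seq) - L) + 1):
            if seq[s : s + L] in pats:
                return True
        return False

    out = {}
    for enz in library:
        t = has_site(tgt.sequence, i0, enz)
        r = [has_site(ref.sequence, i0, enz) for ref in refs]
        if t and not any(r):
            out[enz.name] = "gain_of_site"
        elif not t and all(r):
            out[enz.name] = "loss_of_site"
    return out


class TestFindCaps:
    def test_reference_system_modes(self, truth, library):
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        by_target = {
            "B1b": ("BstV1I", "loss_of_site"),
            "B1p": ("BstHHI", "loss_of_site"),
        }
        for target, (enzyme, mode) in by_target.items():
            cands = find_caps_enzymes(
                snp_set, truth.variant_table[target][0], library
            )
            got = {(c.enzyme, c.mode) for c in cands}
            assert (enzyme, mode) in got

    def test_gain_of_site_at_second_locus(self, truth, library):
        d_set = [truth.allele("D1a"), truth.allele("D1b")]
        cands = find_caps_enzymes(d_set, truth.variant_table["D1b"][0], library)
        assert {(c.enzyme, c.mode) for c in cands} == {("BstSFI", "gain_of_site")}

    def test_forced_dcaps_locus_has_no_caps_enzyme(self, truth, library):
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        assert find_caps_enzymes(snp_set, truth.variant_table["B1e"][0], library) == []

    def test_equivalent_to_bruteforce_oracle(self, truth):
        rng = random.Random(77)
        lib = default_enzyme_library() + [
            random_enzyme(rng, f"R{i}") for i in range(30)
        ]
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        for target in ("B1b", "B1e", "B1p"):
            snp = truth.variant_table[target][0]
            got = {c.enzyme: c.mode for c in find_caps_enzymes(snp_set, snp, lib)}
            assert got == brute_force_caps(snp_set, snp, lib)

    def test_deterministic_ordering(self, truth, library):
        snp_set = [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]
        snp = truth.variant_table["B1b"][0]
        a = [c.enzyme for c in find_caps_enzymes(snp_set, snp, library)]
        b = [c.enzyme for c in find_caps_enzymes(snp_set, snp, library)]
        assert a == b

    def test_empty_library_raises(self, truth):
        snp_set = [truth.allele(n) for n in ("B1a", "B1b")]
        with pytest.raises(Exception, match="empty"):
            find_caps_enzymes(snp_set, truth.variant_table["B1b"][0], [])


class TestDesignDcaps:
    def _snp_set(self, truth):
        return [truth.allele(n) for n in ("B1a", "B1b", "B1e", "B1p")]

    def test_forced_locus_yields_hinfi_candidate(self, truth, library):
        cands = design_dcaps(self._snp_set(truth), truth.variant_table["B1e"][0], library)
        hinfi = [c for c in cands if c.enzyme == "HinfI"]
        assert hinfi
        # the engineered product carries the concrete GATTC realization
        best = hinfi[0]
        assert len(best.introduced_mismatch_positions) == 1

    def test_b1b_class_snp_yields_acc36i_candidate(self, truth, library):
        cands = design_dcaps(self._snp_set(truth), truth.variant_table["B1b"][0], library)
        assert [c for c in cands if c.enzyme == "Acc36I"]

    def test_all_candidates_pass_external_end_to_end_check(self, truth, library):
        # re-verify the self-oracle from outside the design routine
        alleles = self._snp_set(truth)
        byname = {e.name: e for e in library}
        model = BindingModel(max_mismatches=1, clamp_length=1)
        for target in ("B1b", "B1e"):
            snp = truth.variant_table[target][0]
            for cand in design_dcaps(alleles, snp, library):
                if cand.orientation == "forward":
                    fwd, rev = cand.modified_primer, cand.companion_primer
                else:
                    fwd, rev = cand.companion_primer, cand.modified_primer
                cut = {}
                for a in alleles:
                    (amp,) = amplify(a, fwd, rev, model)
                    cut[a.id] = digest(amp, byname[cand.enzyme]).is_cut
                expected_cut = {
                    a.id: (a.id == target) == (cand.cut_in == "target")
                    for a in alleles
                }
                assert cut == expected_cut

    def test_max_introduced_zero_is_caps_limiting_case(self, truth, library):
        # the forced-dCAPS locus has no natural site, so with no introduced
        # mismatches allowed nothing can be engineered
        cands = design_dcaps(
            self._snp_set(truth), truth.variant_table["B1e"][0], library,
            max_introduced=0,
        )
        assert cands == []

    def test_introduced_mismatch_never_at_three_prime_terminus(self, truth, library):
        for target in ("B1b", "B1e"):
            snp = truth.variant_table[target][0]
            for cand in design_dcaps(self._snp_set(truth), snp, library):
                plen = len(cand.modified_primer)
                assert plen not in cand.introduced_mismatch_positions

    def test_invalid_primer_range_raises(self, truth, library):
        with pytest.raises(DesignError):
            design_dcaps(
                self._snp_set(truth), truth.variant_table["B1e"][0], library,
                primer_lengths=range(30, 18),
            )


class TestSiteOverlapping:
    def test_both_strands_detected(self, library):
        byname = {e.name: e for e in library}
        seq = "AAAA" + "GCAGC" + "AAAA"
        assert site_overlapping(seq, 6, byname["BstV1I"])
        assert not site_overlapping(seq, 0, byname["BstV1I"])
        rc = "AAAA" + revcomp("GCAGC") + "AAAA"
        assert site_overlapping(rc, 6, byname["BstV1I"])
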