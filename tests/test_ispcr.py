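"""In-silico PCR: binding model, amplicon construction, nested and
allele-specific behavior."""

import random

import pytest

from capskit.ispcr import (
    Amplicon,
    BindingModel,
    Primer,
    amplify,
    estimate_tm,
    find_binding_sites,
    nested_amplify,
)
from capskit.seqcore import AlleleRecord, expand_degenerate, revcomp

from conftest import random_dna


def _template(rng, fwd, rev, gap):
    """Template 5'-pad + fwd site + gap + revcomp(rev) site + pad-3'."""
    return AlleleRecord(
        id="t",
        sequence=random_dna(rng, 30) + fwd + random_dna(rng, gap)
        + revcomp(rev) + random_dna(rng, 30),
    )


@pytest.fixture
def rng():
    return random.Random(42)


def brute_force_plus_hits(template: str, primer: str, model: BindingModel):
    """Independent Hamming-scan oracle for plus-strand binding."""
    k = len(primer)
    clamp = min(model.clamp_length, k)
    hits = []
    for p in range(len(template) - k + 1):
        mismatches = [
            p + j
            for j in range(k)
            if template[p + j] not in expand_degenerate(primer[j])
        ]
        if any(m >= p + k - clamp for m in mismatches):
            continue
        if len(mismatches) <= model.max_mismatches:
            hits.append(p + 1)
    return hits


class TestBinding:
    def test_exact_site_single_hit(self, rng):
        primer = Primer("f", random_dna(rng, 20))
        t = _template(rng, primer.sequence, "G" * 20, 100)
        (hit,) = find_binding_sites(t, primer, BindingModel(), "+")
        assert hit.position == 31
        assert hit.n_mismatches == 0

    def test_three_prime_terminal_mismatch_blocks_binding(self, rng):
        # the AS-PCR principle: a primer ending on the wrong base does not bind
        core = random_dna(rng, 19)
        primer = Primer("as", core + "T")
        t = AlleleRecord(id="t", sequence="A" * 25 + core + "C" + "A" * 25)
        assert find_binding_sites(t, primer, BindingModel(clamp_length=1), "+") == []

    def test_internal_mismatch_tolerated(self, rng):
        primer_seq = random_dna(rng, 20)
        site = primer_seq[:5] + ("A" if primer_seq[5] != "A" else "C") + primer_seq[6:]
        t = AlleleRecord(id="t", sequence="G" * 20 + site + "G" * 20)
        hits = find_binding_sites(t, Primer("f", primer_seq), BindingModel(), "+")
        assert len(hits) == 1
        assert hits[0].n_mismatches == 1

    def test_agrees_with_hamming_scan_oracle(self, rng):
        for _ in range(50):
            t = random_dna(rng, 150)
            primer = Primer("p", random_dna(rng, 12))
            model = BindingModel(
                max_mismatches=rng.randint(0, 2), clamp_length=rng.randint(0, 4)
            )
            got = [h.position for h in find_binding_sites(t, primer, model, "+")]
            assert got == brute_force_plus_hits(t, primer.sequence, model)

    def test_mismatch_monotonicity(self, rng):
        for _ in range(20):
            t = random_dna(rng, 200)
            primer = Primer("p", random_dna(rng, 11))
            counts = [
                len(find_binding_sites(t, primer, BindingModel(max_mismatches=m), "+"))
                for m in range(4)
            ]
            assert counts == sorted(counts)

    def test_minus_strand_positions(self, rng):
        primer = Primer("r", random_dna(rng, 20))
        t = _template(rng, random_dna(rng, 20), primer.sequence, 80)
        (hit,) = find_binding_sites(t, primer, BindingModel(), "-")
        assert t.sequence[hit.position - 1 : hit.position + 19] == revcomp(
            primer.sequence
        )


class TestAmplify:
    def test_single_product_and_reconstruction(self, rng):
        fwd = Primer("f", random_dna(rng, 20))
        rev = Primer("r", random_dna(rng, 20))
        t = _template(rng, fwd.sequence, rev.sequence, 200)
        (amp,) = amplify(t, fwd, rev, BindingModel())
        assert len(amp) == 240
        assert amp.sequence.startswith(fwd.sequence)
        assert amp.sequence.endswith(revcomp(rev.sequence))
        # removing the primer footprints recovers the template interior
        interior = amp.sequence[20:-20]
        assert interior == t.sequence[amp.start - 1 + 20 : amp.end - 20]

    def test_span_beyond_max_product_yields_nothing(self, rng):
        # primers straddling a ~2 kb insertion: no product
        fwd = Primer("f", random_dna(rng, 20))
        rev = Primer("r", random_dna(rng, 20))
        t = _template(rng, fwd.sequence, rev.sequence, 2026)
        assert amplify(t, fwd, rev, BindingModel(max_product=2000)) == []
        assert len(amplify(t, fwd, rev, BindingModel(max_product=2500))) == 1

    def test_primer_bases_overwrite_template(self, rng):
        # the dCAPS mechanism: a modified primer base appears in the product
        site = random_dna(rng, 20)
        modified = site[:10] + ("G" if site[10] != "G" else "T") + site[11:]
        fwd = Primer("f", modified)
        rev = Primer("r", random_dna(rng, 20))
        t = _template(rng, site, rev.sequence, 100)
        (amp,) = amplify(t, fwd, rev, BindingModel(max_mismatches=1, clamp_length=3))
        assert amp.sequence[10] == modified[10]
        assert amp.sequence[10] != site[10]

    def test_as_pcr_discriminates_alleles(self, rng):
        # two templates differing only under the primer's 3'-terminal base:
        # exactly one amplifies
        left = random_dna(rng, 30)
        core = random_dna(rng, 19)
        rev = Primer("r", random_dna(rng, 20))
        tail = random_dna(rng, 100) + revcomp(rev.sequence) + random_dna(rng, 30)
        mut = AlleleRecord(id="mut", sequence=left + core + "T" + tail)
        wt = AlleleRecord(id="wt", sequence=left + core + "C" + tail)
        as_primer = Primer("as", core + "T")
        model = BindingModel(max_mismatches=1, clamp_length=1)
        assert len(amplify(mut, as_primer, rev, model)) == 1
        assert amplify(wt, as_primer, rev, model) == []


class TestNested:
    def test_inner_contained_in_outer(self, rng):
        inner_f = Primer("if", random_dna(rng, 20))
        inner_r = Primer("ir", random_dna(rng, 20))
        inner_block = inner_f.sequence + random_dna(rng, 100) + revcomp(inner_r.sequence)
        outer_f = Primer("of", random_dna(rng, 20))
        outer_r = Primer("or", random_dna(rng, 20))
        t = AlleleRecord(
            id="t",
            sequence=random_dna(rng, 40) + outer_f.sequence + random_dna(rng, 50)
            + inner_block + random_dna(rng, 50) + revcomp(outer_r.sequence)
            + random_dna(rng, 40),
        )
        outer_amps = amplify(t, outer_f, outer_r, BindingModel())
        (amp,) = nested_amplify(t, (outer_f, outer_r), (inner_f, inner_r), BindingModel())
        assert len(amp) == 140
        assert any(o.start <= amp.start and amp.end <= o.end for o in outer_amps)
        # coordinates are reported on the original template
        assert t.sequence[amp.start - 1 : amp.start + 19] == inner_f.sequence

    def test_no_outer_product_means_no_nested_product(self, rng):
        inner_f = Primer("if", random_dna(rng, 20))
        inner_r = Primer("ir", random_dna(rng, 20))
        outer_f = Primer("of", random_dna(rng, 20))
        outer_r = Primer("or", random_dna(rng, 20))
        inner_block = inner_f.sequence + random_dna(rng, 100) + revcomp(inner_r.sequence)
        # outer span inflated past max_product by a large insertion
        t = AlleleRecord(
            id="t",
            sequence=outer_f.sequence + random_dna(rng, 1000) + inner_block
            + random_dna(rng, 1000) + revcomp(outer_r.sequence),
        )
        model = BindingModel(max_product=2000)
        assert amplify(t, outer_f, outer_r, model) == []
        assert nested_amplify(t, (outer_f, outer_r), (inner_f, inner_r), model) == []
        # the inner pair alone would still amplify
        assert len(amplify(t, inner_f, inner_r, model)) == 1

    def test_inner_outside_outer_yields_nothing(self, rng):
        outer_f = Primer("of", random_dna(rng, 20))
        outer_r = Primer("or", random_dna(rng, 20))
        stray_f = Primer("sf", random_dna(rng, 20))
        stray_r = Primer("sr", random_dna(rng, 20))
        t = _template(rng, outer_f.sequence, outer_r.sequence, 200)
        assert nested_amplify(t, (outer_f, outer_r), (stray_f, stray_r), BindingModel()) == []


class TestTm:
    def test_monotone_in_gc_and_deterministic(self):
        low = estimate_tm(Primer("a", "A" * 10))
        high = estimate_tm(Primer("g", "G" * 10))
        assert low < high
        assert estimate_tm(Primer("a", "A" * 10)) == low

    def test_degenerate_is_mean_over_expansion(self):
        # R averages A and G at one position
        p = Primer("d", "ACGTACGTAR")
        expanded = [
            estimate_tm(Primer("x", "ACGTACGTA" + b)) for b in "AG"
        ]
        assert estimate_tm(p) == pytest.approx(sum(expanded) / 2, abs=0.06)
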