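# Methods

## Scope and model

`capskit` simulates the complete life cycle of restriction-based PCR
markers for known allele variants: design (CAPS enzyme search, dCAPS primer
engineering), assay execution (in-silico PCR, virtual digestion), and
interpretation (profile-table allele calling). It deliberately models the
*information content* of these assays — which bands appear, whether a
product is cut — not their chemistry: thermal cycling programs, polymerase
kinetics, partial digestion and band intensity are out of scope.

## Sequence conventions

Internal computation is 0-based half-open; every coordinate crossing a
public boundary is 1-based inclusive, and coding coordinates count from the
A of ATG as position 1 (so "coding position 178" is the 178th base of the
open reading frame). Input is normalized to upper case with U mapped to T.
IUPAC ambiguity codes are first-class in patterns and primers; in
*template* sequence they are treated conservatively: a window containing an
ambiguous base never supports a recognition-site call and always counts as
a primer mismatch. This biases the simulator toward "uncut"/"no bind" on
uncertain input rather than inventing diagnostic signal.

## Restriction enzymes and digestion

An enzyme is `(recognition pattern, cut_top, cut_bottom, isoschizomers)`.
Offsets are measured from the 5′ end of the recognition site along the
strand carrying it, so Type IIS enzymes (e.g. a `GCAGC(8/12)` cutter) have
offsets exceeding the site length. Site scanning matches the pattern on the
plus strand and its reverse complement for minus-strand sites; palindromic
patterns report one hit per locus. Digestion uses top-strand cut indices —
a plus-strand site at 0-based `s` cuts at `s + cut_top`, a minus-strand
site spanning `[s, s+L)` cuts at `s + L - cut_bottom` — and discards cuts
falling outside the molecule, so a Type IIS site near an amplicon end
produces no cut. Complete digestion is assumed (every site cuts; overlapping
sites each cut). Fragment lengths always partition the molecule; this
conservation law is enforced by construction and re-checked against a naive
splitting oracle in the tests. If a user-supplied enzyme table omits cut
offsets they default to 0 and the resulting profiles are flagged
`approximate`: presence/absence of cutting is still reliable, sub-fragment
sizes are nominal.

The packaged default table holds the five enzymes of the emulated marker
system (BstV1I `GCAGC` 13/17, Acc36I `ACCTGC` 10/14, BstHHI `GCGC` 3/3,
HinfI `GANTC` 1/1, BstSFI `CTRYAG` 1/1) with their catalogue isoschizomers;
lookup resolves isoschizomer names case-insensitively and rejects ambiguous
claims. Note the distinction between HinfI's degenerate recognition
(`GANTC`) and the concrete realization `GATTC` that a dCAPS product
engineers: the table carries the degenerate pattern; the concrete instance
exists only in the product of the matching allele.

## Primer binding and PCR

A primer binds where (a) mismatches outside a 3′-terminal clamp number at
most `max_mismatches` and (b) every clamp base matches exactly, IUPAC-aware
on the primer side. Defaults are `max_mismatches=1`, `clamp_length=3`,
product window 50–2000 bp. The 2000 bp ceiling is what converts a large
insertion between a primer pair into a *no product* observation — a
legitimate diagnostic state, preserved end to end and matchable in profile
rows. Amplicon sequences are assembled as forward primer + template
interior + reverse complement of the reverse primer: primer bases overwrite
the template at both footprints, which is the entire mechanism of dCAPS and
of allele-specific PCR artifacts. All compatible primer placements are
reported (no strongest-band selection). Nested PCR amplifies with the outer
pair and re-amplifies each product with the inner pair, reporting
coordinates on the original template. Melting temperature is a GC-fraction
estimate (`64.9 + 41·(n_GC − 16.4)/N` °C, degenerate codes contributing
their expected GC), advisory only — it never gates amplification.

## Variant discovery

Alleles are compared by exact flank anchoring, not full alignment:
equal-length sequences column-wise (a SNP is a column where the target
differs from every reference and the references agree), length differences
by longest common prefix/suffix splitting into one clean insertion.
Anything messier raises with an instruction to pre-align externally. This
keeps the variant caller exactly testable and matches the intended inputs —
allele series differing by point mutations and clean insertions.

## CAPS search and dCAPS engineering

For a target SNP, every enzyme and every recognition placement overlapping
the SNP column is tested in the target and in each reference context
(references located by flank anchoring). An enzyme qualifies when site
presence separates the target from *all* references — gain of site (cuts
target only) or loss of site (cuts all others). Candidates are ranked by
(extra constitutive sites within the ±20 bp window, recognition length,
name); the ranking criteria are this package's own choice, fixed so
identical inputs give identical output order.

dCAPS search enumerates, per enzyme, both pattern orientations and every
placement covering the SNP column, and both primer orientations. A
placement is viable when the SNP column lies *outside* the primer footprint
(the diagnostic base must come from the template — a primer covering it
would erase the polymorphism from every product), the target base realizes
the pattern at that column while no reference base does, at most
`max_introduced` mismatches (default 1, the classic dCAPS rule) are forced
by the pattern over the footprint, and neither the 3′-terminal base nor the
SNP column is modified. A companion primer is placed naively: an exact
20-mer from the target ~150 bp away on the opposite side, shared verbatim
by every reference. Every surviving construct is then simulated — each
allele amplified with the candidate pair and digested with the candidate
enzyme — and emitted only if the cut/uncut partition is exactly {target}
vs. {all others}. This self-oracle runs *inside* the design routine; the
test suite re-runs it externally. With `max_introduced=0` the search
degenerates to natural-site placements coverable by a primer, i.e. the
CAPS limiting case.

The simulation inside the design routine uses
`BindingModel(max_mismatches=max_introduced, clamp_length=1)`, and the
packaged panel uses the same clamp: a dCAPS primer's deliberate mismatch
can legitimately sit within three bases of the 3′ end (the HinfI-style
design forces it there), so the default clamp of 3 would veto the very
primers the method exists to create, while a clamp of 1 still preserves
allele-specific 3′-terminal discrimination. The module-level default
remains (1, 3) for ordinary STS/e-PCR use.

## Genotyping

A marker panel is an ordered marker list plus a profile table mapping each
known allele to expected outcomes per marker (product flag, cut flag,
product length, fragment multiset; any field may be `any`). Fragment and
product lengths compare under a co-migration tolerance
`max(10 bp, 5% of mean length)` — typical 1–2 % agarose discrimination; the
floor and fraction are configurable per panel. A call is `unique` iff
exactly one row matches; `no_amplification` is returned when no marker
produced anything. Panel validation fails fast on unresolvable enzymes,
dangling primer references, and pairwise-indistinguishable rows under the
configured resolution. One query sequence is one haplotype at one locus;
heterozygotes or bulks are genotyped by calling each sequence separately —
a sequence-level tool has no peak-mixture signal to model. Cross-locus
specificity rests on the binding model's mismatch budget: primers of one
locus simply find no placement on the other locus's sequence.

## The synthetic reference system

`generate_reference_system(seed)` builds two loci (2600 bp and 1400 bp,
ORFs at fixed offsets) and nine alleles emulating a semi-dwarfing allele
series. Planted contexts realize the classic discrimination motifs
literally: `GCAGC → GTAGC` (loss, with the mutant TAG in frame — a true
nonsense mutation), `GCGC → GCGT` at coding position 178 (loss, in-frame
TAG), `CCGTAG → CTGTAG` (gain through the degenerate `CTRYAG`; the
wild-type context differs at the pattern-invariant T and is planted at a
codon frame where its embedded TAG is split across codons, keeping the wild
ORF stop-free). One SNP locus (`ACCATCCAA`, C→T) is constructed to match
*no* library site naturally — verified at generation time — forcing the
dCAPS path, where the designed primer's introduced G completes the concrete
`GATTC` in the product. Three insertion alleles carry 197 bp (5′ flank,
shared by two alleles), 160 bp (promoter) and 2026 bp (ORF interior)
seeded-random inserts; STS primers anchored inside the inserts give 247 bp
and 330 bp carrier-specific products, size-shift primer pairs give
140→337 bp and 180→340 bp, and the 2026 bp insert pushes the first-round
nested span past the 2000 bp ceiling (no product).

Background sequence is random at GC 0.45. After planting, the wild types
are *scrubbed*: every library recognition site not on the intended list is
destroyed by mutating its most constrained mutable column (mutating under
an N can never break a match), iterating with premature-stop repair until a
clean pass. Flanks that a primer-introduced base could combine with into an
accidental constitutive site are pinned as part of the planted context.
Everything derives deterministically from the seed; regeneration is
byte-identical. The panel's dCAPS markers are produced by the design
pipeline itself at generation time, so fixture construction exercises the
full design path, and the generated panel must pass validation.

What the generator does **not** emulate: real genomic base composition and
repeats, homeologous near-identical loci, heterozygosity, sequencing error,
and enzyme-specific biochemistry (methylation sensitivity, star activity,
partial digestion). Passing tests therefore demonstrate the correctness of
the design/simulation/calling logic under clean single-locus input, not
robustness to noisy or repetitive genomes — diverged inputs should be
pre-aligned and curated before design.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run in
seconds: oracle sweeps use 1000 random (sequence, enzyme) pairs of 20–500
bp, the recovery property regenerates 20 independent reference systems
(180 allele calls), and design searches run over the five-enzyme default
library plus up to 45 random enzymes. Every random draw is seeded; derived
seeds stay below 2³¹. Candidate orderings and generator output are fully
deterministic, so identical inputs and seeds reproduce identical files.

## Known limitations

* Companion primers are naively placed, not optimized (no Primer3-style
  pair scoring, no hairpin/dimer screening); Tm is a crude estimate.
* The binding model is positional, not thermodynamic: a mismatch budget and
  a clamp, with no nearest-neighbor ΔG.
* `locate_variants` refuses diverged or multi-indel inputs rather than
  aligning them.
* Single enzyme per marker (no double digests); complete digestion assumed.
* Gel realism is one co-migration threshold; band intensity and faint
  nonspecific products are not scored.
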