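# capskit

**CAPS/dCAPS marker design, in-silico PCR, and restriction-assay genotyping
for single-nucleotide and insertion variants.**

`capskit` is for geneticists and breeders who genotype known allele variants
with gel-based PCR assays rather than sequencing. Given a set of allele
sequences of one locus, it answers three questions:

1. **Marker design.** For a target SNP, is there a restriction enzyme whose
   recognition site distinguishes the target allele from *all* other alleles
   — either because the mutation creates the site (*gain of site*) or
   destroys it (*loss of site*)? That is a **CAPS** marker (cleaved amplified
   polymorphic sequence): amplify, digest, read cut vs. uncut bands.
   When no natural site exists, can a primer ending just short of the SNP
   carry a deliberate mismatch so that, in the PCR product (where primer
   bases overwrite the template), a site is completed by the diagnostic base
   of exactly one allele? That is a **dCAPS** marker (derived CAPS).
2. **Assay simulation.** In-silico PCR with a mismatch/3′-clamp binding
   model — including nested PCR (first-round product as second-round
   template) and allele-specific PCR (discrimination by the 3′-terminal
   base) — followed by virtual digestion into gel-resolvable fragment
   lengths, with IUPAC-degenerate recognition sites (e.g. `CTRYAG`) scanned
   on both strands and Type IIS cut offsets that may fall outside the site.
3. **Allele calling.** Run a whole marker panel against query sequences and
   match the observed outcome vector (product present/absent, cut/uncut,
   fragment sizes under a co-migration tolerance) against a per-allele
   profile table. Absence of a product is itself evidence: a primer pair
   straddling a multi-kilobase insertion yields no product at all.

The model system emulated throughout (and shipped as a seeded synthetic
reference, see `capskit.fixtures`) is the wheat *Rht-B1*/*Rht-D1*
semi-dwarfing allele series: nonsense SNPs whose classic discrimination
contexts are `GCAGC → GTAGC` (BstV1I, loss), `GCGC → GCGT` (BstHHI, loss)
and `CTRYAG` matching the mutant `CTGTAG` (BstSFI, gain); one SNP with no
natural site, resolved by a dCAPS primer that completes a `GATTC` (HinfI)
site in the product; and 197/160/2026 bp insertions detected by STS
products of 247 bp and 330 bp and by first-round nested-PCR dropout.
All fixture sequences are synthetic — generated from a seed, not
downloaded.

## Worked example

Generate the synthetic reference system, design markers, and genotype:

```bash
capskit fixtures --seed 1 --out-dir fix
# -> wrote 9 alleles, truth table and panel to fix
```

`fix/alleles.fasta` holds all nine alleles; the four equal-length SNP-class
alleles (`B1a B1b B1e B1p`) were saved as `snp_alleles.fasta` for the
design steps below (design operates on coordinate-compatible alleles;
insertion alleles are handled by STS markers instead).

CAPS search for the `B1b`-class SNP (C→T inside a `GCAGC` site):

```bash
capskit design-caps snp_alleles.fasta B1b
```
```
snp_position  ref  alt  enzyme  mode          extra_sites
803           C    T    BstV1I  loss_of_site  0
```

The enzyme cuts every allele *except* the target — the classic
loss-of-site read-out. For the `B1e`-class SNP no such enzyme exists, so a
dCAPS primer is engineered:

```bash
capskit design-dcaps snp_alleles.fasta B1e
```
```
snp_position  enzyme  orientation  cut_in  modified_primer     introduced_positions  companion_primer      product_bp
953           HinfI   forward      target  TATAGTCCAGTACACGAT  16                    GGGCAACCAAAGATTAAAGT  188
```

The primer carries one introduced mismatch (position 16, a C→G) three bases
from its 3′ end; in the 188 bp product this completes `GAT_C` so that the
mutant T — and only the mutant T — finishes a `GATTC` HinfI site. Every
emitted candidate has already passed an end-to-end amplify→digest
simulation on all supplied alleles.

Genotyping all nine alleles against the packaged panel:

```bash
capskit genotype fix/panel.yaml fix/alleles.fasta
```
```
query  marker        state    products  fragments  status  called
B1a    CB1b/BstV1I   product  135       69,66      unique  B1a
B1a    dCB1b/Acc36I  product  168       168        unique  B1a
B1a    dCB1e/HinfI   product  188       188        unique  B1a
...
```

Each query is called `unique` when exactly one profile row matches;
`ambiguous`, `inconsistent` and `no_amplification` are reported with the
full evidence vector. The same operations are available as a library
(`capskit.find_caps_enzymes`, `capskit.design_dcaps`, `capskit.amplify`,
`capskit.digest`, `capskit.call_alleles`, ...).

## Documentation

`docs/methods.md` describes the binding model, the digestion conventions,
the dCAPS search and its self-oracle, the synthetic generator's layout and
what it does and does not emulate, and the package's numerical choices and
limitations.
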