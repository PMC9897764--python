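# trnacurate

Curation of predicted prokaryotic tRNA gene sets: distinguishing canonical
tRNA genes from tRNA gene fragments, rescuing isotype misassignments caused
by ambiguous bases, and reporting deviations from a standard gene set.

## The problem

Automated tRNA gene finders (tRNAscan-SE, as mirrored in GtRNAdb) are very
good at finding tRNA-like sequences — including ones that are not canonical
tRNA genes.  Two biological processes routinely leave partial tRNA gene
copies in prokaryotic genomes:

* **Mobile-element integration.**  Prophages and integrative/conjugative
  elements preferentially integrate into tRNA genes.  Integration
  reconstitutes one complete gene copy and leaves a partial copy (typically
  the 3'-terminal segment containing the T-arm and one acceptor-stem side)
  at the opposite end of the element, flanked by direct repeats (attL/attR).
  The partial copy is often listed as a second, standard tRNA gene.
* **CRISPR-Cas spacer acquisition.**  A spacer derived from a viral tRNA
  gene can make a repeat–spacer array look like a (long, very low-scoring)
  tRNA gene.

A third source of spurious deviations is assembly ambiguity: `N` bases
inside a gene make the finder misassign the anticodon or isotype, producing
a false "additional" gene of one type plus a false "missing" gene of
another.

In Archaea the expected complement is a standard set of 46 tRNA types, each
encoded by a single gene copy (three distinct CAT-anticodon isotypes:
initiator Met, elongator Met, and Ile2).  Measured against that set, these
artefacts masquerade as biologically interesting gene-set deviations.
`trnacurate` automates the triage workflow a careful curator would apply:

1. **Structure annotation** — a rule engine locates the cloverleaf elements
   in order (acceptor stem 1–7/72–66 with optional 3' CCA and discriminator
   73; T-arm with loop consensus `UUCRANN`; variable region; anticodon arm
   with a 7-nt loop and the anticodon at positions 34–36; D-arm with a
   3–4-bp stem; connectors 8–9 and 26), collecting a defect list.
2. **Context screens** — shared terminal repeats between full/partial gene
   pairs (attR geometry, both strands, up to 250 kb apart), a minimal
   periodic direct-repeat finder for CRISPR arrays, `N`-ambiguity checks,
   and intersection with a user-supplied tmRNA track.
3. **Triage** — per-gene categories (`CANONICAL`, `FRAGMENT_ATTR`,
   `FRAGMENT_CRISPR`, `MISASSIGNED_AMBIGUOUS`, `NONCANONICAL_OTHER`,
   `LEGITIMATE_DUPLICATE`), driven by context evidence first, then isotype
   score bands (<60 likely non-canonical, 60–90 uncertain, >90 likely
   canonical), structural defects and pseudogene flags.  An `N`-containing
   gene that is structurally sound is rescued to the unique missing
   standard type it matches.  A separate <85 low-score flag marks genes
   deserving manual scrutiny.
4. **Comparison** — per-unit anomaly records and a genomes × tRNA-types
   count matrix against the standard set, in raw and curated modes.

A seeded synthetic-genome generator plants canonical genes, integration
remnants, CRISPR arrays and `N`-masked genes with machine-readable ground
truth, so the whole pipeline is testable offline.

## Worked example

Generate a synthetic genome with one integration remnant, one CRISPR array
carrying a tRNA fragment in a spacer, and one `N`-masked gene, then curate
it:

```python
from trnacurate.synthetic_fixtures import (
    FixtureSpec, IntegrationSpec, ArraySpec, MaskSpec, generate,
    write_fixture,
)
fx = generate(FixtureSpec(
    seed=11, genome_length=120_000, n_canonical=46,
    integrations=(IntegrationSpec(target_index=0),),
    arrays=(ArraySpec(n_repeats=12, embed_trna_fragment=True,
                      fragment_source_index=1),),
    maskings=(MaskSpec(gene_index=2),),
))
write_fixture(fx, "demo_fixture")
```

```bash
trnacurate curate --genome demo_fixture/genome.fasta \
    --predictions demo_fixture/predictions.tsv \
    --genome-id demo --outdir demo_out
cat demo_out/summary.txt
```

```
genome: demo
genes: 48
category CANONICAL: 45
category FRAGMENT_ATTR: 1
category FRAGMENT_CRISPR: 1
category MISASSIGNED_AMBIGUOUS: 1
category NONCANONICAL_OTHER: 0
category LEGITIMATE_DUPLICATE: 0
category UNCERTAIN: 0
raw anomalies: 4
curated anomalies: 0
isotype scores: n=48 min=9.6 median=119.7 max=140.0
low-score genes (<85): 2: tRNA-Leu-CAA-41, tRNA-Thr-CGT-48
```

Reading the output: of the 48 predicted genes, the two planted fragments
were removed (the partial integration copy via its shared 44-bp terminal
repeat with the full gene 21.4 kb away; the array-embedded fragment via its
CRISPR overlap), and the `N`-masked gene was rescued to its true type.  The
raw listing deviates from the 46-type standard set in 4 units; after
curation the gene set conforms exactly (`curated anomalies: 0`).  The two
low-score genes are exactly the two fragments.

`demo_out/` also contains the per-gene curation table (TSV and JSON, with
band, category, evidence and rationale per gene), BED6/GFF3 tracks, the
anomaly table and the score histogram.

## The packaged survey fixture

`trnacurate.survey` ships a literature-curated table of the 15 deviations
of the 20 Thermococcaceae tRNA gene sets listed in GtRNAdb (Release 19)
from the archaeal standard set, and reconstructs the full raw listings
(929 genes) from it.  Running the curation over those listings reduces the
15 raw anomalies (12 additional, 3 missing, across 7 of 20 genomes) to a
single genuine deviation — a duplicated Ala-TGC gene — and reassigns the
three ambiguity-driven misassignments (Leu-NAG→Leu-CAG, Pro-NGG→Pro-GGG,
Und-NTG→Gln-CTG).

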