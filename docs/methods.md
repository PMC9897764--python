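# Methods

This note documents the models, rules and numerical choices behind
`trnacurate`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 1-based inclusive, matching tRNAscan-SE
tabular output and database gene listings; conversion to 0-based half-open
intervals happens only when reading or writing BED.  tRNAscan-SE rows with
`Begin > End` encode minus-strand genes and are normalized at parse time to
`start <= end` plus an explicit strand.  Isotype spellings are normalized
to a single vocabulary (the 20 amino acids plus `iMet`, `Ile2`, `Und`,
`Sup`, `SeC`); `iMet`/elongator `Met`/`Ile2` are always distinct types,
since all three share the CAT anticodon and conflating them hides real
deviations.  Intron spans are taken from the prediction table and spliced
out before structure annotation; the package does not detect introns.

The packaged `archaea46.tsv` standard set (46 single-copy types) is
configuration, not code: it ships as an editable TSV and any standard set
with columns `isotype / anticodon / expected_copies` can be substituted.
The composition encodes the consensus archaeal decoding strategy (no A34
anticodons, three CAT isotypes, five-anticodon Arg and Leu families,
four-anticodon Ser).

## Structure annotation

The annotator applies six location steps in a fixed order, each anchored
on the previously found element, mirroring how a curator walks a tRNA
sequence from its 3' end:

1. **Acceptor/CCA/discriminator.**  If the sequence ends in `CCA` the
   discriminator is position −4 from the end and the acceptor 3' side the
   seven bases before it; otherwise the CCA is assumed post-
   transcriptionally added (warning `NO_CCA`, not fatal — many prokaryotic
   tRNA genes do not encode CCA) and the anchoring falls back to the last
   base as discriminator.  Both anchorings are tried and the one with
   fewer acceptor mispairs wins.  Pairing is Watson–Crick plus G·T wobble
   in all stems; `N` matches anything but is tallied.
2. **T-arm.**  The 3'-most 17-nt window 5' of the acceptor 3' side whose
   loop matches `TTCRANN` and whose 5-bp stem pairs (zero-mismatch
   default).  3'-most because the T-arm is the last arm before the
   acceptor stem.
3. **Variable region** (implied by step 4's admissible gaps).
4. **Anticodon arm.**  A 17-nt window (5-bp stem, 7-nt loop) whose gap to
   the T-arm is 5 or 4 nt (standard variable region) or 10–24 nt (type II
   long variable arm, Ser/Leu).  Gaps are tried in that order, so the
   compact geometry is preferred.  The anticodon is loop positions 3–5
   (Sprinzl 34–36); a loop not starting `CT` is a warning, as the CU start
   is typical but not universal.
5. **D-arm.**  A 3–4-bp stem with a 4–12-nt loop ending 1–2 nt before the
   anticodon arm and starting after position 8.  Among pairing candidates,
   those leaving a standard 2–3-nt connector after the acceptor stem are
   preferred, then the smallest gap to the anticodon arm, then the longest
   stem — a deterministic tie-break that recovers the planted geometry of
   every generated gene.
6. **Connectors 8–9 and 26** are derived from the located arms; a
   non-standard 8–9 gap is the warning `BAD_CONNECTOR`.

Missing core arms are fatal defects; when an anchor is missing the
elements that would be sought from it are reported missing as well (no
T-arm implies no locatable anticodon arm or D-arm).  A sequence under
50 nt is fatally `TRUNCATED` but still annotated as far as possible, so
fragments report which elements they do retain.  A gene is *canonical*
iff it has no fatal defect.  The acceptor stem tolerates one mispair by
default (warning, not fatal): a single broken pair is compatible with a
point mutation or a reference error in an otherwise complete, essential
gene, whereas two or more are treated as a genuine structural failure.

Positions are simplified Sprinzl-style indices; genes with long variable
arms shift absolute indices, so element order — checked structurally in
the tests — is authoritative, not absolute position.

## Context screens

**attR pairs.**  The screen is anchored on predictions rather than doing
genome-wide repeat discovery: terminal segments of same-isotype (or
`Und`) prediction pairs on a contig are compared, and each prediction's
terminal 100-bp window is additionally scanned against the whole contig
(both strands) to catch partial copies the gene finder never called.  A
shared terminal repeat is the maximal end-anchored match within a
mismatch budget (default 1), trimmed so its inner boundary is a match —
this makes the reported repeat length well defined.  The de novo scan is
seeded by pigeonhole: a valid hit must contain an exact chunk of the
terminal `min_repeat_length` bases, so candidate anchors come from exact
substring search and only candidates are extended.  The default minimum
repeat length of 20 bp is a configurable floor (observed integration
repeats are well above it, e.g. 44 bp); `max_separation` defaults to
250 kb to cover rearranged cases where the partial copy has drifted
~179 kb from its partner, and element size is reported but never
filtered on.  Which copy of a pair is "partial" is decided by fewer
located structural elements, then lower isotype score, then flagged
uncertain.

**CRISPR arrays.**  A minimal periodic direct-repeat finder, not a
CRISPRFinder replacement (an external array track can be supplied
instead): exact 13-mers recurring at a period of repeat+spacer length
(40–110 bp for the default 20–50 bp repeats and 20–60 bp spacers) seed
chains of at least 3 copies; chains are extended column-by-column while
all copies agree, bounded by the repeat/spacer ranges.  A copy carrying a
substitution inside the seed breaks the exact chain; gaps of up to
`max_repeat_copy_mismatches + 1` periods are allowed and the skipped copy
is recovered against the consensus.  Overlapping candidate arrays are
merged, preferring more repeat copies, then fewer copy mismatches —
this also resolves the case where a subset of copies shares a longer
unanimous flank than the full array.

**Ambiguity and tmRNA.**  `N` bases in a gene (or its listed anticodon)
yield `AMBIGUOUS_N` evidence with the count and whether an `N` sits in
the anticodon; intersection with a user-supplied tmRNA BED yields
`TMRNA_OVERLAP` evidence with the overlap size.  tmRNA genes are not
detected de novo.

## Triage

Category precedence: CRISPR overlap, then attR evidence where the gene is
the partial copy, then ambiguity rescue, then tmRNA overlap, then the
score bands combined with structure and the pseudogene flag.  Context
evidence outranks scores because mechanistic evidence is more specific
than a low score.  Decision bands default to <60 likely non-canonical,
60–90 uncertain, >90 likely canonical; a gene in the uncertain band with
no fatal defects is called `CANONICAL` with a "manual review recommended"
rationale (the single-tolerated-mispair precedent), while fatal defects
there mean `NONCANONICAL_OTHER`.  The <85 low-score flag is a reporting
flag on every call, deliberately distinct from the decision bands.  The
pseudogene flag is advisory: it only forces a non-canonical call when
structural defects concur, so a flagged but complete, well-scoring gene
survives.

Rescue of `N`-containing genes is two-pass: the per-genome deficit of
missing standard types is computed from the confidently canonical
first-pass calls (excluding `N`-typed genes), then an `N`-gene with no
fatal defects is reassigned to the *unique* deficit type whose anticodon
matches at every non-`N` position (isotypes must agree unless the gene is
`Und`).  Zero or multiple matches leave the gene unrescued — uniqueness is
what justifies the reassignment.  Surplus clean copies of an
already-satisfied type are `LEGITIMATE_DUPLICATE`; copies are walked in
(contig, position) order, so which twin of an identical pair carries the
duplicate label is positional, not biological.

In curated comparisons, rescued genes count under their reassigned type,
fragments and other non-canonical calls are excluded from the canonical
matrix, and anomalies are per-unit records (observed 3 vs expected 1
yields two records), so the anomaly count equals the L1 distance between
count vectors.

## Synthetic fixtures

The generator emulates: uniform-GC background (default 50%, configurable
over the 40–56% range typical of the relevant genomes); canonical genes
built stem-by-stem with exact Watson–Crick pairing and randomized loops
outside the fixed motifs, validated by the annotator at build time;
integration remnants as a terminal segment of a planted gene duplicated
at a configurable distance with a configurable mismatch count, optionally
inverted; CRISPR arrays of identical repeats with unique random spacers,
optionally carrying a diverged (3-substitution) T-arm+acceptor fragment
of a planted gene in one spacer; and `N`-masked genes (default: the
wobble base 34).  A tRNAscan-SE-style prediction table accompanies each
genome, with fragment predictions flagged as pseudogenes and given low
isotype scores, so the pipeline runs without the gene finder.

Two disambiguation steps make planted events exactly recoverable: the
bases flanking a planted partial copy are forced to differ from the
source gene's continuation (so the maximal shared repeat equals the
planted length), and the columns flanking planted array repeats are made
non-unanimous across copies (so the maximal common repeat equals the
planted repeat).  Without these, a random flanking base can extend a
maximal match by a base or two — a property of maximal-match definitions,
not of the detectors.

What passing on fixtures does **not** show: performance on real element
cargo (interiors are random sequence, so there are no nested repeats,
transposases or tandem arrays), on genomes with skewed or heterogeneous
composition, on degraded/ancient fragments, or on the gene finder's own
errors — the prediction tables here are by construction consistent with
the planted truth.

## Determinism, sizes and degenerate inputs

Every random draw flows from one seeded generator per fixture; the
pipeline itself contains no randomness, so identical inputs and configs
give byte-identical outputs, and re-curating the canonical output is a
fixed point.  Test and acceptance runs use desk-scale sizes chosen to
exercise every geometry: 48-kb genomes for the oracle-equivalence sweeps
(20 seeds), a 220-kb genome for the rearranged-integration case, 100
seeded genes for annotator recall.  Degenerate inputs are values, not
crashes: empty prediction tables parse to empty lists, absent isotype
scores band as uncertain with a warning, sequences under 50 nt annotate
as truncated, and an empty score list yields an empty histogram summary.

The 20-genome survey fixture reconstructs full raw listings (929 genes)
from the packaged deviation table; conforming background records carry no
isotype scores, so score distributions are computed only over the
table's scored records.  Full-scale score distributions across hundreds
of genomes would require the external genome and database downloads and
are outside the packaged fixture's scope, though the batch interfaces
support them.
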