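"""Seeded synthetic genomes with planted tRNA genes and confounders.

The generator emulates the genomic situations the curation pipeline must
resolve: structurally canonical tRNA genes; partial gene copies left by
mobile-element integration (a terminal segment of a gene duplicated at a
configurable distance, optionally inverted, with a configurable mismatch
count — the attR geometry); CRISPR arrays of identical direct repeats with
unique spacers, optionally carrying a tRNA gene fragment in one spacer;
and N-masked genes emulating ambiguous assembly regions.  Machine-readable
ground truth accompanies every genome, and a tRNAscan-SE-style prediction
table is emitted so the pipeline can run without the gene finder.

What it deliberately does not emulate: real element cargo (element
interiors are random sequence), transcription signals, and base
composition beyond a uniform GC dial (default 50%, configurable over the
40-56% range observed across Thermococcaceae genomes).

Planted events are made unambiguously recoverable: the bases immediately
flanking a planted repeat copy are forced to disagree with the source
continuation, so the maximal shared repeat equals the planted length
rather than being randomly extendable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    TRNAGenePrediction,
    load_standard_set,
    reverse_complement,
    to_bed_interval,
    write_trnascan_output,
)
from .structure_annotator import (
    StructureConfig,
    annotate_structure,
    is_canonical_structure,
)

__all__ = [
    "IntegrationSpec",
    "ArraySpec",
    "MaskSpec",
    "FixtureSpec",
    "PlantedGene",
    "PlantedPartial",
    "PlantedArray",
    "PlantedMask",
    "GroundTruth",
    "Fixture",
    "make_canonical_gene",
    "generate",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rand_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    return "".join(chr(b) for b in rng.choice(_BASES, size=n, p=p))


def _wc(seq: str) -> str:
    """Watson-Crick reverse complement of a stem side."""
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class IntegrationSpec:
    """One planted integration remnant (full gene + partial terminal copy)."""

    target_index: int
    dup_length: int = 44
    mismatches: int = 1
    element_length: int = 21_400
    invert: bool = False
    predict_partial: bool = True


@dataclass(frozen=True)
class ArraySpec:
    """One planted CRISPR array of identical repeats and unique spacers."""

    n_repeats: int = 5
    repeat_length: int = 30
    spacer_length: int = 36
    embed_trna_fragment: bool = False
    fragment_source_index: int = 0


@dataclass(frozen=True)
class MaskSpec:
    """N-mask positions of a planted gene (default: the wobble base 34)."""

    gene_index: int
    positions: tuple[int, ...] = ()  # 1-based within the oriented gene
    listed_isotype: str | None = None


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genome_length: int = 50_000
    n_canonical: int = 8
    gc: float = 0.5
    seq_id: str = "contig_1"
    genome_id: str = "synthetic"
    integrations: tuple[IntegrationSpec, ...] = ()
    arrays: tuple[ArraySpec, ...] = ()
    maskings: tuple[MaskSpec, ...] = ()


@dataclass
class PlantedGene:
    name: str
    seq_id: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    sequence: str


@dataclass
class PlantedPartial:
    name: str | None
    seq_id: str
    start: int
    end: int
    strand: str
    target_name: str
    repeat_length: int
    mismatches: int
    element_length: int
    inverted: bool
    predicted: bool


@dataclass
class PlantedArray:
    seq_id: str
    repeat_consensus: str
    repeat_spans: list[tuple[int, int]]
    spacer_spans: list[tuple[int, int]]
    fragment_prediction: str | None


@dataclass
class PlantedMask:
    gene_name: str
    gene_positions: tuple[int, ...]
    genomic_positions: tuple[int, ...]
    true_isotype: str
    true_anticodon: str
    listed_isotype: str
    listed_anticodon: str


@dataclass
class GroundTruth:
    seq_id: str
    genes: list[PlantedGene] = field(default_factory=list)
    partials: list[PlantedPartial] = field(default_factory=list)
    arrays: list[PlantedArray] = field(default_factory=list)
    masks: list[PlantedMask] = field(default_factory=list)

    def canonical_names(self) -> set[str]:
        return {g.name for g in self.genes}

    def noncanonical_names(self) -> set[str]:
        names = {p.name for p in self.partials if p.name}
        names |= {a.fragment_prediction for a in self.arrays
                  if a.fragment_prediction}
        return names

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    truth: GroundTruth
    predictions: list[TRNAGenePrediction]


def make_canonical_gene(
    rng: np.random.Generator,
    isotype: str,
    anticodon: str,
    extra_arm: bool | None = None,
    structure_config: StructureConfig | None = None,
) -> str:
    """Sample a 72-90 nt gene sequence that annotates cleanly.

    Stems are drawn with exact Watson-Crick pairing; loops are random
    outside the fixed motifs (T-loop TTCRANN, anticodon loop CT + NNN +
    NN).  Type II tRNAs (Ser/Leu) receive a long variable arm by default.
    The draw is validated with the structural annotator and redrawn on the
    rare accidental rule violation, so the result is canonical by
    construction.
    """
    if "N" in anticodon:
        raise ValueError("anticodon must be N-free for generation")
    if extra_arm is None:
        extra_arm = isotype in {"Ser", "Leu"}
    config = structure_config or StructureConfig()
    for _ in range(100):
        acc5 = _rand_bases(rng, 7)
        conn89 = _rand_bases(rng, 2)
        d_stem = _rand_bases(rng, 4)
        d_loop = _rand_bases(rng, 8)
        pos26 = _rand_bases(rng, 1)
        ac_stem = _rand_bases(rng, 5)
        ac_loop = "CT" + anticodon + _rand_bases(rng, 2)
        if extra_arm:
            v_stem = _rand_bases(rng, 4)
            variable = (
                _rand_bases(rng, 2) + v_stem + _rand_bases(rng, 4)
                + _wc(v_stem) + _rand_bases(rng, 1)
            )
        else:
            variable = _rand_bases(rng, 5)
        t_stem = _rand_bases(rng, 5)
        t_loop = "TTC" + ("A" if rng.integers(2) else "G") + "A" \
            + _rand_bases(rng, 2)
        seq = (
            acc5 + conn89
            + d_stem + d_loop + _wc(d_stem)
            + pos26
            + ac_stem + ac_loop + _wc(ac_stem)
            + variable
            + t_stem + t_loop + _wc(t_stem)
            + _wc(acc5) + _rand_bases(rng, 1) + "CCA"
        )
        ann = annotate_structure(seq, config)
        if is_canonical_structure(ann) and ann.anticodon == anticodon:
            return seq
    raise RuntimeError(
        f"failed to sample a canonical {isotype}-{anticodon} gene"
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_PAD = 60


class _Layout:
    """Non-overlapping feature placement by rejection sampling."""

    def __init__(self, rng: np.random.Generator, length: int):
        self.rng = rng
        self.length = length
        self.occupied: list[tuple[int, int]] = []

    def is_free(self, start0: int, end0: int) -> bool:
        if start0 < _PAD or end0 >= self.length - _PAD:
            return False
        return not any(
            start0 - _PAD <= oe and os <= end0 + _PAD
            for os, oe in self.occupied
        )

    def reserve(self, start0: int, end0: int) -> None:
        self.occupied.append((start0, end0))

    def place(self, length: int, tries: int = 2000) -> int:
        for _ in range(tries):
            start0 = int(self.rng.integers(_PAD, self.length - length - _PAD))
            if self.is_free(start0, start0 + length - 1):
                self.reserve(start0, start0 + length - 1)
                return start0
        raise ValueError(
            f"could not place a {length}-bp feature without overlap; "
            "increase genome_length or reduce features"
        )


def _paste(genome: np.ndarray, start0: int, seq: str) -> None:
    genome[start0:start0 + len(seq)] = np.frombuffer(
        seq.encode(), dtype=np.uint8
    )


def _force_differ(genome: np.ndarray, pos0: int, forbidden: str,
                  rng: np.random.Generator) -> None:
    choices = [b for b in "ACGT" if b != forbidden]
    genome[pos0] = ord(choices[int(rng.integers(len(choices)))])


def generate(spec: FixtureSpec) -> Fixture:
    """Build the genome, ground truth and prediction table for a spec.

    Deterministic: the same spec (seed included) yields byte-identical
    output.  Raises ``ValueError`` when the requested features cannot be
    placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    standard = load_standard_set()
    if spec.n_canonical > len(standard):
        raise ValueError("n_canonical exceeds the standard set size")
    type_idx = rng.choice(len(standard), size=spec.n_canonical, replace=False)
    types = [standard.types[int(i)] for i in type_idx]

    gene_seqs = [
        make_canonical_gene(rng, isotype, anticodon)
        for isotype, anticodon in types
    ]
    genome = np.frombuffer(
        _rand_bases(rng, spec.genome_length, spec.gc).encode(),
        dtype=np.uint8,
    ).copy()
    layout = _Layout(rng, spec.genome_length)
    truth = GroundTruth(seq_id=spec.seq_id)
    predictions: list[TRNAGenePrediction] = []

    # ---- CRISPR arrays (largest features first) -------------------------
    planted_arrays: list[tuple[ArraySpec, int, str, list[str]]] = []
    for aspec in spec.arrays:
        repeat = _rand_bases(rng, aspec.repeat_length)
        spacers = []
        for s in range(aspec.n_repeats - 1):
            spacers.append(_rand_bases(rng, aspec.spacer_length))
        embed_idx = None
        if aspec.embed_trna_fragment:
            embed_idx = min(9, len(spacers) - 1)
            source = gene_seqs[aspec.fragment_source_index]
            frag = list(source[-35:-3])  # T-arm + acceptor 3' side, sans CCA
            # a diverged (viral-style) fragment: below the attR mismatch
            # budget so only the CRISPR screen claims it
            for pos in sorted(rng.choice(
                np.arange(2, len(frag) - 2), size=3, replace=False,
            )):
                _i = int(pos)
                frag[_i] = [b for b in "ACGT" if b != frag[_i]][
                    int(rng.integers(3))
                ]
            frag_seq = "".join(frag)
            pad = aspec.spacer_length - len(frag_seq)
            spacers[embed_idx] = frag_seq + _rand_bases(rng, max(0, pad))
        body = repeat + "".join(s + repeat for s in spacers)
        start0 = layout.place(len(body))
        _paste(genome, start0, body)
        planted_arrays.append((aspec, start0, repeat, spacers))

    # ---- integration targets (gene + partial placed jointly) ------------
    integration_targets = {i.target_index for i in spec.integrations}
    gene_pos: dict[int, tuple[int, str]] = {}  # index -> (start0, strand)
    for ispec in spec.integrations:
        gi = ispec.target_index
        seq = gene_seqs[gi]
        glen = len(seq)
        d = ispec.dup_length
        if d >= glen:
            raise ValueError("dup_length must be shorter than the gene")
        strand = "+" if rng.integers(2) else "-"
        placed = False
        for _ in range(2000):
            gstart0 = int(rng.integers(_PAD, spec.genome_length - glen - _PAD))
            gend0 = gstart0 + glen - 1
            if strand == "+":
                pstart0 = gend0 + ispec.element_length + 1
            else:
                pstart0 = gstart0 - ispec.element_length - d
            pend0 = pstart0 + d - 1
            if layout.is_free(gstart0, gend0) and layout.is_free(
                pstart0, pend0
            ):
                layout.reserve(gstart0, gend0)
                layout.reserve(pstart0, pend0)
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place integration geometry; increase genome_length"
            )
        oriented = seq if strand == "+" else reverse_complement(seq)
        _paste(genome, gstart0, oriented)
        gene_pos[gi] = (gstart0, strand)

        # extended image: 3 continuation bases + the duplicated terminal
        ext = seq[-(d + 3):]
        seg = list(ext[3:])
        for pos in (
            sorted(rng.choice(np.arange(3, d - 3), size=ispec.mismatches,
                              replace=False))
            if ispec.mismatches else []
        ):
            _i = int(pos)
            seg[_i] = [b for b in "ACGT" if b != seg[_i]][
                int(rng.integers(3))
            ]
        seg_seq = "".join(seg)
        pstrand = strand if not ispec.invert else (
            "-" if strand == "+" else "+"
        )
        img = seg_seq if pstrand == "+" else reverse_complement(seg_seq)
        _paste(genome, pstart0, img)
        cont = ext[:3]  # bases 5'-ward of the duplicated segment
        for i in range(3):
            forbidden = cont[2 - i]  # nearest continuation base first
            if pstrand == "+":
                _force_differ(genome, pstart0 - 1 - i, forbidden, rng)
            else:
                _force_differ(genome, pend0 + 1 + i, _COMP[forbidden], rng)

        pname = None
        if ispec.predict_partial:
            isotype, anticodon = types[gi]
            pname = f"tRNA-{isotype}-{anticodon}-partial{gi + 1}"
            predictions.append(TRNAGenePrediction(
                genome_id=spec.genome_id, seq_id=spec.seq_id,
                gene_name=pname, start=pstart0 + 1, end=pend0 + 1,
                strand=pstrand, isotype=isotype, anticodon=anticodon,
                general_score=round(float(rng.uniform(20, 40)), 1),
                isotype_score=round(float(rng.uniform(2, 35)), 1),
                pseudo_flag=True, note="pseudo",
            ))
        truth.partials.append(PlantedPartial(
            name=pname, seq_id=spec.seq_id, start=pstart0 + 1,
            end=pend0 + 1, strand=pstrand,
            target_name="",  # filled once gene names exist
            repeat_length=d, mismatches=ispec.mismatches,
            element_length=ispec.element_length, inverted=ispec.invert,
            predicted=ispec.predict_partial,
        ))

    # ---- remaining canonical genes --------------------------------------
    for gi, seq in enumerate(gene_seqs):
        if gi in gene_pos:
            continue
        strand = "+" if rng.integers(2) else "-"
        start0 = layout.place(len(seq))
        oriented = seq if strand == "+" else reverse_complement(seq)
        _paste(genome, start0, oriented)
        gene_pos[gi] = (start0, strand)

    # ---- gene records, masks, predictions -------------------------------
    mask_by_gene = {m.gene_index: m for m in spec.maskings}
    partial_iter = iter(truth.partials)
    for gi, seq in enumerate(gene_seqs):
        isotype, anticodon = types[gi]
        start0, strand = gene_pos[gi]
        glen = len(seq)
        name = f"tRNA-{isotype}-{anticodon}-{gi + 1}-1"
        listed_isotype, listed_anticodon = isotype, anticodon
        if gi in mask_by_gene:
            mspec = mask_by_gene[gi]
            ann = annotate_structure(seq)
            positions = mspec.positions or (ann.anticodon_span[0],)
            genomic = []
            for pos in positions:
                if strand == "+":
                    g0 = start0 + pos - 1
                else:
                    g0 = start0 + glen - pos
                genome[g0] = ord("N")
                genomic.append(g0 + 1)
            seq = "".join(
                "N" if (i + 1) in positions else c
                for i, c in enumerate(seq)
            )
            ac_start = ann.anticodon_span[0]
            listed_anticodon = "".join(
                "N" if (ac_start + k) in positions else anticodon[k]
                for k in range(3)
            )
            listed_isotype = mspec.listed_isotype or isotype
            name = f"tRNA-{listed_isotype}-{listed_anticodon}-{gi + 1}-1"
            truth.masks.append(PlantedMask(
                gene_name=name,
                gene_positions=tuple(positions),
                genomic_positions=tuple(genomic),
                true_isotype=isotype, true_anticodon=anticodon,
                listed_isotype=listed_isotype,
                listed_anticodon=listed_anticodon,
            ))
        truth.genes.append(PlantedGene(
            name=name, seq_id=spec.seq_id, start=start0 + 1,
            end=start0 + glen, strand=strand, isotype=isotype,
            anticodon=anticodon, sequence=seq,
        ))
        predictions.append(TRNAGenePrediction(
            genome_id=spec.genome_id, seq_id=spec.seq_id, gene_name=name,
            start=start0 + 1, end=start0 + glen, strand=strand,
            isotype=listed_isotype, anticodon=listed_anticodon,
            general_score=round(float(rng.uniform(60, 90)), 1),
            isotype_score=round(
                float(np.clip(rng.normal(120, 8), 95, 140)), 1
            ),
        ))
    for partial, ispec in zip(truth.partials, spec.integrations):
        partial.target_name = truth.genes[ispec.target_index].name

    # ---- array truth, boundary disambiguation, fragment predictions -----
    for ai, (aspec, astart0, repeat, spacers) in enumerate(planted_arrays):
        r, s = aspec.repeat_length, aspec.spacer_length
        period = r + s
        repeat_spans = [
            (astart0 + i * period + 1, astart0 + i * period + r)
            for i in range(aspec.n_repeats)
        ]
        spacer_spans = [
            (astart0 + i * period + r + 1, astart0 + (i + 1) * period)
            for i in range(aspec.n_repeats - 1)
        ]
        # make boundary columns non-unanimous so the maximal common repeat
        # is exactly the planted repeat
        for side in ("left", "right"):
            cols = []
            for rs, re_ in repeat_spans:
                pos0 = rs - 2 if side == "left" else re_
                cols.append(pos0)
            bases = {chr(genome[c]) for c in cols}
            if len(bases) == 1:
                _force_differ(genome, cols[0], bases.pop(), rng)
        frag_name = None
        if aspec.embed_trna_fragment:
            embed_idx = min(9, len(spacers) - 1)
            lo_idx = max(0, embed_idx - 3)
            fstart = spacer_spans[lo_idx][0]
            fend = spacer_spans[embed_idx][1]
            frag_name = f"tRNA-Leu-CAA-frag-crispr{ai + 1}"
            predictions.append(TRNAGenePrediction(
                genome_id=spec.genome_id, seq_id=spec.seq_id,
                gene_name=frag_name, start=fstart, end=fend, strand="+",
                isotype="Leu", anticodon="CAA",
                general_score=round(float(rng.uniform(20, 40)), 1),
                isotype_score=round(float(rng.uniform(2, 20)), 1),
                pseudo_flag=True, note="pseudo",
            ))
        truth.arrays.append(PlantedArray(
            seq_id=spec.seq_id, repeat_consensus=repeat,
            repeat_spans=repeat_spans, spacer_spans=spacer_spans,
            fragment_prediction=frag_name,
        ))

    predictions.sort(key=lambda p: (p.seq_id, p.start, p.gene_name))
    genome_str = genome.tobytes().decode()
    return Fixture(
        spec=spec,
        genome={spec.seq_id: genome_str},
        truth=truth,
        predictions=predictions,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, truth JSON, truth BED and the prediction table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "truth_json": outdir / "truth.json",
        "truth_bed": outdir / "truth.bed",
        "predictions": outdir / "predictions.tsv",
    }
    with open(paths["fasta"], "w") as handle:
        for seq_id, seq in fixture.genome.items():
            handle.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i:i + 70] + "\n")
    paths["truth_json"].write_text(fixture.truth.to_json())
    with open(paths["truth_bed"], "w") as handle:
        truth = fixture.truth
        for gene in truth.genes:
            cs, ce = to_bed_interval(gene.start, gene.end)
            handle.write(
                f"{gene.seq_id}\t{cs}\t{ce}\t{gene.name}|canonical\t0\t"
                f"{gene.strand}\n"
            )
        for part in truth.partials:
            cs, ce = to_bed_interval(part.start, part.end)
            name = part.name or f"partial_of_{part.target_name}"
            handle.write(
                f"{part.seq_id}\t{cs}\t{ce}\t{name}|partial\t0\t"
                f"{part.strand}\n"
            )
        for array in truth.arrays:
            start, end = array.repeat_spans[0][0], array.repeat_spans[-1][1]
            cs, ce = to_bed_interval(start, end)
            handle.write(
                f"{array.seq_id}\t{cs}\t{ce}\tcrispr_array\t0\t+\n"
            )
    write_trnascan_output(fixture.predictions, paths["predictions"])
    return paths
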