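"""Readers, writers and the shared data model.

All internal coordinates are 1-based and inclusive on both ends, matching
tRNAscan-SE tabular output and GtRNAdb gene listings.  Conversion to the
0-based half-open convention happens only at BED boundaries, through
:func:`to_bed_interval` / :func:`from_bed_interval`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ISOTYPES",
    "TRNAGenePrediction",
    "StandardSet",
    "normalize_isotype",
    "normalize_sequence",
    "reverse_complement",
    "parse_trnascan_output",
    "write_trnascan_output",
    "load_genome",
    "extract_span",
    "gene_sequence",
    "load_standard_set",
    "write_bed",
    "parse_bed",
    "write_gff3",
    "to_bed_interval",
    "from_bed_interval",
]

AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: Valid isotype vocabulary.  ``iMet`` is the initiator methionine tRNA,
#: ``Met`` the elongator; ``Ile2`` is the CAT-anticodon isoleucine tRNA whose
#: wobble base is post-transcriptionally modified to read AUA.
ISOTYPES = frozenset(AMINO_ACIDS) | {"iMet", "Ile2", "Und", "Sup", "SeC"}

_ISOTYPE_ALIASES = {name.lower(): name for name in ISOTYPES}
_ISOTYPE_ALIASES.update({
    "fmet": "iMet",
    "ini": "iMet",
    "met_i": "iMet",
    "undet": "Und",
    "unknown": "Und",
})

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB"
)


def normalize_isotype(name: str) -> str:
    """Map the various isotype spellings to the canonical vocabulary.

    Accepts GtRNAdb gene-name components (``"iMet"``, ``"fMet"``, ``"Ile2"``)
    as well as plain three-letter amino-acid codes in any case.
    """
    key = name.strip().lower()
    if key in _ISOTYPE_ALIASES:
        return _ISOTYPE_ALIASES[key]
    raise ValueError(f"unknown tRNA isotype: {name!r}")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide sequence and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open (chromStart, chromEnd)."""
    return start - 1, end


def from_bed_interval(chrom_start: int, chrom_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive span."""
    return chrom_start + 1, chrom_end


@dataclass
class TRNAGenePrediction:
    """One predicted tRNA gene, as reported by tRNAscan-SE or GtRNAdb.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    ``start <= end``; the original reading direction is carried by
    ``strand``.  ``isotype_score`` is the tRNAscan-SE isotype-specific
    covariance-model bit score (``None`` when the run did not emit the
    detail columns).
    """

    genome_id: str
    seq_id: str
    gene_name: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    general_score: float | None = None
    isotype_score: float | None = None
    hmm_score: float | None = None
    ss_score: float | None = None
    pseudo_flag: bool = False
    intron_spans: tuple[tuple[int, int], ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_name}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_name}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_name}: strand must be + or -")
        self.isotype = normalize_isotype(self.isotype)
        self.anticodon = normalize_sequence(self.anticodon)
        if len(self.anticodon) != 3 or any(
            c not in "ACGTN" for c in self.anticodon
        ):
            raise ValueError(
                f"{self.gene_name}: anticodon must be 3 chars over ACGTN, "
                f"got {self.anticodon!r}"
            )
        self.intron_spans = tuple(tuple(s) for s in self.intron_spans)

    @property
    def length_bp(self) -> int:
        """Genomic span length (introns included)."""
        return self.end - self.start + 1

    @property
    def type_key(self) -> tuple[str, str]:
        return (self.isotype, self.anticodon)

    def overlaps(self, start: int, end: int) -> int:
        """Overlap in bp with a 1-based inclusive interval."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)


@dataclass(frozen=True)
class StandardSet:
    """A reference tRNA gene-set: expected copy number per (isotype, anticodon).

    The packaged default ``archaea46`` is the standard archaeal complement of
    46 tRNA types, each expected as a single-copy gene.
    """

    name: str
    entries: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for isotype, anticodon, copies in self.entries:
            key = (isotype, anticodon)
            if key in seen:
                raise ValueError(f"duplicate standard-set entry {key}")
            if len(anticodon) != 3:
                raise ValueError(f"anticodon must be 3 characters: {anticodon!r}")
            if copies < 1:
                raise ValueError(f"expected_copies must be positive for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def types(self) -> tuple[tuple[str, str], ...]:
        return tuple((iso, anti) for iso, anti, _ in self.entries)

    def expected_counts(self) -> dict[tuple[str, str], int]:
        return {(iso, anti): n for iso, anti, n in self.entries}


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular output
# ---------------------------------------------------------------------------

_PSEUDO_TOKENS = ("pseudo", "possible pseudogene")

#: Column layout written by :func:`write_trnascan_output`, mirroring
#: ``tRNAscan-SE -H --detail`` tabular output.
_TRNASCAN_COLUMNS = (
    "SequenceName", "tRNA#", "Begin", "End", "Type", "Codon",
    "IntronBegin", "IntronEnd", "InfScore", "HMMScore", "StrScore",
    "IsotypeCM", "IsotypeScore", "Note",
)


def _is_header_line(fields: Sequence[str]) -> bool:
    first = fields[0].strip()
    return (
        first.startswith("-") or first in {"Sequence", "Name", "SequenceName"}
        or (len(fields) > 2 and not _is_int(fields[2]))
        and first != ""
        and fields[1].strip() in {"tRNA", "tRNA#", "Num", ""}
    )


def _is_int(text: str) -> bool:
    try:
        int(text.strip())
        return True
    except ValueError:
        return False


def _opt_float(text: str) -> float | None:
    text = text.strip()
    if text in {"", ".", "NA", "nan"}:
        return None
    return float(text)


def parse_trnascan_output(
    stream: Iterable[str] | str | Path,
    genome_id: str,
) -> tuple[list[TRNAGenePrediction], list[str]]:
    """Parse tRNAscan-SE tabular output into prediction records.

    Header lines are tolerated.  Rows with ``Begin > End`` encode
    minus-strand genes and are normalized to ``start <= end`` with an
    explicit strand.  Pseudogene notes set ``pseudo_flag``.

    Returns ``(predictions, warnings)``.  A missing isotype-score column is
    recorded as a warning and leaves the field ``None``.

    Raises ``ValueError`` naming the line number for malformed rows.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as handle:
            return parse_trnascan_output(handle, genome_id)

    predictions: list[TRNAGenePrediction] = []
    warnings: list[str] = []
    missing_isotype = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if _is_header_line(fields):
            continue
        if len(fields) < 9:
            raise ValueError(
                f"line {lineno}: expected >=9 tab-separated columns, "
                f"got {len(fields)}"
            )
        seq_id = fields[0].strip()
        num = fields[1].strip()
        try:
            begin = int(fields[2])
            end = int(fields[3])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: non-numeric coordinates "
                f"({fields[2]!r}, {fields[3]!r})"
            ) from exc
        if begin <= end:
            start, stop, strand = begin, end, "+"
        else:
            start, stop, strand = end, begin, "-"
        isotype = fields[4].strip()
        anticodon = fields[5].strip() or "NNN"
        try:
            intron_begin = int(fields[6])
            intron_end = int(fields[7])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: non-numeric intron coordinates"
            ) from exc
        introns: tuple[tuple[int, int], ...] = ()
        if intron_begin and intron_end:
            introns = ((min(intron_begin, intron_end),
                        max(intron_begin, intron_end)),)
        try:
            general_score = _opt_float(fields[8])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric score") from exc

        hmm_score = ss_score = isotype_score = None
        isotype_cm = ""
        note = ""
        extra = fields[9:]
        if len(extra) >= 4:
            hmm_score = _opt_float(extra[0])
            ss_score = _opt_float(extra[1])
            isotype_cm = extra[2].strip()
            isotype_score = _opt_float(extra[3])
            note = " ".join(f.strip() for f in extra[4:]).strip()
        elif extra:
            # short (no --detail) format: trailing column is the note
            note = " ".join(f.strip() for f in extra).strip()
            missing_isotype = True
        else:
            missing_isotype = True

        pseudo = any(tok in note.lower() for tok in _PSEUDO_TOKENS)
        name = f"tRNA-{isotype}-{anticodon}-{num or len(predictions) + 1}"
        try:
            pred = TRNAGenePrediction(
                genome_id=genome_id,
                seq_id=seq_id,
                gene_name=name,
                start=start,
                end=stop,
                strand=strand,
                isotype=isotype,
                anticodon=anticodon,
                general_score=general_score,
                isotype_score=isotype_score,
                hmm_score=hmm_score,
                ss_score=ss_score,
                pseudo_flag=pseudo,
                intron_spans=introns,
                note=note,
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        predictions.append(pred)

    if missing_isotype and predictions:
        warnings.append(
            "isotype-score column absent; isotype scores unavailable "
            "(was tRNAscan-SE run without --detail?)"
        )
    if not any(p.pseudo_flag for p in predictions) and all(
        not p.note for p in predictions
    ) and predictions:
        warnings.append(
            "no pseudogene notes present in input; if pseudogene detection "
            "was deactivated, fragment genes may be listed as standard"
        )
    return predictions, warnings


def write_trnascan_output(
    predictions: Sequence[TRNAGenePrediction],
    path_or_handle: str | Path | IO[str],
) -> None:
    """Write predictions in the 14-column tabular layout of ``-H --detail``."""
    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as handle:
            write_trnascan_output(predictions, handle)
        return
    handle = path_or_handle
    handle.write("\t".join(_TRNASCAN_COLUMNS) + "\n")
    handle.write("\t".join("-" * max(4, len(c)) for c in _TRNASCAN_COLUMNS) + "\n")
    for i, p in enumerate(predictions, start=1):
        if p.strand == "+":
            begin, end = p.start, p.end
        else:
            begin, end = p.end, p.start
        intron_b, intron_e = (0, 0)
        if p.intron_spans:
            intron_b, intron_e = p.intron_spans[0]
            if p.strand == "-":
                intron_b, intron_e = intron_e, intron_b
        def fmt(x: float | None) -> str:
            return "" if x is None else f"{x:.1f}"
        note = p.note
        if p.pseudo_flag and not any(
            tok in note.lower() for tok in _PSEUDO_TOKENS
        ):
            note = (note + " pseudo").strip()
        handle.write(
            "\t".join([
                p.seq_id, str(i), str(begin), str(end), p.isotype,
                p.anticodon, str(intron_b), str(intron_e),
                fmt(p.general_score), fmt(p.hmm_score), fmt(p.ss_score),
                p.isotype, fmt(p.isotype_score), note,
            ]) + "\n"
        )


# ---------------------------------------------------------------------------
# FASTA genomes
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a contig-id -> uppercase DNA mapping.

    IUPAC ambiguity codes are kept; lowercase and RNA U are normalized.
    Duplicate contig ids and empty files are errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        genome[record.id] = normalize_sequence(str(record.seq))
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def extract_span(
    genome: Mapping[str, str],
    seq_id: str,
    start: int,
    end: int,
    strand: str = "+",
) -> str:
    """Extract a 1-based inclusive span, reverse-complemented on minus strand."""
    if seq_id not in genome:
        raise KeyError(f"contig {seq_id!r} not in genome")
    contig = genome[seq_id]
    if not (1 <= start <= end <= len(contig)):
        raise ValueError(
            f"span {start}-{end} outside contig {seq_id} (len {len(contig)})"
        )
    segment = contig[start - 1:end]
    return reverse_complement(segment) if strand == "-" else segment


def gene_sequence(
    prediction: TRNAGenePrediction,
    genome: Mapping[str, str],
    splice_introns: bool = True,
) -> str:
    """Oriented (5'->3') gene sequence, introns spliced out by default."""
    seq = extract_span(
        genome, prediction.seq_id, prediction.start, prediction.end,
        prediction.strand,
    )
    if splice_introns and prediction.intron_spans:
        for istart, iend in sorted(prediction.intron_spans, reverse=True):
            if prediction.strand == "+":
                lo = istart - prediction.start
                hi = iend - prediction.start + 1
            else:
                lo = prediction.end - iend
                hi = prediction.end - istart + 1
            seq = seq[:lo] + seq[hi:]
    return seq


# ---------------------------------------------------------------------------
# Standard sets
# ---------------------------------------------------------------------------

def load_standard_set(path: str | Path | None = None) -> StandardSet:
    """Load a standard-set TSV (columns: isotype, anticodon, expected_copies).

    With ``path=None`` the packaged archaeal 46-type single-copy set is
    returned.
    """
    if path is None:
        ref = resources.files("trnacurate.data").joinpath("archaea46.tsv")
        with ref.open() as handle:
            return _read_standard_set(handle, name="archaea46")
    with open(path) as handle:
        return _read_standard_set(handle, name=Path(path).stem)


def _read_standard_set(handle: IO[str], name: str) -> StandardSet:
    entries: list[tuple[str, str, int]] = []
    reader = csv.DictReader(
        (line for line in handle if not line.startswith("#")), delimiter="\t"
    )
    required = {"isotype", "anticodon", "expected_copies"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"standard-set TSV must have columns {sorted(required)}"
        )
    for row in reader:
        entries.append((
            normalize_isotype(row["isotype"]),
            normalize_sequence(row["anticodon"]),
            int(row["expected_copies"]),
        ))
    return StandardSet(name=name, entries=tuple(entries))


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def write_bed(calls: Sequence, path_or_handle: str | Path | IO[str]) -> None:
    """Write curation calls (or predictions) as BED6.

    Name is ``gene_name|category`` when a category is present; score is the
    isotype score clamped to the BED 0-1000 integer range.
    """
    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as handle:
            write_bed(calls, handle)
        return
    handle = path_or_handle
    for call in calls:
        pred = getattr(call, "prediction", call)
        category = getattr(call, "category", None)
        name = pred.gene_name if category is None else f"{pred.gene_name}|{category}"
        score = pred.isotype_score
        bed_score = 0 if score is None else max(0, min(1000, int(round(score))))
        chrom_start, chrom_end = to_bed_interval(pred.start, pred.end)
        handle.write(
            f"{pred.seq_id}\t{chrom_start}\t{chrom_end}\t{name}\t"
            f"{bed_score}\t{pred.strand}\n"
        )


def parse_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file into 1-based inclusive ``(seq_id, start, end, name)``."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            start, end = from_bed_interval(int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 else ""
            intervals.append((fields[0], start, end, name))
    return intervals


def write_gff3(calls: Sequence, path_or_handle: str | Path | IO[str]) -> None:
    """Write curation calls as GFF3 ``tRNA`` features with curation attributes."""
    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as handle:
            write_gff3(calls, handle)
        return
    handle = path_or_handle
    handle.write("##gff-version 3\n")
    for call in calls:
        pred = getattr(call, "prediction", call)
        category = getattr(call, "category", "")
        evidence = getattr(call, "evidence", ())
        attrs = [
            f"ID={pred.gene_name}",
            f"isotype={pred.isotype}",
            f"anticodon={pred.anticodon}",
        ]
        if category:
            attrs.append(f"curation_category={category}")
        if evidence:
            kinds = ",".join(sorted({ev.kind for ev in evidence}))
            attrs.append(f"evidence={kinds}")
        score = "." if pred.isotype_score is None else f"{pred.isotype_score:.1f}"
        handle.write(
            "\t".join([
                pred.seq_id, "trnacurate", "tRNA", str(pred.start),
                str(pred.end), score, pred.strand, ".", ";".join(attrs),
            ]) + "\n"
        )
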