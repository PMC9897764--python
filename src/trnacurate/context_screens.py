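"""Genomic-context evidence for non-canonical tRNA gene calls.

Four screens are provided:

* ``find_attr_pairs`` — integration remnants.  Integration of a mobile
  element (prophage, ICE) into a tRNA gene leaves one complete and one
  partial copy of the target gene at opposing ends of the element, flanked
  by direct repeats (attL/attR).  The screen is anchored on predicted
  genes: terminal segments of prediction pairs are compared, and each
  prediction's terminal window is additionally scanned against the whole
  contig to catch partial copies that the gene finder did not call.
* ``detect_crispr_arrays`` — a minimal periodic direct-repeat finder for
  CRISPR arrays (near-identical 20-50 bp repeats separated by unique
  20-60 bp spacers).  Users may substitute an externally produced array
  track; this is not a CRISPRFinder replacement.
* ``ambiguity_check`` — N (unknown identity) bases inside a gene.
* ``tmrna_overlap`` — intersection with a user-supplied tmRNA track.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .io_formats import (
    TRNAGenePrediction,
    gene_sequence,
    reverse_complement,
)
from .structure_annotator import StructureConfig, annotate_structure

__all__ = [
    "ScreenConfig",
    "RepeatPair",
    "CrisprArray",
    "ContextEvidence",
    "ATTR_PAIR",
    "CRISPR_OVERLAP",
    "AMBIGUOUS_N",
    "TMRNA_OVERLAP",
    "find_attr_pairs",
    "detect_crispr_arrays",
    "crispr_overlap",
    "ambiguity_check",
    "tmrna_overlap",
]

ATTR_PAIR = "ATTR_PAIR"
CRISPR_OVERLAP = "CRISPR_OVERLAP"
AMBIGUOUS_N = "AMBIGUOUS_N"
TMRNA_OVERLAP = "TMRNA_OVERLAP"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the context screens.

    ``max_separation`` of 250 kb accommodates integration events where a
    later rearrangement moved the partial copy far from its full partner
    (observed up to ~179 kb), with headroom.  Element size is reported but
    never filtered on: the integration mechanism is size-agnostic.
    """

    min_repeat_length: int = 20
    max_mismatches: int = 1
    max_separation: int = 250_000
    terminal_window: int = 100
    min_copy_distance: int = 100
    crispr_seed_k: int = 13
    repeat_length_range: tuple[int, int] = (20, 50)
    spacer_length_range: tuple[int, int] = (20, 60)
    min_repeats: int = 3
    max_repeat_copy_mismatches: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("repeat_length_range", "spacer_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GenomicSpan:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatPair:
    """A shared terminal repeat between two tRNA gene copies (attL/attR)."""

    copy_a: GenomicSpan
    copy_b: GenomicSpan
    repeat_length: int
    mismatches: int
    element_span: GenomicSpan | None
    element_length: int
    same_strand: bool


@dataclass(frozen=True)
class CrisprArray:
    """A CRISPR array: near-identical direct repeats with unique spacers."""

    seq_id: str
    repeat_consensus: str
    repeat_length: int
    repeat_spans: tuple[tuple[int, int], ...]
    spacer_spans: tuple[tuple[int, int], ...]
    #: summed substitutions of repeat copies relative to the consensus
    total_copy_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.repeat_spans) != len(self.spacer_spans) + 1:
            raise ValueError("repeats and spacers must alternate")

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_spans)

    @property
    def array_span(self) -> tuple[int, int]:
        return (self.repeat_spans[0][0], self.repeat_spans[-1][1])


@dataclass(frozen=True)
class ContextEvidence:
    """One piece of genomic-context evidence attached to a gene."""

    kind: str
    subject: str  # gene_name
    partner: str | None = None
    payload: object | None = None
    partial_copy: str | None = None  # "subject" | "partner" | "uncertain"
    detail: str = ""
    extra: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        allowed = {ATTR_PAIR, CRISPR_OVERLAP, AMBIGUOUS_N, TMRNA_OVERLAP}
        if self.kind not in allowed:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.payload is not None:
            expected = {
                ATTR_PAIR: RepeatPair,
                CRISPR_OVERLAP: CrisprArray,
                AMBIGUOUS_N: int,
                TMRNA_OVERLAP: tuple,
            }[self.kind]
            if not isinstance(self.payload, expected):
                raise ValueError(
                    f"payload type {type(self.payload).__name__} does not "
                    f"match evidence kind {self.kind}"
                )

    def get(self, key: str, default=None):
        return dict(self.extra).get(key, default)


# ---------------------------------------------------------------------------
# attR pair detection
# ---------------------------------------------------------------------------

def _terminal_match(a: str, b: str, max_mismatches: int,
                    from_3p: bool) -> tuple[int, int]:
    """Maximal shared terminal segment of two oriented sequences.

    Extends inward from the 3' (or 5') termini while the mismatch count
    stays within budget, then trims back so the inner boundary is a match.
    Returns ``(length, mismatches)``.
    """
    limit = min(len(a), len(b))
    mismatch_at: list[bool] = []
    mism = 0
    length = 0
    for i in range(1, limit + 1):
        ca = a[-i] if from_3p else a[i - 1]
        cb = b[-i] if from_3p else b[i - 1]
        hit = ca != cb
        if hit and mism + 1 > max_mismatches:
            break
        mism += hit
        mismatch_at.append(hit)
        length = i
    while length > 0 and mismatch_at[length - 1]:
        mism -= 1
        length -= 1
    return length, mism


def _scan_terminal_window(
    window: str,
    contig: str,
    max_mismatches: int,
    min_length: int,
) -> list[tuple[int, int, int]]:
    """All maximal terminal-anchored matches of ``window`` in ``contig``.

    The window is anchored at its 3' end: a hit at 0-based end position
    ``e`` means ``contig[e-length+1 : e+1]`` matches the last ``length``
    bases of the window, inner boundary trimmed to a match.  Returns
    ``(end_pos0, length, mismatches)`` tuples with length >= min_length.
    """
    w = len(window)
    L = len(contig)
    if L < min_length or w < min_length:
        return []
    # pigeonhole seeding: any hit matches the terminal min_length bases
    # with <= max_mismatches mismatches, so at least one of
    # (max_mismatches + 1) chunks of that tail occurs exactly
    nchunks = max_mismatches + 1
    tail = window[-min_length:]
    chunk = max(1, min_length // nchunks)
    anchors: set[int] = set()
    for ci in range(nchunks):
        lo = ci * chunk
        hi = min_length if ci == nchunks - 1 else (ci + 1) * chunk
        sub = tail[lo:hi]
        offset_from_end = min_length - hi
        pos = contig.find(sub)
        while pos != -1:
            anchor = pos + len(sub) - 1 + offset_from_end
            if anchor < L:
                anchors.add(anchor)
            pos = contig.find(sub, pos + 1)
    hits: list[tuple[int, int, int]] = []
    for anchor in sorted(anchors):
        mism = 0
        length = 0
        marks: list[bool] = []
        max_len = min(w, anchor + 1)
        for i in range(1, max_len + 1):
            differs = contig[anchor - i + 1] != window[w - i]
            if differs and mism + 1 > max_mismatches:
                break
            mism += differs
            marks.append(differs)
            length = i
        while length > 0 and marks[length - 1]:
            mism -= 1
            length -= 1
        if length >= min_length:
            hits.append((anchor, length, mism))
    return hits


def _annotation_rank(seq: str, config: StructureConfig) -> int:
    return annotate_structure(seq, config).located_elements


def _pick_partial(
    pred_a: TRNAGenePrediction,
    pred_b: TRNAGenePrediction,
    genome: Mapping[str, str] | None,
    structure_config: StructureConfig,
) -> str:
    """Decide which copy of a pair is the partial one.

    Fewer located structural elements wins; ties broken by lower isotype
    score; a further tie leaves both flagged uncertain.
    """
    if genome is not None:
        rank_a = _annotation_rank(gene_sequence(pred_a, genome), structure_config)
        rank_b = _annotation_rank(gene_sequence(pred_b, genome), structure_config)
        if rank_a != rank_b:
            return "subject" if rank_a < rank_b else "partner"
    score_a, score_b = pred_a.isotype_score, pred_b.isotype_score
    if score_a is not None and score_b is not None and score_a != score_b:
        return "subject" if score_a < score_b else "partner"
    return "uncertain"


def _pair_evidence(
    pred_a: TRNAGenePrediction,
    pred_b: TRNAGenePrediction,
    pair: RepeatPair,
    partial: str,
) -> list[ContextEvidence]:
    """Emit one evidence per involved prediction."""
    flipped = {"subject": "partner", "partner": "subject",
               "uncertain": "uncertain"}[partial]
    mirrored = RepeatPair(
        copy_a=pair.copy_b, copy_b=pair.copy_a,
        repeat_length=pair.repeat_length, mismatches=pair.mismatches,
        element_span=pair.element_span, element_length=pair.element_length,
        same_strand=pair.same_strand,
    )
    return [
        ContextEvidence(
            kind=ATTR_PAIR, subject=pred_a.gene_name,
            partner=pred_b.gene_name, payload=pair, partial_copy=partial,
            detail=f"shared {pair.repeat_length}-bp terminal repeat "
                   f"({pair.mismatches} mismatch(es)), element "
                   f"~{pair.element_length} bp",
        ),
        ContextEvidence(
            kind=ATTR_PAIR, subject=pred_b.gene_name,
            partner=pred_a.gene_name, payload=mirrored, partial_copy=flipped,
            detail=f"shared {pair.repeat_length}-bp terminal repeat "
                   f"({pair.mismatches} mismatch(es)), element "
                   f"~{pair.element_length} bp",
        ),
    ]


def _compatible(a: TRNAGenePrediction, b: TRNAGenePrediction) -> bool:
    return a.isotype == b.isotype or "Und" in (a.isotype, b.isotype)


def _element_between(
    seq_id: str,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
) -> tuple[GenomicSpan | None, int]:
    """Element span and length between the inner edges of two repeat copies."""
    (a_start, a_end), (b_start, b_end) = sorted([span_a, span_b])
    gap_start, gap_end = a_end + 1, b_start - 1
    if gap_end < gap_start:
        return None, 0
    return GenomicSpan(seq_id, gap_start, gap_end), gap_end - gap_start + 1


def _repeat_genome_span(
    pred: TRNAGenePrediction, length: int, at_3p: bool,
) -> tuple[int, int]:
    """Genomic span of a gene's terminal segment of ``length`` bases."""
    if (pred.strand == "+") == at_3p:
        return (pred.end - length + 1, pred.end)
    return (pred.start, pred.start + length - 1)


def find_attr_pairs(
    predictions: Sequence[TRNAGenePrediction],
    genome: Mapping[str, str] | None,
    config: ScreenConfig | None = None,
    structure_config: StructureConfig | None = None,
) -> list[ContextEvidence]:
    """Detect full/partial tRNA gene pairs flanking an integrated element.

    Pairwise mode compares terminal segments of same-isotype (or Und)
    prediction pairs on a contig; de novo mode scans each prediction's
    terminal window against the contig (both strands) for partial copies
    that were not themselves predicted.  Opposite-strand copies are found
    via reverse-complement comparison.  Two evidences (one per gene) are
    emitted for predicted pairs, one for de novo hits.
    """
    config = config or ScreenConfig()
    structure_config = structure_config or StructureConfig()
    evidences: list[ContextEvidence] = []
    by_contig: dict[str, list[TRNAGenePrediction]] = defaultdict(list)
    for pred in predictions:
        if genome is not None and pred.seq_id not in genome:
            raise KeyError(
                f"{pred.gene_name} references missing contig {pred.seq_id!r}"
            )
        by_contig[pred.seq_id].append(pred)

    for seq_id, preds in by_contig.items():
        preds = sorted(preds, key=lambda p: (p.start, p.gene_name))
        paired_spans: set[tuple[tuple[int, int], tuple[int, int]]] = set()
        # ---- pairwise mode ----
        for i, pa in enumerate(preds):
            for pb in preds[i + 1:]:
                separation = pb.start - pa.end
                if separation > config.max_separation:
                    break
                if not _compatible(pa, pb):
                    continue
                if genome is not None:
                    seq_a = gene_sequence(pa, genome)
                    seq_b = gene_sequence(pb, genome)
                else:
                    continue
                best = None
                for from_3p in (True, False):
                    length, mism = _terminal_match(
                        seq_a, seq_b, config.max_mismatches, from_3p
                    )
                    if length >= config.min_repeat_length and (
                        best is None or length > best[0]
                    ):
                        best = (length, mism, from_3p)
                if best is None:
                    continue
                length, mism, from_3p = best
                span_a = _repeat_genome_span(pa, length, from_3p)
                span_b = _repeat_genome_span(pb, length, from_3p)
                element_span, element_length = _element_between(
                    seq_id, span_a, span_b
                )
                pair = RepeatPair(
                    copy_a=GenomicSpan(seq_id, *span_a, strand=pa.strand),
                    copy_b=GenomicSpan(seq_id, *span_b, strand=pb.strand),
                    repeat_length=length,
                    mismatches=mism,
                    element_span=element_span,
                    element_length=element_length,
                    same_strand=pa.strand == pb.strand,
                )
                partial = _pick_partial(pa, pb, genome, structure_config)
                evidences.extend(_pair_evidence(pa, pb, pair, partial))
                paired_spans.add((span_a, span_b))
                paired_spans.add((span_b, span_a))

        # ---- de novo mode ----
        if genome is None:
            continue
        contig = genome[seq_id]
        rc_contig = reverse_complement(contig)
        L = len(contig)
        for pred in preds:
            seq = gene_sequence(pred, genome)
            window = seq[-min(config.terminal_window, len(seq)):]
            for at_3p in (True, False):
                term = window if at_3p else reverse_complement(
                    seq[:min(config.terminal_window, len(seq))]
                )
                # anchored at the segment's inner-facing genome end; scan
                # forward strand then reverse complement
                for strand, target in (("+", contig), ("-", rc_contig)):
                    hits = _scan_terminal_window(
                        term, target, config.max_mismatches,
                        config.min_repeat_length,
                    )
                    for end0, length, mism in hits:
                        span = _denovo_span(
                            strand, at_3p, end0, length, L
                        )
                        if span is None:
                            continue
                        hstart, hend, hstrand = span
                        ev = _denovo_evidence(
                            pred, preds, seq_id, hstart, hend, hstrand,
                            length, mism, at_3p, config, genome,
                            structure_config, paired_spans,
                        )
                        if ev:
                            evidences.extend(ev)
    return _dedupe_attr(evidences)


def _denovo_span(strand: str, at_3p: bool, end0: int, length: int,
                 L: int) -> tuple[int, int, str] | None:
    """Map a scan hit back to forward-strand 1-based coordinates."""
    if strand == "+":
        start = end0 - length + 2  # 1-based
        end = end0 + 1
        hstrand = "+" if at_3p else "-"
    else:
        # hit on the reverse complement: mirror coordinates
        start = L - end0
        end = L - (end0 - length + 1)
        hstrand = "-" if at_3p else "+"
    if start < 1 or end > L:
        return None
    return start, end, hstrand


def _denovo_evidence(
    pred: TRNAGenePrediction,
    preds: Sequence[TRNAGenePrediction],
    seq_id: str,
    hstart: int,
    hend: int,
    hstrand: str,
    length: int,
    mism: int,
    at_3p: bool,
    config: ScreenConfig,
    genome: Mapping[str, str],
    structure_config: StructureConfig,
    paired_spans: set,
) -> list[ContextEvidence]:
    own_span = _repeat_genome_span(pred, length, at_3p)
    # discard self-hits and anything too close to the source gene
    if min(abs(hstart - pred.end), abs(pred.start - hend)) < \
            config.min_copy_distance and _intersects(
                (hstart, hend), (pred.start - config.min_copy_distance,
                                 pred.end + config.min_copy_distance)):
        return []
    separation = max(0, max(hstart - pred.end, pred.start - hend))
    if separation > config.max_separation:
        return []
    if ((hstart, hend), own_span) in paired_spans or \
            (own_span, (hstart, hend)) in paired_spans:
        return []
    # hit inside another prediction: report as a predicted pair (covers
    # partial copies whose isotype was called differently)
    for other in preds:
        if other is pred:
            continue
        if other.overlaps(hstart, hend) >= length // 2:
            if _compatible(pred, other):
                return []  # pairwise mode already compared these
            element_span, element_length = _element_between(
                seq_id, own_span, (hstart, hend)
            )
            pair = RepeatPair(
                copy_a=GenomicSpan(seq_id, *own_span, strand=pred.strand),
                copy_b=GenomicSpan(seq_id, hstart, hend, strand=hstrand),
                repeat_length=length, mismatches=mism,
                element_span=element_span, element_length=element_length,
                same_strand=pred.strand == hstrand,
            )
            partial = _pick_partial(pred, other, genome, structure_config)
            return _pair_evidence(pred, other, pair, partial)
    element_span, element_length = _element_between(
        seq_id, own_span, (hstart, hend)
    )
    pair = RepeatPair(
        copy_a=GenomicSpan(seq_id, *own_span, strand=pred.strand),
        copy_b=GenomicSpan(seq_id, hstart, hend, strand=hstrand),
        repeat_length=length, mismatches=mism,
        element_span=element_span, element_length=element_length,
        same_strand=pred.strand == hstrand,
    )
    return [ContextEvidence(
        kind=ATTR_PAIR, subject=pred.gene_name, partner=None, payload=pair,
        partial_copy="partner",
        detail=f"unannotated partial copy at {seq_id}:{hstart}-{hend}"
               f"({hstrand}), {length}-bp repeat, {mism} mismatch(es)",
    )]


def _intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _dedupe_attr(evidences: list[ContextEvidence]) -> list[ContextEvidence]:
    seen = set()
    out = []
    for ev in evidences:
        if ev.kind != ATTR_PAIR:
            out.append(ev)
            continue
        pair: RepeatPair = ev.payload  # type: ignore[assignment]
        key = (
            ev.subject, ev.partner,
            (pair.copy_a.start, pair.copy_a.end),
            (pair.copy_b.start, pair.copy_b.end),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# CRISPR array detection
# ---------------------------------------------------------------------------

def detect_crispr_arrays(
    genome: Mapping[str, str],
    config: ScreenConfig | None = None,
) -> list[CrisprArray]:
    """Find arrays of near-identical direct repeats with admissible spacers.

    Seeding uses exact k-mers whose occurrences recur at period
    ``repeat + spacer``; chains are extended to the maximal unanimous
    repeat length.  A repeat copy carrying up to
    ``max_repeat_copy_mismatches`` substitutions (which breaks the exact
    seed chain) is recovered by scanning over-long gaps for a near-match of
    the consensus.
    """
    config = config or ScreenConfig()
    arrays: list[CrisprArray] = []
    for seq_id, seq in genome.items():
        arrays.extend(_detect_on_contig(seq_id, seq, config))
    return arrays


def _detect_on_contig(seq_id: str, seq: str,
                      config: ScreenConfig) -> list[CrisprArray]:
    k = config.crispr_seed_k
    rep_lo, rep_hi = config.repeat_length_range
    sp_lo, sp_hi = config.spacer_length_range
    min_period = rep_lo + sp_lo
    max_period = rep_hi + sp_hi
    n = len(seq)
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        positions[seq[i:i + k]].append(i)

    candidates: dict[frozenset, CrisprArray] = {}
    for kmer, pos in positions.items():
        if len(pos) < config.min_repeats or "N" in kmer:
            continue
        for chain in _chains(pos, min_period, max_period,
                             config.min_repeats,
                             config.max_repeat_copy_mismatches):
            array = _extend_chain(seq, chain, k, config)
            if array is None:
                continue
            key = frozenset(array)
            if key not in candidates:
                built = _build_array(seq_id, seq, array, config)
                if built is not None:
                    candidates[key] = built
    return _merge_arrays(list(candidates.values()))


def _chains(pos: list[int], min_period: int, max_period: int,
            min_repeats: int, copy_tolerance: int = 0) -> list[list[int]]:
    # a copy mutated inside the seed k-mer drops out of the exact-match
    # chain; allow gaps spanning up to copy_tolerance skipped periods and
    # recover the copy later against the consensus
    allowed = [
        (m * min_period, m * max_period) for m in range(1, copy_tolerance + 2)
    ]
    chains: list[list[int]] = []
    current = [pos[0]]
    for p in pos[1:]:
        gap = p - current[-1]
        if any(lo <= gap <= hi for lo, hi in allowed):
            current.append(p)
        else:
            if len(current) >= min_repeats:
                chains.append(current)
            current = [p]
    if len(current) >= min_repeats:
        chains.append(current)
    return chains


def _extend_chain(seq: str, chain: list[int], k: int,
                  config: ScreenConfig) -> list[tuple[int, int]] | None:
    """Extend k-mer anchors to the maximal unanimous common repeat."""
    rep_lo, rep_hi = config.repeat_length_range
    sp_lo, _ = config.spacer_length_range
    n = len(seq)
    left = 0
    while True:
        d = left + 1
        if chain[0] - d < 0 or k + d > rep_hi:
            break
        column = {seq[p - d] for p in chain}
        if len(column) != 1 or "N" in column:
            break
        # keep spacers above their minimum length
        if any((chain[i + 1] - d) - (chain[i] + k) < sp_lo
               for i in range(len(chain) - 1)):
            break
        left = d
    right = 0
    while True:
        d = right + 1
        if chain[-1] + k - 1 + d >= n or k + left + d > rep_hi:
            break
        column = {seq[p + k - 1 + d] for p in chain}
        if len(column) != 1 or "N" in column:
            break
        if any((chain[i + 1] - left) - (chain[i] + k + d) < sp_lo
               for i in range(len(chain) - 1)):
            break
        right = d
    length = k + left + right
    if length < rep_lo:
        return None
    return [(p - left, p + k - 1 + right) for p in chain]


def _build_array(seq_id: str, seq: str, spans: list[tuple[int, int]],
                 config: ScreenConfig) -> CrisprArray | None:
    sp_lo, sp_hi = config.spacer_length_range
    consensus = seq[spans[0][0]:spans[0][1] + 1]
    # recover repeat copies that exact seeding missed (mismatched copies)
    if config.max_repeat_copy_mismatches > 0:
        spans = _insert_mismatched_copies(seq, spans, consensus, config)
    spacers = []
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        length = s1 - e0 - 1
        if not sp_lo <= length <= sp_hi:
            return None
        spacers.append((e0 + 2, s1))  # 1-based inclusive
    if len(spans) < config.min_repeats:
        return None
    total_mism = sum(
        sum(seq[s + i] != consensus[i] for i in range(len(consensus)))
        for s, _ in spans
    )
    return CrisprArray(
        seq_id=seq_id,
        repeat_consensus=consensus,
        repeat_length=len(consensus),
        repeat_spans=tuple((s + 1, e + 1) for s, e in spans),
        spacer_spans=tuple(spacers),
        total_copy_mismatches=total_mism,
    )


def _insert_mismatched_copies(
    seq: str, spans: list[tuple[int, int]], consensus: str,
    config: ScreenConfig,
) -> list[tuple[int, int]]:
    sp_lo, sp_hi = config.spacer_length_range
    r = len(consensus)
    out = list(spans)
    changed = True
    while changed:
        changed = False
        for (s0, e0), (s1, _) in zip(out, out[1:]):
            gap = s1 - e0 - 1
            if gap <= sp_hi:
                continue
            lo = e0 + 1 + sp_lo
            hi = s1 - sp_lo - r
            best = None
            for start in range(lo, hi + 1):
                mism = sum(
                    seq[start + i] != consensus[i] for i in range(r)
                )
                if mism <= config.max_repeat_copy_mismatches and (
                    best is None or mism < best[1]
                ):
                    best = (start, mism)
            if best is not None:
                start = best[0]
                out.append((start, start + r - 1))
                out.sort()
                changed = True
                break
    return out


def _merge_arrays(arrays: list[CrisprArray]) -> list[CrisprArray]:
    # prefer more repeats, then exact (mismatch-free) copies: a chain that
    # drops one copy and over-extends into its flank produces a longer but
    # mismatched variant of the same array
    arrays = sorted(
        arrays,
        key=lambda a: (-a.n_repeats, a.total_copy_mismatches, a.array_span),
    )
    kept: list[CrisprArray] = []
    for array in arrays:
        span = array.array_span
        if any(
            a.seq_id == array.seq_id and _intersects(span, a.array_span)
            for a in kept
        ):
            continue
        kept.append(array)
    return sorted(kept, key=lambda a: (a.seq_id, a.array_span))


def crispr_overlap(
    predictions: Sequence[TRNAGenePrediction],
    arrays: Sequence[CrisprArray],
) -> list[ContextEvidence]:
    """Evidence for every prediction intersecting an array span by >= 1 bp."""
    evidences = []
    for pred in predictions:
        for array in arrays:
            if array.seq_id != pred.seq_id:
                continue
            if pred.overlaps(*array.array_span) < 1:
                continue
            covered_spacers = [
                i + 1 for i, span in enumerate(array.spacer_spans)
                if pred.overlaps(*span) >= 1
            ]
            covered_repeats = [
                i + 1 for i, span in enumerate(array.repeat_spans)
                if pred.overlaps(*span) >= 1
            ]
            evidences.append(ContextEvidence(
                kind=CRISPR_OVERLAP,
                subject=pred.gene_name,
                payload=array,
                detail=f"inside CRISPR array "
                       f"{array.seq_id}:{array.array_span[0]}-"
                       f"{array.array_span[1]}; covers "
                       f"{len(covered_spacers)} spacer(s), "
                       f"{len(covered_repeats)} repeat(s)",
                extra=(
                    ("covered_spacers", tuple(covered_spacers)),
                    ("covered_repeats", tuple(covered_repeats)),
                ),
            ))
    return evidences


# ---------------------------------------------------------------------------
# N ambiguity and tmRNA overlap
# ---------------------------------------------------------------------------

def ambiguity_check(
    prediction: TRNAGenePrediction,
    genome: Mapping[str, str] | None,
    annotation=None,
) -> ContextEvidence | None:
    """Evidence when the gene sequence (or listed anticodon) contains Ns."""
    n_count = 0
    n_in_anticodon = "N" in prediction.anticodon
    if genome is not None:
        seq = gene_sequence(prediction, genome)
        n_count = seq.count("N")
        if annotation is not None and annotation.anticodon:
            n_in_anticodon = n_in_anticodon or "N" in annotation.anticodon
    else:
        n_count = prediction.anticodon.count("N")
    if n_count == 0 and not n_in_anticodon:
        return None
    return ContextEvidence(
        kind=AMBIGUOUS_N,
        subject=prediction.gene_name,
        payload=max(n_count, prediction.anticodon.count("N")),
        detail=f"{n_count} ambiguous base(s); "
               f"anticodon {'contains' if n_in_anticodon else 'free of'} N",
        extra=(("n_in_anticodon", n_in_anticodon),),
    )


def tmrna_overlap(
    predictions: Sequence[TRNAGenePrediction],
    track: Sequence[tuple[str, int, int, str]],
) -> list[ContextEvidence]:
    """Evidence per prediction intersecting a tmRNA track interval.

    ``track`` holds 1-based inclusive ``(seq_id, start, end, name)`` rows,
    e.g. from :func:`trnacurate.io_formats.parse_bed`.
    """
    evidences = []
    for pred in predictions:
        for seq_id, start, end, name in track:
            if seq_id != pred.seq_id:
                continue
            overlap = pred.overlaps(start, end)
            if overlap < 1:
                continue
            evidences.append(ContextEvidence(
                kind=TMRNA_OVERLAP,
                subject=pred.gene_name,
                partner=name or None,
                payload=(seq_id, start, end),
                detail=f"overlaps tmRNA interval {seq_id}:{start}-{end} "
                       f"by {overlap} bp",
                extra=(("overlap_bp", overlap),),
            ))
    return evidences
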