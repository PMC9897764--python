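"""Per-gene triage: combine scores, structure, flags and context evidence.

The final verdict per predicted gene is one of:

* ``CANONICAL`` — structurally complete, no disqualifying context;
* ``FRAGMENT_CRISPR`` — lies within a CRISPR array (a spacer-borne tRNA
  gene fragment);
* ``FRAGMENT_ATTR`` — the partial member of a full/partial gene pair
  flanking an integrated element;
* ``MISASSIGNED_AMBIGUOUS`` — an N-containing gene rescued to the unique
  missing standard type it is compatible with;
* ``NONCANONICAL_OTHER`` — tmRNA overlap, very low isotype score, or
  structural defects without a specific mechanism;
* ``LEGITIMATE_DUPLICATE`` — a clean extra copy of an already-satisfied
  standard type (e.g. a tRNA gene inside a duplicated rrn operon);
* ``UNCERTAIN`` — reserved for genes no rule can settle.

Isotype-score decision bands default to <60 likely non-canonical, 60-90
uncertain, >90 likely canonical.  A separate <85 "low score" reporting
flag is emitted on every call; it marks genes deserving manual scrutiny
and is distinct from the decision bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import yaml

from .context_screens import (
    AMBIGUOUS_N,
    ATTR_PAIR,
    CRISPR_OVERLAP,
    TMRNA_OVERLAP,
    ContextEvidence,
    ScreenConfig,
    ambiguity_check,
    crispr_overlap,
    detect_crispr_arrays,
    find_attr_pairs,
    tmrna_overlap,
)
from .io_formats import StandardSet, TRNAGenePrediction, gene_sequence
from .structure_annotator import (
    Defect,
    StructuralAnnotation,
    StructureConfig,
    annotate_structure,
)

__all__ = [
    "TriageConfig",
    "CurationCall",
    "LIKELY_NONCANONICAL",
    "UNCERTAIN_BAND",
    "LIKELY_CANONICAL",
    "CATEGORIES",
    "score_band",
    "resolve_ambiguous",
    "classify",
    "curate_geneset",
    "curate_batch",
    "write_curation_table",
]

LIKELY_NONCANONICAL = "LIKELY_NONCANONICAL"
UNCERTAIN_BAND = "UNCERTAIN"
LIKELY_CANONICAL = "LIKELY_CANONICAL"

CANONICAL = "CANONICAL"
FRAGMENT_ATTR = "FRAGMENT_ATTR"
FRAGMENT_CRISPR = "FRAGMENT_CRISPR"
MISASSIGNED_AMBIGUOUS = "MISASSIGNED_AMBIGUOUS"
NONCANONICAL_OTHER = "NONCANONICAL_OTHER"
LEGITIMATE_DUPLICATE = "LEGITIMATE_DUPLICATE"
UNCERTAIN = "UNCERTAIN"

CATEGORIES = (
    CANONICAL, FRAGMENT_ATTR, FRAGMENT_CRISPR, MISASSIGNED_AMBIGUOUS,
    NONCANONICAL_OTHER, LEGITIMATE_DUPLICATE, UNCERTAIN,
)

#: Categories whose genes count toward the curated canonical gene set.
CANONICAL_CATEGORIES = (CANONICAL, LEGITIMATE_DUPLICATE)
#: Categories excluded from the curated set (fragments & other artefacts).
NONCANONICAL_CATEGORIES = (
    FRAGMENT_ATTR, FRAGMENT_CRISPR, NONCANONICAL_OTHER,
)


@dataclass(frozen=True)
class TriageConfig:
    band_low: float = 60.0
    band_high: float = 90.0
    low_flag: float = 85.0
    honor_pseudo_flag: bool = True

    def __post_init__(self) -> None:
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriageConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)


@dataclass
class CurationCall:
    """Final per-gene verdict with its supporting evidence."""

    prediction: TRNAGenePrediction
    band: str
    category: str
    reassigned_to: tuple[str, str] | None = None
    evidence: list[ContextEvidence] = field(default_factory=list)
    defects: list[Defect] = field(default_factory=list)
    rationale: str = ""
    low_score_flag: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category == MISASSIGNED_AMBIGUOUS and not self.reassigned_to:
            raise ValueError(
                f"{self.prediction.gene_name}: MISASSIGNED_AMBIGUOUS "
                "requires reassigned_to"
            )
        required = {FRAGMENT_ATTR: ATTR_PAIR, FRAGMENT_CRISPR: CRISPR_OVERLAP}
        kind = required.get(self.category)
        if kind and not any(ev.kind == kind for ev in self.evidence):
            raise ValueError(
                f"{self.prediction.gene_name}: category {self.category} "
                f"requires {kind} evidence"
            )

    @property
    def effective_type(self) -> tuple[str, str]:
        """Type under which the gene counts in curated mode."""
        if self.reassigned_to:
            return self.reassigned_to
        return self.prediction.type_key


def score_band(
    isotype_score: float | None,
    config: TriageConfig | None = None,
) -> tuple[str, str | None]:
    """Band an isotype score; an absent score is UNCERTAIN with a warning."""
    config = config or TriageConfig()
    if isotype_score is None:
        return UNCERTAIN_BAND, "isotype score absent; banded as uncertain"
    if isotype_score < config.band_low:
        return LIKELY_NONCANONICAL, None
    if isotype_score <= config.band_high:
        return UNCERTAIN_BAND, None
    return LIKELY_CANONICAL, None


def resolve_ambiguous(
    prediction: TRNAGenePrediction,
    annotation: StructuralAnnotation | None,
    deficit: Sequence[tuple[str, str]],
) -> tuple[str, str] | None:
    """Rescue an N-containing gene to the unique missing standard type.

    The observed anticodon must match the candidate's at every non-N
    position, and the isotypes must agree when the prediction's isotype is
    determined (not Und).  Returns ``None`` when zero or multiple standard
    types match, or when the gene has fatal structural defects.
    """
    anticodon = prediction.anticodon
    has_n = "N" in anticodon or (
        prediction.isotype == "Und" and annotation is not None
        and annotation.n_count > 0
    )
    if not has_n:
        return None
    if annotation is not None and annotation.fatal_defects:
        return None
    matches = []
    for isotype, candidate in deficit:
        if prediction.isotype != "Und" and prediction.isotype != isotype:
            continue
        if all(o == "N" or o == c for o, c in zip(anticodon, candidate)):
            matches.append((isotype, candidate))
    if len(matches) == 1:
        return matches[0]
    return None


def classify(
    prediction: TRNAGenePrediction,
    annotation: StructuralAnnotation | None,
    evidence: Sequence[ContextEvidence],
    config: TriageConfig | None = None,
    deficit: Sequence[tuple[str, str]] = (),
    type_satisfied: bool = False,
) -> CurationCall:
    """Assign the final category for one gene.

    Precedence: CRISPR overlap, then attR partial-copy evidence, then
    ambiguity rescue, then tmRNA overlap, then score band combined with
    structural defects and the pseudogene flag.  Context evidence outranks
    scores because mechanistic evidence is more specific than a low score.
    """
    config = config or TriageConfig()
    for ev in evidence:
        if ev.subject != prediction.gene_name:
            raise ValueError(
                f"evidence for {ev.subject!r} attached to "
                f"{prediction.gene_name!r}"
            )
    band, band_warning = score_band(prediction.isotype_score, config)
    warnings = [band_warning] if band_warning else []
    defects = list(annotation.defects) if annotation else []
    fatal = bool(annotation.fatal_defects) if annotation else False
    low_flag = (
        prediction.isotype_score is not None
        and prediction.isotype_score < config.low_flag
    )

    def call(category: str, rationale: str,
             reassigned: tuple[str, str] | None = None) -> CurationCall:
        return CurationCall(
            prediction=prediction, band=band, category=category,
            reassigned_to=reassigned, evidence=list(evidence),
            defects=defects, rationale=rationale,
            low_score_flag=low_flag, warnings=warnings,
        )

    crispr = [ev for ev in evidence if ev.kind == CRISPR_OVERLAP]
    if crispr:
        return call(
            FRAGMENT_CRISPR,
            "prediction lies within a CRISPR array; spacer-borne tRNA gene "
            "fragment",
        )
    attr_partial = [
        ev for ev in evidence
        if ev.kind == ATTR_PAIR and ev.partial_copy in ("subject", "uncertain")
    ]
    if attr_partial:
        return call(
            FRAGMENT_ATTR,
            "partial member of a full/partial tRNA gene pair flanking an "
            "integrated element (attR remnant)",
        )
    reassigned = resolve_ambiguous(prediction, annotation, deficit)
    if reassigned is not None and any(
        ev.kind == AMBIGUOUS_N for ev in evidence
    ):
        iso, anti = reassigned
        return call(
            MISASSIGNED_AMBIGUOUS,
            f"ambiguous (N) bases misled isotype assignment; gene matches "
            f"the missing standard type {iso}-{anti}",
            reassigned=(iso, anti),
        )
    if any(ev.kind == TMRNA_OVERLAP for ev in evidence):
        return call(
            NONCANONICAL_OTHER,
            "overlaps an annotated tmRNA gene; tRNA-like features belong "
            "to the tmRNA",
        )
    if band == LIKELY_NONCANONICAL:
        return call(
            NONCANONICAL_OTHER,
            f"isotype score {prediction.isotype_score} below "
            f"{config.band_low}; likely non-canonical",
        )
    if config.honor_pseudo_flag and prediction.pseudo_flag and fatal:
        return call(
            NONCANONICAL_OTHER,
            "flagged as possible pseudogene and structurally defective",
        )
    if band == UNCERTAIN_BAND:
        if fatal:
            codes = sorted({d.code for d in defects if d.severity == "fatal"})
            return call(
                NONCANONICAL_OTHER,
                f"borderline isotype score with fatal structural defects "
                f"({', '.join(codes)})",
            )
        if type_satisfied:
            return call(
                LEGITIMATE_DUPLICATE,
                "clean additional copy of an already-satisfied standard type",
            )
        return call(
            CANONICAL,
            "borderline isotype score but structurally complete; manual "
            "review recommended",
        )
    if fatal:
        codes = sorted({d.code for d in defects if d.severity == "fatal"})
        return call(
            NONCANONICAL_OTHER,
            f"fatal structural defects ({', '.join(codes)}) despite "
            "high isotype score",
        )
    if type_satisfied:
        return call(
            LEGITIMATE_DUPLICATE,
            "clean additional copy of an already-satisfied standard type",
        )
    return call(CANONICAL, "structurally complete canonical tRNA gene")


def curate_geneset(
    predictions: Sequence[TRNAGenePrediction],
    genome: Mapping[str, str] | None = None,
    standard: StandardSet | None = None,
    structure_config: StructureConfig | None = None,
    screen_config: ScreenConfig | None = None,
    triage_config: TriageConfig | None = None,
    extra_evidence: Mapping[str, Sequence[ContextEvidence]] | None = None,
    tmrna_track: Sequence[tuple[str, int, int, str]] = (),
) -> list[CurationCall]:
    """Curate one genome's predicted tRNA gene set end to end.

    With a genome, structure annotation and all context screens run; in
    listing-only mode (``genome=None``) structural and screen evidence must
    be supplied through ``extra_evidence``.  Classification is two-pass:
    the per-genome deficit of missing standard types is computed from the
    confidently canonical first-pass calls, then N-ambiguous genes are
    rescued against that deficit.
    """
    structure_config = structure_config or StructureConfig()
    screen_config = screen_config or ScreenConfig()
    triage_config = triage_config or TriageConfig()
    genome_ids = {p.genome_id for p in predictions}
    if len(genome_ids) > 1:
        raise ValueError(
            f"curate_geneset expects one genome, got {sorted(genome_ids)}; "
            "use curate_batch"
        )
    preds = sorted(predictions, key=lambda p: (p.seq_id, p.start, p.gene_name))

    annotations: dict[str, StructuralAnnotation | None] = {}
    evidence: dict[str, list[ContextEvidence]] = {p.gene_name: [] for p in preds}
    if genome is not None:
        for pred in preds:
            annotations[pred.gene_name] = annotate_structure(
                gene_sequence(pred, genome), structure_config
            )
        for ev in find_attr_pairs(preds, genome, screen_config,
                                  structure_config):
            evidence[ev.subject].append(ev)
        arrays = detect_crispr_arrays(genome, screen_config)
        for ev in crispr_overlap(preds, arrays):
            evidence[ev.subject].append(ev)
        for pred in preds:
            ev = ambiguity_check(pred, genome, annotations[pred.gene_name])
            if ev is not None:
                evidence[pred.gene_name].append(ev)
    else:
        for pred in preds:
            annotations[pred.gene_name] = None
            ev = ambiguity_check(pred, None)
            if ev is not None:
                evidence[pred.gene_name].append(ev)
    for ev in tmrna_overlap(preds, tmrna_track):
        evidence[ev.subject].append(ev)
    if extra_evidence:
        for name, evs in extra_evidence.items():
            evidence.setdefault(name, []).extend(evs)

    # pass 1: classify without rescue to establish the canonical backbone
    first_pass = [
        classify(p, annotations[p.gene_name], evidence[p.gene_name],
                 triage_config, deficit=())
        for p in preds
    ]
    expected = standard.expected_counts() if standard else {}
    satisfied: dict[tuple[str, str], int] = {}
    for call in first_pass:
        if call.category in CANONICAL_CATEGORIES and \
                "N" not in call.prediction.anticodon:
            key = call.prediction.type_key
            satisfied[key] = satisfied.get(key, 0) + 1
    deficit = [
        key for key, want in expected.items()
        if satisfied.get(key, 0) < want
    ]

    # pass 2: rescue against the deficit
    calls = [
        classify(p, annotations[p.gene_name], evidence[p.gene_name],
                 triage_config, deficit=deficit)
        for p in preds
    ]

    # mark surplus canonical copies of satisfied types as duplicates
    if expected:
        counts: dict[tuple[str, str], int] = {}
        for idx, call in enumerate(calls):
            if call.category != CANONICAL:
                continue
            key = call.effective_type
            counts[key] = counts.get(key, 0) + 1
            if counts[key] > expected.get(key, 0) >= 1:
                calls[idx] = replace(
                    call, category=LEGITIMATE_DUPLICATE,
                    rationale="clean additional copy of an already-"
                              "satisfied standard type",
                )
    return calls


def curate_batch(
    listings: Mapping[str, Sequence[TRNAGenePrediction]],
    genomes: Mapping[str, Mapping[str, str]] | None = None,
    standard: StandardSet | None = None,
    extra_evidence: Mapping[str, Mapping[str, Sequence[ContextEvidence]]]
        | None = None,
    **kwargs,
) -> dict[str, list[CurationCall]]:
    """Curate several genomes; returns calls keyed by genome id."""
    out: dict[str, list[CurationCall]] = {}
    for genome_id, preds in listings.items():
        genome = genomes.get(genome_id) if genomes else None
        extra = extra_evidence.get(genome_id) if extra_evidence else None
        out[genome_id] = curate_geneset(
            preds, genome=genome, standard=standard,
            extra_evidence=extra, **kwargs,
        )
    return out


_TABLE_COLUMNS = (
    "genome_id", "seq_id", "gene_name", "start", "end", "strand", "isotype",
    "anticodon", "isotype_score", "pseudo_flag", "band", "category",
    "low_score_flag", "reassigned_to", "evidence", "defects", "rationale",
)


def write_curation_table(
    calls: Sequence[CurationCall],
    path_or_handle: str | Path | IO[str],
) -> None:
    """One TSV row per gene: band, category, evidence summary, rationale."""
    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as handle:
            write_curation_table(calls, handle)
        return
    handle = path_or_handle
    handle.write("\t".join(_TABLE_COLUMNS) + "\n")
    for call in calls:
        p = call.prediction
        reassigned = (
            "-".join(call.reassigned_to) if call.reassigned_to else ""
        )
        ev_summary = ";".join(
            ev.kind + (f"->{ev.partner}" if ev.partner else "")
            for ev in call.evidence
        )
        defect_summary = ";".join(
            f"{d.code}({d.severity})" for d in call.defects
        )
        handle.write("\t".join([
            p.genome_id, p.seq_id, p.gene_name, str(p.start), str(p.end),
            p.strand, p.isotype, p.anticodon,
            "" if p.isotype_score is None else f"{p.isotype_score:.1f}",
            str(p.pseudo_flag), call.band, call.category,
            str(call.low_score_flag), reassigned, ev_summary,
            defect_summary, call.rationale,
        ]) + "\n")
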