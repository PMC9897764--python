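"""Rule-based annotation of tRNA cloverleaf structure from primary sequence.

The annotator locates the seven canonical structural elements of a tRNA gene
in a fixed order, each anchored relative to the previously found element:

1. the 3' CCA terminus (when genomically encoded), the discriminator base
   (position 73) and the acceptor stem (positions 1-7 pairing with 72-66);
2. the T-arm (stem-loop with loop consensus TTCRANN) 5' of the acceptor
   3' side;
3. the variable region between T-arm and anticodon arm (4-5 nt, or a long
   extra arm in Ser/Leu tRNAs);
4. the anticodon arm (5-bp stem, 7-nt loop, anticodon at loop positions
   34-36, loop typically starting 5'-CT);
5. the D-arm (3-4-bp stem with a flexible 4-12-nt loop);
6. the connector nucleotides 8-9 and 26.

Positions use the simplified Sprinzl-style numbering (1-76 for a 76-nt
tRNA); genes with long variable arms shift absolute indices, so element
*order*, not absolute index, is authoritative.  Each element that cannot be
located contributes a defect; a gene is considered structurally canonical
iff it has no fatal defect.  N bases match anything but are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_formats import normalize_sequence

__all__ = [
    "StructureConfig",
    "Defect",
    "StructuralAnnotation",
    "find_t_arm",
    "annotate_structure",
    "is_canonical_structure",
    "base_pairs",
]

Span = tuple[int, int]  # 1-based inclusive

#: Watson-Crick pairs plus the G:T wobble accepted in all stems.
_WC_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class StructureConfig:
    """Tunable thresholds of the structural rule engine.

    The acceptor-stem tolerance of one mispair reflects that a single
    acceptor mispair (a point mutation or sequencing error) does not by
    itself disqualify an otherwise complete gene.
    """

    acceptor_mismatch_tolerance: int = 1
    t_stem_mismatch_tolerance: int = 0
    anticodon_stem_mismatch_tolerance: int = 0
    d_stem_mismatch_tolerance: int = 0
    d_stem_lengths: tuple[int, ...] = (4, 3)
    d_loop_range: tuple[int, int] = (4, 12)
    variable_gaps: tuple[int, ...] = (5, 4)
    extra_arm_gap: tuple[int, int] = (10, 24)
    connector_gaps: tuple[int, ...] = (2, 3)
    min_gene_length: int = 50
    allow_wobble: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StructureConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("d_stem_lengths", "variable_gaps", "connector_gaps",
                    "d_loop_range", "extra_arm_gap"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class Defect:
    """One structural defect.  ``fatal`` defects disqualify canonicity."""

    code: str
    severity: str  # "fatal" | "warning"
    detail: str = ""


FATAL = "fatal"
WARNING = "warning"


def base_pairs(a: str, b: str, allow_wobble: bool = True) -> bool:
    """Whether two bases can pair in a stem (WC, optional G:T wobble, N wild)."""
    if "N" in (a, b):
        return True
    if (a, b) in _WC_PAIRS:
        return True
    return allow_wobble and (a, b) in _WOBBLE_PAIRS


def _stem_mismatches(seq: str, left: int, right: int, length: int,
                     allow_wobble: bool) -> int:
    """Mispair count for a stem pairing seq[left..] with seq[..right] inward.

    ``left`` is the 0-based start of the 5' side; ``right`` the 0-based end
    (inclusive) of the 3' side.
    """
    return sum(
        not base_pairs(seq[left + i], seq[right - i], allow_wobble)
        for i in range(length)
    )


def _matches(base: str, allowed: str) -> bool:
    return base == "N" or base in allowed


def _t_loop_ok(loop: str) -> bool:
    # consensus TTCRANN
    return (
        _matches(loop[0], "T") and _matches(loop[1], "T")
        and _matches(loop[2], "C") and _matches(loop[3], "AG")
        and _matches(loop[4], "A")
    )


def find_t_arm(
    seq: str,
    config: StructureConfig | None = None,
    search_end: int | None = None,
) -> Span | None:
    """Locate the T-arm: a 17-nt stem-loop whose 7-nt loop matches TTCRANN.

    Returns the 1-based inclusive span of the rightmost (3'-most) matching
    window, or ``None``.  ``search_end`` restricts the window to end at or
    before that 0-based exclusive limit (used to keep the T-arm 5' of the
    acceptor-stem 3' side, i.e. "prior to position 66").
    """
    config = config or StructureConfig()
    seq = normalize_sequence(seq)
    limit = len(seq) if search_end is None else min(search_end, len(seq))
    for start in range(limit - 17, -1, -1):
        loop = seq[start + 5:start + 12]
        if not _t_loop_ok(loop):
            continue
        mism = _stem_mismatches(seq, start, start + 16, 5, config.allow_wobble)
        if mism <= config.t_stem_mismatch_tolerance:
            return (start + 1, start + 17)
    return None


@dataclass
class StructuralAnnotation:
    """Located structural elements plus the defect list for one gene.

    All spans are 1-based inclusive positions within the (intron-spliced,
    5'->3' oriented) gene sequence.  ``None`` marks an element that could
    not be located.
    """

    sequence: str
    acceptor_stem: tuple[Span, Span] | None = None
    acceptor_mismatches: int | None = None
    discriminator_pos: int | None = None
    cca_present: bool = False
    t_arm: Span | None = None
    variable_region: Span | None = None
    anticodon_arm: Span | None = None
    anticodon_span: Span | None = None
    anticodon: str | None = None
    d_arm: Span | None = None
    connector_8_9: Span | None = None
    connector_26: Span | None = None
    defects: list[Defect] = field(default_factory=list)
    n_count: int = 0
    n_in_anticodon: bool = False

    @property
    def fatal_defects(self) -> list[Defect]:
        return [d for d in self.defects if d.severity == FATAL]

    @property
    def defect_codes(self) -> set[str]:
        return {d.code for d in self.defects}

    @property
    def located_elements(self) -> int:
        """How many of the core elements were located (used to rank
        partial vs complete gene copies)."""
        elements = (
            self.acceptor_stem, self.t_arm, self.anticodon_arm, self.d_arm,
        )
        return sum(e is not None for e in elements) + int(self.cca_present)

    def element_order(self) -> list[tuple[str, Span]]:
        """Located elements in 5'->3' order of their spans."""
        named: list[tuple[str, Span]] = []
        if self.acceptor_stem:
            named.append(("acceptor_5p", self.acceptor_stem[0]))
            named.append(("acceptor_3p", self.acceptor_stem[1]))
        for name in ("connector_8_9", "d_arm", "connector_26",
                     "anticodon_arm", "variable_region", "t_arm"):
            span = getattr(self, name)
            if span:
                named.append((name, span))
        if self.discriminator_pos:
            named.append(("discriminator",
                          (self.discriminator_pos, self.discriminator_pos)))
        return sorted(named, key=lambda item: item[1])


def is_canonical_structure(annotation: StructuralAnnotation) -> bool:
    """True iff the annotation carries no fatal defect."""
    return not annotation.fatal_defects


def annotate_structure(
    seq: str,
    config: StructureConfig | None = None,
) -> StructuralAnnotation:
    """Apply the six annotation steps in order and collect defects.

    The input is the predicted gene sequence, 5'->3', with introns already
    spliced out.  Absence of an element is reported as a defect, never as an
    exception.
    """
    config = config or StructureConfig()
    seq = normalize_sequence(seq)
    ann = StructuralAnnotation(sequence=seq)
    ann.n_count = seq.count("N")
    n = len(seq)

    if n < config.min_gene_length:
        ann.defects.append(Defect(
            "TRUNCATED", FATAL,
            f"sequence length {n} < minimum {config.min_gene_length}",
        ))

    # -- step (i): CCA terminus, discriminator, acceptor stem --------------
    acc3_start0: int | None = None  # 0-based start of the acceptor 3' side
    if n >= 26:
        candidates = []
        if n >= 12 and all(_matches(b, e) for b, e in zip(seq[-3:], "CCA")):
            # CCA genomically encoded: discriminator at -4, 3' side at -11..-5
            candidates.append((True, n - 11, n - 4))
        candidates.append((False, n - 8, n - 1))
        best = None
        for cca, start0, disc0 in candidates:
            mism = sum(
                not base_pairs(seq[i], seq[start0 + 6 - i],
                               config.allow_wobble)
                for i in range(7)
            )
            if best is None or mism < best[0]:
                best = (mism, cca, start0, disc0)
        mism, cca, start0, disc0 = best
        ann.cca_present = cca
        ann.discriminator_pos = disc0 + 1
        ann.acceptor_stem = ((1, 7), (start0 + 1, start0 + 7))
        ann.acceptor_mismatches = mism
        acc3_start0 = start0
        if not cca:
            ann.defects.append(Defect(
                "NO_CCA", WARNING, "no genomically encoded 3' CCA",
            ))
        if mism > config.acceptor_mismatch_tolerance:
            ann.defects.append(Defect(
                "ACCEPTOR_MISPAIR", FATAL,
                f"{mism} acceptor-stem mispairs "
                f"(tolerance {config.acceptor_mismatch_tolerance})",
            ))
        elif mism > 0:
            ann.defects.append(Defect(
                "ACCEPTOR_MISPAIR", WARNING,
                f"{mism} acceptor-stem mispair(s) within tolerance",
            ))
    else:
        ann.defects.append(Defect(
            "NO_ACCEPTOR_STEM", FATAL,
            f"sequence too short ({n} nt) to anchor an acceptor stem",
        ))

    # -- step (ii): T-arm prior to the acceptor 3' side --------------------
    t_span = find_t_arm(seq, config, search_end=acc3_start0)
    if t_span is None and acc3_start0 is not None:
        # fall back to an unrestricted search so fragments lacking a real
        # acceptor stem still report their T-arm
        t_span = find_t_arm(seq, config)
    if t_span is None:
        # the anticodon arm and D-arm are anchored relative to the T-arm;
        # without it they cannot be located either
        ann.defects.append(Defect("NO_T_ARM", FATAL, "no TTCRANN stem-loop"))
        ann.defects.append(Defect(
            "NO_ANTICODON_ARM", FATAL, "no T-arm anchor to search from",
        ))
        ann.defects.append(Defect(
            "NO_D_ARM", FATAL, "no anticodon-arm anchor to search from",
        ))
    else:
        ann.t_arm = t_span

    # -- steps (iii)+(iv): variable region and anticodon arm ---------------
    ac_start0: int | None = None
    if t_span is not None:
        t_start0 = t_span[0] - 1
        gaps = list(config.variable_gaps) + list(
            range(config.extra_arm_gap[0], config.extra_arm_gap[1] + 1)
        )
        for gap in gaps:
            end0 = t_start0 - gap - 1  # inclusive end of the 17-nt arm
            start0 = end0 - 16
            if start0 < 0:
                continue
            mism = _stem_mismatches(seq, start0, end0, 5, config.allow_wobble)
            if mism <= config.anticodon_stem_mismatch_tolerance:
                ac_start0 = start0
                ann.anticodon_arm = (start0 + 1, end0 + 1)
                ann.variable_region = (end0 + 2, t_start0)
                loop = seq[start0 + 5:start0 + 12]
                ann.anticodon_span = (start0 + 8, start0 + 10)
                ann.anticodon = loop[2:5]
                ann.n_in_anticodon = "N" in ann.anticodon
                if not (_matches(loop[0], "C") and _matches(loop[1], "T")):
                    ann.defects.append(Defect(
                        "NON_CU_LOOP_START", WARNING,
                        f"anticodon loop starts {loop[:2]}, not CT",
                    ))
                break
        if ac_start0 is None:
            ann.defects.append(Defect(
                "NO_ANTICODON_ARM", FATAL,
                "no paired 17-nt anticodon arm at an admissible distance "
                "5' of the T-arm",
            ))
            ann.defects.append(Defect(
                "NO_D_ARM", FATAL, "no anticodon-arm anchor to search from",
            ))

    # -- step (v): D-arm 5' of the anticodon arm ---------------------------
    d_span: Span | None = None
    if ac_start0 is not None:
        candidates = []
        lo_loop, hi_loop = config.d_loop_range
        for gap26 in (1, 2):
            for stem in config.d_stem_lengths:
                for loop_len in range(lo_loop, hi_loop + 1):
                    end0 = ac_start0 - gap26 - 1
                    start0 = end0 - (2 * stem + loop_len) + 1
                    if start0 < 7:  # positions 1-7 are the acceptor 5' side
                        continue
                    mism = _stem_mismatches(
                        seq, start0, end0, stem, config.allow_wobble
                    )
                    if mism <= config.d_stem_mismatch_tolerance:
                        conn_gap = start0 - 7
                        candidates.append((
                            conn_gap not in config.connector_gaps,
                            gap26, -stem, start0, end0,
                        ))
        if candidates:
            _, gap26, _, start0, end0 = min(candidates)
            d_span = (start0 + 1, end0 + 1)
            ann.d_arm = d_span
            # -- step (vi): connectors 8-9 and 26 --------------------------
            if start0 >= 8:
                ann.connector_8_9 = (8, start0)
            ann.connector_26 = (end0 + 2, ac_start0)
            conn_gap = start0 - 7
            if conn_gap not in config.connector_gaps:
                ann.defects.append(Defect(
                    "BAD_CONNECTOR", WARNING,
                    f"{conn_gap} nt between acceptor stem and D-arm "
                    f"(expected one of {config.connector_gaps})",
                ))
        else:
            ann.defects.append(Defect(
                "NO_D_ARM", FATAL,
                "no paired 3-4 bp D-stem with an admissible loop 5' of the "
                "anticodon arm",
            ))

    return ann
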