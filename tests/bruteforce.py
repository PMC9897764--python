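"""Independent brute-force oracles used to cross-check the screens.

These scanners implement the operation definitions directly by exhaustive
enumeration, without any of the seeding or anchoring shortcuts of the
implementation, and stay deliberately simple (quadratic where needed).
"""

from __future__ import annotations

from trnacurate.io_formats import gene_sequence, reverse_complement

_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def _pairs(a: str, b: str) -> bool:
    return "N" in (a, b) or (a, b) in _PAIRS


def t_arm_scan(seq: str) -> tuple[int, int] | None:
    """Rightmost 17-nt window with a TTCRANN loop and a paired 5-bp stem."""
    seq = seq.upper().replace("U", "T")
    best = None
    for start in range(len(seq) - 16):
        window = seq[start:start + 17]
        loop = window[5:12]
        ok = (
            loop[0] in "TN" and loop[1] in "TN" and loop[2] in "CN"
            and loop[3] in "AGN" and loop[4] in "AN"
        )
        if not ok:
            continue
        if all(_pairs(window[i], window[16 - i]) for i in range(5)):
            best = (start + 1, start + 17)
    return best


def _trimmed_terminal_match(window: str, segment: str,
                            max_mismatches: int) -> tuple[int, int]:
    """Maximal end-anchored match of two strings, inner boundary trimmed."""
    limit = min(len(window), len(segment))
    marks = []
    mism = 0
    length = 0
    for i in range(1, limit + 1):
        differs = window[-i] != segment[-i]
        if differs and mism + 1 > max_mismatches:
            break
        mism += differs
        marks.append(differs)
        length = i
    while length and marks[length - 1]:
        mism -= 1
        length -= 1
    return length, mism


def attr_hits(
    prediction,
    genome: dict[str, str],
    min_repeat_length: int = 20,
    max_mismatches: int = 1,
    max_separation: int = 250_000,
    terminal_window: int = 100,
    min_copy_distance: int = 100,
) -> set[tuple[int, int, str, int, int]]:
    """Every terminal-repeat hit of one prediction, by full enumeration.

    Checks every contig position on both strands against both the 3'- and
    5'-terminal windows of the gene.  Returns forward-strand 1-based spans
    ``(start, end, strand, length, mismatches)``, self-hits excluded.
    """
    contig = genome[prediction.seq_id]
    L = len(contig)
    seq = gene_sequence(prediction, genome)
    hits: set[tuple[int, int, str, int, int]] = set()
    for at_3p in (True, False):
        if at_3p:
            window = seq[-min(terminal_window, len(seq)):]
        else:
            window = reverse_complement(seq[:min(terminal_window, len(seq))])
        for strand, target in (("+", contig), ("-", reverse_complement(contig))):
            for end0 in range(L):
                segment = target[max(0, end0 - len(window) + 1):end0 + 1]
                length, mism = _trimmed_terminal_match(
                    window, segment, max_mismatches
                )
                if length < min_repeat_length:
                    continue
                if strand == "+":
                    start, end = end0 - length + 2, end0 + 1
                    hstrand = "+" if at_3p else "-"
                else:
                    start = L - end0
                    end = L - (end0 - length + 1)
                    hstrand = "-" if at_3p else "+"
                near = (prediction.start - min_copy_distance,
                        prediction.end + min_copy_distance)
                if start <= near[1] and near[0] <= end:
                    continue
                separation = max(0, max(start - prediction.end,
                                        prediction.start - end))
                if separation > max_separation:
                    continue
                hits.add((start, end, hstrand, length, mism))
    return hits


def crispr_arrays_scan(
    seq: str,
    repeat_range: tuple[int, int] = (20, 50),
    spacer_range: tuple[int, int] = (20, 60),
    min_repeats: int = 3,
) -> set[tuple[tuple[int, int], ...]]:
    """All maximal identical-direct-repeat arrays, by exhaustive grouping.

    Groups every exact 20-mer occurrence, chains occurrences whose period
    lies in the admissible repeat+spacer range, extends each chain to the
    maximal length over which all copies stay identical, and validates
    spacer lengths.  Returns sets of 1-based repeat spans.
    """
    rep_lo, rep_hi = repeat_range
    sp_lo, sp_hi = spacer_range
    min_period, max_period = rep_lo + sp_lo, rep_hi + sp_hi
    k = rep_lo
    n = len(seq)
    occurrences: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        occurrences.setdefault(seq[i:i + k], []).append(i)

    results: set[tuple[tuple[int, int], ...]] = set()
    for positions in occurrences.values():
        if len(positions) < min_repeats:
            continue
        chain = [positions[0]]
        chains = []
        for p in positions[1:]:
            if min_period <= p - chain[-1] <= max_period:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for chain in chains:
            if len(chain) < min_repeats:
                continue
            left = 0
            while (chain[0] - left - 1 >= 0
                   and k + left + 1 <= rep_hi
                   and len({seq[p - left - 1] for p in chain}) == 1
                   and all((chain[i + 1] - left - 1) - (chain[i] + k)
                           >= sp_lo for i in range(len(chain) - 1))):
                left += 1
            right = 0
            while (chain[-1] + k + right < n
                   and k + left + right + 1 <= rep_hi
                   and len({seq[p + k + right] for p in chain}) == 1
                   and all((chain[i + 1] - left) - (chain[i] + k + right + 1)
                           >= sp_lo for i in range(len(chain) - 1))):
                right += 1
            length = k + left + right
            if length < rep_lo:
                continue
            spans = tuple(
                (p - left + 1, p + k + right) for p in chain
            )
            gaps = [
                s1 - e0 - 1 for (_, e0), (s1, _) in zip(spans, spans[1:])
            ]
            if all(sp_lo <= g <= sp_hi for g in gaps):
                results.add(spans)

    # merge overlapping variants: a subset of copies may share a longer
    # unanimous extension; keep the variant with the most repeat copies
    merged: list[tuple[tuple[int, int], ...]] = []
    for spans in sorted(results, key=lambda s: (-len(s), s)):
        lo, hi = spans[0][0], spans[-1][1]
        if not any(
            lo <= kept[-1][1] and kept[0][0] <= hi for kept in merged
        ):
            merged.append(spans)
    return set(merged)


def median_by_sorting(values) -> float:
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return float(ordered[mid])
    return (ordered[mid - 1] + ordered[mid]) / 2.0
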