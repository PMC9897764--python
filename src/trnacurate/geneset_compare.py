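"""Compare tRNA gene sets against a standard set across genomes.

Produces per-unit anomaly records (one record per unit of copy-number
deviation), a genomes x tRNA-types count matrix, and isotype-score
distribution summaries.  In curated mode, rescued genes count under their
reassigned type and fragments are excluded from the canonical matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import StandardSet, TRNAGenePrediction
from .triage import CANONICAL_CATEGORIES, MISASSIGNED_AMBIGUOUS, CurationCall

__all__ = [
    "Anomaly",
    "GeneSetMatrix",
    "type_counts",
    "compare_to_standard",
    "compare_batch",
    "build_matrix",
    "score_histogram",
    "HistogramSummary",
]

ADDITIONAL = "ADDITIONAL"
MISSING = "MISSING"


@dataclass(frozen=True)
class Anomaly:
    """One unit of deviation from the standard set.

    A type observed 3 times against an expectation of 1 yields two
    ADDITIONAL records, so the number of anomaly records equals the L1
    distance between the observed and expected count vectors.
    """

    genome_id: str
    isotype: str
    anticodon: str
    direction: str
    observed: int
    expected: int

    def __post_init__(self) -> None:
        if self.direction == ADDITIONAL and not self.observed > self.expected:
            raise ValueError("ADDITIONAL requires observed > expected")
        if self.direction == MISSING and not self.observed < self.expected:
            raise ValueError("MISSING requires observed < expected")


def type_counts(
    items: Iterable[TRNAGenePrediction | CurationCall]
        | Mapping[tuple[str, str], int],
    curated: bool = False,
) -> dict[tuple[str, str], int]:
    """Count genes per (isotype, anticodon).

    ``curated=True`` restricts curation calls to canonical categories
    (CANONICAL, LEGITIMATE_DUPLICATE) plus MISASSIGNED_AMBIGUOUS, the
    latter counted under its reassigned type.  Raw mode counts every
    record under its listed type.
    """
    if isinstance(items, Mapping):
        return dict(items)
    counts: dict[tuple[str, str], int] = {}
    for item in items:
        if isinstance(item, CurationCall):
            if curated:
                if item.category in CANONICAL_CATEGORIES:
                    key = item.prediction.type_key
                elif item.category == MISASSIGNED_AMBIGUOUS:
                    key = item.reassigned_to
                else:
                    continue
            else:
                key = item.prediction.type_key
        else:
            key = item.type_key
        counts[key] = counts.get(key, 0) + 1
    return counts


def compare_to_standard(
    items,
    standard: StandardSet,
    genome_id: str = "",
    curated: bool = False,
) -> list[Anomaly]:
    """Anomaly records for one genome's gene set versus the standard.

    Types observed but absent from the standard produce ADDITIONAL records
    with expected 0.  An empty result means the set conforms exactly.
    """
    counts = type_counts(items, curated=curated)
    if not genome_id:
        for item in items if not isinstance(items, Mapping) else ():
            pred = getattr(item, "prediction", item)
            genome_id = pred.genome_id
            break
    expected = standard.expected_counts()
    anomalies: list[Anomaly] = []
    keys = list(expected) + [k for k in counts if k not in expected]
    for key in keys:
        observed = counts.get(key, 0)
        want = expected.get(key, 0)
        if observed > want:
            direction, units = ADDITIONAL, observed - want
        elif observed < want:
            direction, units = MISSING, want - observed
        else:
            continue
        anomalies.extend(
            Anomaly(genome_id, key[0], key[1], direction, observed, want)
            for _ in range(units)
        )
    return anomalies


def compare_batch(
    listings: Mapping[str, Sequence],
    standard: StandardSet,
    curated: bool = False,
) -> dict[str, list[Anomaly]]:
    """Per-genome anomalies; genomes with an empty list are standard."""
    return {
        genome_id: compare_to_standard(
            items, standard, genome_id=genome_id, curated=curated
        )
        for genome_id, items in listings.items()
    }


@dataclass
class GeneSetMatrix:
    """Genomes x tRNA-types count matrix (the gene-set heatmap data)."""

    counts: pd.DataFrame  # index: genome ids; columns: "Isotype-ANT" labels
    standard: StandardSet | None = None

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def types(self) -> list[tuple[str, str]]:
        return [tuple(c.rsplit("-", 1)) for c in self.counts.columns]

    def deviant_genomes(self) -> list[str]:
        if self.standard is None:
            raise ValueError("deviance requires a standard set")
        expected = self.standard.expected_counts()
        out = []
        for genome_id, row in self.counts.iterrows():
            obs = {
                tuple(col.rsplit("-", 1)): int(row[col])
                for col in self.counts.columns
            }
            keys = set(expected) | {k for k, v in obs.items() if v}
            if any(obs.get(k, 0) != expected.get(k, 0) for k in keys):
                out.append(genome_id)
        return out

    def to_tsv(self, path_or_handle: str | Path | IO[str]) -> None:
        self.counts.to_csv(path_or_handle, sep="\t", index_label="genome_id")

    def to_heatmap(self, path: str | Path) -> None:
        """Render the count matrix as a heatmap image (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(6, 0.18 * len(self.counts.columns)),
                     max(3, 0.3 * len(self.counts.index))),
        )
        im = ax.imshow(self.counts.to_numpy(), aspect="auto",
                       cmap="viridis", interpolation="nearest")
        ax.set_xticks(range(len(self.counts.columns)))
        ax.set_xticklabels(self.counts.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(self.counts.index)))
        ax.set_yticklabels(self.counts.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="gene copies")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_matrix(
    listings: Mapping[str, Sequence],
    standard: StandardSet | None = None,
    curated: bool = False,
) -> GeneSetMatrix:
    """Count matrix over the union of standard and observed types.

    Columns follow standard-set order, then any extra observed types in
    sorted order.  Output is invariant to the order of input records.
    """
    if not listings:
        raise ValueError("at least one genome required")
    per_genome = {
        genome_id: type_counts(items, curated=curated)
        for genome_id, items in listings.items()
    }
    columns: list[tuple[str, str]] = list(standard.types) if standard else []
    extra = sorted(
        {key for counts in per_genome.values() for key in counts}
        - set(columns)
    )
    columns = columns + extra
    labels = [f"{iso}-{anti}" for iso, anti in columns]
    data = {
        genome_id: [counts.get(key, 0) for key in columns]
        for genome_id, counts in per_genome.items()
    }
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=labels
    ).loc[list(listings)]
    return GeneSetMatrix(counts=frame, standard=standard)


@dataclass(frozen=True)
class HistogramSummary:
    """Binned isotype-score counts with exact order statistics."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    minimum: float | None
    maximum: float | None
    median: float | None
    n: int
    n_flagged: int | None = None  # scores below the flag threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "count": self.counts,
        })


def score_histogram(
    records: Sequence,
    bin_width: float = 5.0,
    flag_threshold: float | None = None,
) -> HistogramSummary:
    """Histogram of isotype scores with exact min/max/median.

    ``records`` may be predictions, curation calls, or bare numbers;
    records without a score are skipped.  Empty input yields an empty
    summary.
    """
    scores = []
    for rec in records:
        if isinstance(rec, (int, float)):
            scores.append(float(rec))
            continue
        pred = getattr(rec, "prediction", rec)
        if pred.isotype_score is not None:
            scores.append(float(pred.isotype_score))
    if not scores:
        return HistogramSummary((), (), None, None, None, 0,
                                0 if flag_threshold is not None else None)
    arr = np.asarray(scores)
    lo = np.floor(arr.min() / bin_width) * bin_width
    hi = np.ceil(arr.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    flagged = int((arr < flag_threshold).sum()) if flag_threshold is not None \
        else None
    return HistogramSummary(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        median=float(np.median(arr)),
        n=len(arr),
        n_flagged=flagged,
    )
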