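"""The 20-genome Thermococcaceae survey as a packaged, desk-scale fixture.

GtRNAdb (Data Release 19) lists tRNA gene sets for 20 Thermococcaceae
genomes; 13 conform to the standard archaeal 46-type single-copy set and 7
deviate, in 15 unit anomalies.  The deviations — coordinates, scores,
classifications and curation categories — are transcribed in the packaged
``thermococcaceae_deviations.tsv``.  This module reconstructs the full raw
listings from that table (standard background plus deviations) so the
whole raw-vs-curated accounting can be recomputed without downloading
genomes.

Genome ids for the 12 conforming genomes not individually discussed in the
source material are synthetic placeholders; per-genome identity is
irrelevant to the set-level accounting.
"""

from __future__ import annotations

from importlib import resources
import pandas as pd

from .context_screens import (
    AMBIGUOUS_N,
    ATTR_PAIR,
    CRISPR_OVERLAP,
    ContextEvidence,
)
from .io_formats import StandardSet, TRNAGenePrediction, load_standard_set

__all__ = [
    "load_survey_deviations",
    "survey_genome_ids",
    "reconstruct_survey_listings",
    "survey_evidence_stubs",
    "deviation_predictions",
]

#: Genomes with deviant GtRNAdb listings, plus the conforming genomes that
#: are individually documented.  Synthetic ids fill the remainder of the 20.
_DEVIANT_GENOMES = (
    "T_gammatolerans_EJ3",
    "T_nautili_30-1",
    "T_kodakarensis_KOD1",
    "P_yayanosii_CH1",
    "T_sp_ES1",
    "T_litoralis_DSM5473",
    "Pa_pacificus_DY20341",
)
_NAMED_CONFORMING = ("P_furiosus_DSM3638",)
_N_SURVEY_GENOMES = 20


def load_survey_deviations() -> pd.DataFrame:
    """The packaged deviation table as a DataFrame (one row per anomaly)."""
    ref = resources.files("trnacurate.data").joinpath(
        "thermococcaceae_deviations.tsv"
    )
    with ref.open() as handle:
        frame = pd.read_csv(handle, sep="\t", comment="#")
    frame["anomaly_id"] = frame["anomaly_id"].astype(int)
    return frame


def survey_genome_ids() -> list[str]:
    """All 20 survey genome ids (deviant, named conforming, placeholders)."""
    ids = list(_DEVIANT_GENOMES) + list(_NAMED_CONFORMING)
    n_placeholder = _N_SURVEY_GENOMES - len(ids)
    ids += [f"Thermococcaceae_sp_{i:02d}" for i in range(1, n_placeholder + 1)]
    return ids


def _background_predictions(
    genome_id: str,
    standard: StandardSet,
    skip: set[tuple[str, str]],
) -> list[TRNAGenePrediction]:
    """Standard-conforming placeholder records for types not in the table.

    Coordinates are synthetic (sequential); isotype scores are left absent
    because the table does not report them for conforming genes.
    """
    preds = []
    pos = 1000
    for i, (isotype, anticodon) in enumerate(standard.types, start=1):
        if (isotype, anticodon) in skip:
            continue
        preds.append(TRNAGenePrediction(
            genome_id=genome_id,
            seq_id="chromosome",
            gene_name=f"tRNA-{isotype}-{anticodon}-1-1",
            start=pos,
            end=pos + 75,
            strand="+",
            isotype=isotype,
            anticodon=anticodon,
        ))
        pos += 1000
    return preds


def deviation_predictions(
    deviations: pd.DataFrame | None = None,
) -> list[TRNAGenePrediction]:
    """Prediction records for the additional (direction ``+``) table rows."""
    frame = deviations if deviations is not None else load_survey_deviations()
    preds = []
    for _, row in frame.iterrows():
        if row["direction"] != "+":
            continue
        preds.append(TRNAGenePrediction(
            genome_id=row["genome_id"],
            seq_id=str(row["seq_id"]),
            gene_name=(
                f"tRNA-{row['isotype']}-{row['anticodon']}"
                f"-anomaly{int(row['anomaly_id'])}"
            ),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            isotype=row["isotype"],
            anticodon=row["anticodon"],
            isotype_score=float(row["isotype_score"]),
            pseudo_flag=row["trnascan_class"] == "Ps",
            note="pseudo" if row["trnascan_class"] == "Ps" else "",
        ))
    return preds


def reconstruct_survey_listings(
    deviations: pd.DataFrame | None = None,
    standard: StandardSet | None = None,
) -> dict[str, list[TRNAGenePrediction]]:
    """Raw GtRNAdb-style listings for all 20 survey genomes.

    Each genome receives one record per standard type, minus the types the
    table marks missing for it, plus the additional records the table
    lists.  Summed over genomes this reproduces the survey's full raw gene
    count.
    """
    frame = deviations if deviations is not None else load_survey_deviations()
    standard = standard or load_standard_set()
    missing: dict[str, set[tuple[str, str]]] = {}
    for _, row in frame.iterrows():
        if row["direction"] == "-":
            missing.setdefault(row["genome_id"], set()).add(
                (row["isotype"], row["anticodon"])
            )
    extra = deviation_predictions(frame)
    listings: dict[str, list[TRNAGenePrediction]] = {}
    for genome_id in survey_genome_ids():
        listings[genome_id] = _background_predictions(
            genome_id, standard, missing.get(genome_id, set())
        )
    for pred in extra:
        listings[pred.genome_id].append(pred)
    return listings


def survey_evidence_stubs(
    deviations: pd.DataFrame | None = None,
) -> dict[str, dict[str, list[ContextEvidence]]]:
    """Context-evidence stubs derived from the table's category column.

    The table records the *outcome* of the genomic-context screens
    (category 1a = CRISPR overlap, 1b = attR partial copy, 2 = ambiguous
    N); without the underlying genomes the corresponding evidence is
    asserted rather than recomputed.  Keyed by genome id, then gene name.
    """
    frame = deviations if deviations is not None else load_survey_deviations()
    stubs: dict[str, dict[str, list[ContextEvidence]]] = {}
    for _, row in frame.iterrows():
        if row["direction"] != "+":
            continue
        name = (
            f"tRNA-{row['isotype']}-{row['anticodon']}"
            f"-anomaly{int(row['anomaly_id'])}"
        )
        category = str(row["category"])
        evs: list[ContextEvidence] = []
        if category == "1a":
            evs.append(ContextEvidence(
                kind=CRISPR_OVERLAP, subject=name,
                detail="lies within a CRISPR repeat-spacer array "
                       "(externally determined)",
            ))
        elif category == "1b":
            evs.append(ContextEvidence(
                kind=ATTR_PAIR, subject=name, partial_copy="subject",
                detail="partial copy of a full/partial pair flanking an "
                       "integrated element (externally determined)",
            ))
        elif category == "2":
            evs.append(ContextEvidence(
                kind=AMBIGUOUS_N, subject=name,
                payload=int(str(row["anticodon"]).count("N")) or 1,
                detail="N bases in gene and genome sequence "
                       "(externally determined)",
            ))
        if evs:
            stubs.setdefault(row["genome_id"], {})[name] = evs
    return stubs
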