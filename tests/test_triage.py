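import pytest

from trnacurate.context_screens import (
    AMBIGUOUS_N,
    ATTR_PAIR,
    CRISPR_OVERLAP,
    TMRNA_OVERLAP,
    ContextEvidence,
)
from trnacurate.io_formats import TRNAGenePrediction
from trnacurate.structure_annotator import Defect, StructuralAnnotation
from trnacurate.triage import (
    CANONICAL_CATEGORIES,
    TriageConfig,
    classify,
    curate_geneset,
    resolve_ambiguous,
    score_band,
)


def _pred(isotype="Val", anticodon="CAC", score=83.4, pseudo=False,
          name=None, start=1000, genome_id="g"):
    return TRNAGenePrediction(
        genome_id=genome_id, seq_id="c",
        gene_name=name or f"tRNA-{isotype}-{anticodon}-1",
        start=start, end=start + 71, strand="-", isotype=isotype,
        anticodon=anticodon, isotype_score=score, pseudo_flag=pseudo,
    )


def _ann(*defects):
    return StructuralAnnotation(sequence="N" * 72, defects=list(defects))


_FATAL_D = Defect("NO_D_ARM", "fatal")
_FATAL_ACC = Defect("ACCEPTOR_MISPAIR", "fatal")
_WARN_ACC = Defect("ACCEPTOR_MISPAIR", "warning")


class TestScoreBand:
    @pytest.mark.parametrize("score,band", [
        (83.4, "UNCERTAIN"),        # borderline Val-CAC-style score
        (2.3, "LIKELY_NONCANONICAL"),
        (135.1, "LIKELY_CANONICAL"),
        (60.0, "UNCERTAIN"),        # band edges are inclusive
        (90.0, "UNCERTAIN"),
        (59.9, "LIKELY_NONCANONICAL"),
        (90.1, "LIKELY_CANONICAL"),
    ])
    def test_banding(self, score, band):
        assert score_band(score)[0] == band

    def test_absent_score_uncertain_with_warning(self):
        band, warning = score_band(None)
        assert band == "UNCERTAIN"
        assert warning is not None

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            TriageConfig(band_low=95, band_high=90)


class TestResolveAmbiguous:
    def test_unique_match_same_isotype(self):
        pred = _pred("Leu", "NAG", 135.1)
        deficit = [("Leu", "CAG"), ("Pro", "GGG"), ("Gln", "CTG")]
        assert resolve_ambiguous(pred, None, deficit) == ("Leu", "CAG")

    def test_und_isotype_matches_any(self):
        pred = _pred("Und", "NTG", 117.9)
        deficit = [("Leu", "CAG"), ("Pro", "GGG"), ("Gln", "CTG")]
        assert resolve_ambiguous(pred, None, deficit) == ("Gln", "CTG")

    def test_multiple_matches_stay_unresolved(self):
        pred = _pred("Und", "NNN", 50.0)
        deficit = [("Leu", "CAG"), ("Pro", "GGG")]
        assert resolve_ambiguous(pred, None, deficit) is None

    def test_no_n_no_rescue(self):
        pred = _pred("Leu", "CAG", 135.1)
        assert resolve_ambiguous(pred, None, [("Leu", "CAG")]) is None

    def test_fatal_defects_block_rescue(self):
        pred = _pred("Leu", "NAG", 135.1)
        assert resolve_ambiguous(pred, _ann(_FATAL_D),
                                 [("Leu", "CAG")]) is None


class TestClassify:
    def test_borderline_score_with_fatal_defects(self):
        # a 83.4-scoring gene whose acceptor stem and D-arm are defective
        call = classify(_pred(score=83.4), _ann(_FATAL_ACC, _FATAL_D), [])
        assert call.category == "NONCANONICAL_OTHER"
        assert call.band == "UNCERTAIN"
        assert call.low_score_flag

    def test_single_tolerated_mispair_is_canonical(self):
        # one acceptor-stem mispair within tolerance (a point mutation or
        # reference error) does not disqualify an essential single-copy gene
        call = classify(_pred("Arg", "GCG", 88.1), _ann(_WARN_ACC), [])
        assert call.category == "CANONICAL"
        assert call.band == "UNCERTAIN"

    def test_clean_surplus_copy_is_legitimate_duplicate(self):
        call = classify(_pred("Ala", "TGC", 122.6), _ann(), [],
                        type_satisfied=True)
        assert call.category == "LEGITIMATE_DUPLICATE"

    def test_crispr_outranks_everything(self):
        pred = _pred("Leu", "CAA", 2.3, pseudo=True)
        evidence = [
            ContextEvidence(kind=CRISPR_OVERLAP, subject=pred.gene_name),
            ContextEvidence(kind=ATTR_PAIR, subject=pred.gene_name,
                            partial_copy="subject"),
        ]
        call = classify(pred, _ann(_FATAL_D), evidence)
        assert call.category == "FRAGMENT_CRISPR"

    def test_attr_partial_copy_is_fragment(self):
        pred = _pred("Gln", "TTG", 13.4, pseudo=True)
        evidence = [ContextEvidence(kind=ATTR_PAIR, subject=pred.gene_name,
                                    partial_copy="subject")]
        call = classify(pred, _ann(_FATAL_D), evidence)
        assert call.category == "FRAGMENT_ATTR"

    def test_attr_full_copy_not_penalized(self):
        pred = _pred("Gln", "TTG", 120.0)
        evidence = [ContextEvidence(kind=ATTR_PAIR, subject=pred.gene_name,
                                    partial_copy="partner")]
        call = classify(pred, _ann(), evidence)
        assert call.category == "CANONICAL"

    def test_rescue_requires_ambiguity_evidence(self):
        pred = _pred("Leu", "NAG", 135.1)
        evidence = [ContextEvidence(kind=AMBIGUOUS_N,
                                    subject=pred.gene_name, payload=1)]
        call = classify(pred, _ann(), evidence, deficit=[("Leu", "CAG")])
        assert call.category == "MISASSIGNED_AMBIGUOUS"
        assert call.reassigned_to == ("Leu", "CAG")

    def test_tmrna_overlap_noncanonical(self):
        pred = _pred("Und", "NNN", 23.7)
        evidence = [ContextEvidence(kind=TMRNA_OVERLAP,
                                    subject=pred.gene_name)]
        call = classify(pred, _ann(), evidence)
        assert call.category == "NONCANONICAL_OTHER"

    def test_very_low_score_noncanonical_without_evidence(self):
        call = classify(_pred("Ser", "CGA", 10.4), _ann(), [])
        assert call.category == "NONCANONICAL_OTHER"

    def test_pseudo_flag_advisory_without_defects(self):
        # a flagged but structurally complete, well-scoring gene stays
        call = classify(_pred("Gln", "TTG", 110.0, pseudo=True), _ann(), [])
        assert call.category == "CANONICAL"

    def test_foreign_evidence_rejected(self):
        pred = _pred()
        evidence = [ContextEvidence(kind=CRISPR_OVERLAP, subject="other")]
        with pytest.raises(ValueError, match="other"):
            classify(pred, _ann(), evidence)


class TestCurateGeneset:
    def test_all_planted_genes_canonical(self, plain_fixture, standard):
        fx = plain_fixture
        calls = curate_geneset(fx.predictions, genome=fx.genome,
                               standard=standard)
        assert all(c.category == "CANONICAL" for c in calls)
        assert len(calls) == len(fx.truth.genes)

    def test_planted_events_resolved(self, event_fixture, standard):
        fx = event_fixture
        calls = curate_geneset(fx.predictions, genome=fx.genome,
                               standard=standard)
        by_name = {c.prediction.gene_name: c for c in calls}
        partial = fx.truth.partials[0]
        frag = fx.truth.arrays[0].fragment_prediction
        mask = fx.truth.masks[0]
        assert by_name[partial.name].category == "FRAGMENT_ATTR"
        assert by_name[frag].category == "FRAGMENT_CRISPR"
        rescued = by_name[mask.gene_name]
        assert rescued.category == "MISASSIGNED_AMBIGUOUS"
        assert rescued.reassigned_to == (mask.true_isotype,
                                         mask.true_anticodon)
        for gene in fx.truth.genes:
            if gene.name == mask.gene_name:
                continue
            assert by_name[gene.name].category == "CANONICAL", gene.name

    def test_band_low_monotonicity(self, event_fixture, standard):
        # raising the lower decision band can only shrink the canonical set
        fx = event_fixture
        canonical_sets = []
        for low in (20.0, 60.0, 85.0):
            calls = curate_geneset(
                fx.predictions, genome=fx.genome, standard=standard,
                triage_config=TriageConfig(band_low=low),
            )
            canonical_sets.append({
                c.prediction.gene_name for c in calls
                if c.category == "CANONICAL"
            })
        assert canonical_sets[0] >= canonical_sets[1] >= canonical_sets[2]

    def test_idempotent_on_canonical_output(self, event_fixture, standard):
        fx = event_fixture
        calls = curate_geneset(fx.predictions, genome=fx.genome,
                               standard=standard)
        kept = [c for c in calls if c.category in CANONICAL_CATEGORIES]
        again = curate_geneset([c.prediction for c in kept],
                               genome=fx.genome, standard=standard)
        assert [(c.prediction.gene_name, c.category) for c in again] == \
            [(c.prediction.gene_name, c.category) for c in kept]

    def test_deterministic(self, event_fixture, standard):
        fx = event_fixture
        first = curate_geneset(fx.predictions, genome=fx.genome,
                               standard=standard)
        second = curate_geneset(fx.predictions, genome=fx.genome,
                                standard=standard)
        assert first == second

    def test_multiple_genomes_rejected(self):
        preds = [_pred(genome_id="a"), _pred(genome_id="b", start=5000)]
        with pytest.raises(ValueError, match="curate_batch"):
            curate_geneset(preds)
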