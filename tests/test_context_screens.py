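import numpy as np
import pytest

from trnacurate.context_screens import (
    AMBIGUOUS_N,
    ATTR_PAIR,
    CRISPR_OVERLAP,
    ScreenConfig,
    ambiguity_check,
    crispr_overlap,
    detect_crispr_arrays,
    find_attr_pairs,
    tmrna_overlap,
)
from trnacurate.io_formats import TRNAGenePrediction, reverse_complement
from trnacurate.synthetic_fixtures import (
    ArraySpec,
    FixtureSpec,
    IntegrationSpec,
    MaskSpec,
    generate,
    make_canonical_gene,
)

from .bruteforce import attr_hits, crispr_arrays_scan


def _pred(seq_id, start, end, strand="+", isotype="Gln", anticodon="TTG",
          name=None, score=120.0, genome_id="g"):
    return TRNAGenePrediction(
        genome_id=genome_id, seq_id=seq_id,
        gene_name=name or f"tRNA-{isotype}-{anticodon}-{start}",
        start=start, end=end, strand=strand, isotype=isotype,
        anticodon=anticodon, isotype_score=score,
    )


class TestAttrPairs:
    def test_planted_integration_recovered(self, event_fixture):
        fx = event_fixture
        evidences = find_attr_pairs(fx.predictions, fx.genome)
        partial = fx.truth.partials[0]
        subject_evs = [e for e in evidences if e.partial_copy == "subject"]
        assert {e.subject for e in subject_evs} == {partial.name}
        pair = subject_evs[0].payload
        assert pair.repeat_length == partial.repeat_length == 44
        assert pair.mismatches == partial.mismatches == 1
        assert pair.element_length == partial.element_length == 21_400
        assert pair.same_strand

    def test_no_duplication_no_pairs(self, plain_fixture):
        fx = plain_fixture
        evidences = find_attr_pairs(fx.predictions, fx.genome)
        assert evidences == []

    def test_inverted_distant_partial_found(self):
        # a rearranged integration: the unpredicted partial copy sits
        # ~179 kb away on the opposite strand
        spec = FixtureSpec(
            seed=7, genome_length=220_000, n_canonical=10,
            integrations=(IntegrationSpec(
                target_index=4, element_length=179_000, invert=True,
                predict_partial=False,
            ),),
        )
        fx = generate(spec)
        evidences = find_attr_pairs(fx.predictions, fx.genome)
        assert len(evidences) == 1
        ev = evidences[0]
        assert ev.partial_copy == "partner" and ev.partner is None
        pair = ev.payload
        assert not pair.same_strand
        assert pair.repeat_length == 44
        assert pair.element_length == 179_000
        truth = fx.truth.partials[0]
        assert (pair.copy_b.start, pair.copy_b.end) == (truth.start,
                                                        truth.end)

    def test_missing_contig_raises(self):
        pred = _pred("absent", 100, 175)
        with pytest.raises(KeyError, match="absent"):
            find_attr_pairs([pred], {"c": "ACGT" * 100})

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        spec = FixtureSpec(
            seed=100 + seed, genome_length=20_000, n_canonical=4,
            integrations=(IntegrationSpec(
                target_index=0, dup_length=30, mismatches=1,
                element_length=9_000, invert=bool(seed % 2),
                predict_partial=False,
            ),),
        )
        fx = generate(spec)
        cfg = ScreenConfig()
        evidences = find_attr_pairs(fx.predictions, fx.genome, cfg)
        impl_hits = {
            (e.subject, e.payload.copy_b.start, e.payload.copy_b.end,
             e.payload.copy_b.strand, e.payload.repeat_length,
             e.payload.mismatches)
            for e in evidences if e.partial_copy == "partner"
        }
        oracle_hits = set()
        for pred in fx.predictions:
            for start, end, strand, length, mism in attr_hits(
                pred, fx.genome,
                min_repeat_length=cfg.min_repeat_length,
                max_mismatches=cfg.max_mismatches,
                max_separation=cfg.max_separation,
                terminal_window=cfg.terminal_window,
                min_copy_distance=cfg.min_copy_distance,
            ):
                oracle_hits.add(
                    (pred.gene_name, start, end, strand, length, mism)
                )
        assert impl_hits == oracle_hits

    def test_strand_symmetry(self):
        spec = FixtureSpec(
            seed=21, genome_length=30_000, n_canonical=4,
            integrations=(IntegrationSpec(
                target_index=1, dup_length=36, mismatches=0,
                element_length=10_000, predict_partial=False,
            ),),
        )
        fx = generate(spec)
        seq_id = fx.spec.seq_id
        contig = fx.genome[seq_id]
        L = len(contig)
        mirrored_genome = {seq_id: reverse_complement(contig)}
        mirrored_preds = [
            TRNAGenePrediction(
                genome_id=p.genome_id, seq_id=p.seq_id,
                gene_name=p.gene_name,
                start=L - p.end + 1, end=L - p.start + 1,
                strand="-" if p.strand == "+" else "+",
                isotype=p.isotype, anticodon=p.anticodon,
                isotype_score=p.isotype_score,
            )
            for p in fx.predictions
        ]
        fwd = find_attr_pairs(fx.predictions, fx.genome)
        rev = find_attr_pairs(mirrored_preds, mirrored_genome)
        def key(evs):
            return sorted(
                (e.subject, e.payload.repeat_length, e.payload.mismatches,
                 e.payload.element_length, e.payload.same_strand)
                for e in evs
            )
        assert key(fwd) == key(rev)


class TestCrisprArrays:
    def test_planted_array_recovered_exactly(self):
        spec = FixtureSpec(
            seed=5, genome_length=20_000, n_canonical=2,
            arrays=(ArraySpec(n_repeats=5, repeat_length=30,
                              spacer_length=36),),
        )
        fx = generate(spec)
        (array,) = detect_crispr_arrays(fx.genome)
        truth = fx.truth.arrays[0]
        assert array.n_repeats == 5
        assert array.repeat_length == 30
        assert list(array.repeat_spans) == truth.repeat_spans
        assert list(array.spacer_spans) == truth.spacer_spans

    def test_large_array_geometry(self):
        # an array of 41 identical 30-bp repeats with ~36-bp spacers
        spec = FixtureSpec(
            seed=8, genome_length=30_000, n_canonical=4,
            arrays=(ArraySpec(n_repeats=41, repeat_length=30,
                              spacer_length=36, embed_trna_fragment=True),),
        )
        fx = generate(spec)
        (array,) = detect_crispr_arrays(fx.genome)
        assert array.n_repeats == 41
        assert array.repeat_length == 30

    @pytest.mark.parametrize("seed", range(20))
    def test_random_sequence_negative_control(self, seed):
        rng = np.random.default_rng(900 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert detect_crispr_arrays({"c": seq}) == []

    def test_two_repeats_below_threshold(self):
        rng = np.random.default_rng(17)
        repeat = "".join(rng.choice(list("ACGT"), size=30))
        spacer = "".join(rng.choice(list("ACGT"), size=36))
        flank = "".join(rng.choice(list("ACGT"), size=1000))
        seq = flank + repeat + spacer + repeat + flank
        assert detect_crispr_arrays({"c": seq}) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        spec = FixtureSpec(
            seed=300 + seed, genome_length=25_000, n_canonical=3,
            arrays=(
                ArraySpec(n_repeats=4 + seed, repeat_length=25 + seed,
                          spacer_length=30 + seed),
            ),
        )
        fx = generate(spec)
        seq = fx.genome[fx.spec.seq_id]
        impl = {
            a.repeat_spans for a in detect_crispr_arrays(fx.genome)
        }
        oracle = crispr_arrays_scan(seq)
        assert impl == oracle
        assert impl == {tuple(map(tuple, a.repeat_spans))
                        for a in fx.truth.arrays}


class TestCrisprOverlap:
    def test_embedded_fragment_coverage(self, event_fixture):
        fx = event_fixture
        arrays = detect_crispr_arrays(fx.genome)
        evidences = crispr_overlap(fx.predictions, arrays)
        frag_name = fx.truth.arrays[0].fragment_prediction
        assert [e.subject for e in evidences] == [frag_name]
        ev = evidences[0]
        assert len(ev.get("covered_spacers")) == 4
        assert len(ev.get("covered_repeats")) == 3

    def test_one_bp_outside_no_evidence(self):
        spec = FixtureSpec(
            seed=5, genome_length=20_000, n_canonical=2,
            arrays=(ArraySpec(n_repeats=5),),
        )
        fx = generate(spec)
        (array,) = detect_crispr_arrays(fx.genome)
        start, end = array.array_span
        outside = _pred(fx.spec.seq_id, end + 1, end + 80,
                        genome_id=fx.spec.genome_id)
        touching = _pred(fx.spec.seq_id, end, end + 80,
                         genome_id=fx.spec.genome_id)
        assert crispr_overlap([outside], [array]) == []
        assert len(crispr_overlap([touching], [array])) == 1

    def test_canonical_genes_outside_arrays(self, event_fixture):
        fx = event_fixture
        arrays = detect_crispr_arrays(fx.genome)
        gene_names = fx.truth.canonical_names()
        evidences = crispr_overlap(fx.predictions, arrays)
        assert not any(e.subject in gene_names for e in evidences)


class TestAmbiguityCheck:
    def test_masked_anticodon_flagged(self, event_fixture):
        fx = event_fixture
        mask = fx.truth.masks[0]
        pred = next(p for p in fx.predictions
                    if p.gene_name == mask.gene_name)
        ev = ambiguity_check(pred, fx.genome)
        assert ev is not None and ev.kind == AMBIGUOUS_N
        assert ev.payload == 1
        assert ev.get("n_in_anticodon") is True

    def test_n_free_gene_absent(self, plain_fixture):
        fx = plain_fixture
        for pred in fx.predictions:
            assert ambiguity_check(pred, fx.genome) is None

    def test_ns_outside_anticodon_counted(self):
        rng = np.random.default_rng(1)
        gene = make_canonical_gene(rng, "Gln", "TTG")
        masked = gene[:11] + "NN" + gene[13:]  # two D-arm bases
        genome = {"c": "A" * 500 + masked + "A" * 500}
        pred = _pred("c", 501, 500 + len(gene))
        ev = ambiguity_check(pred, genome)
        assert ev.payload == 2
        assert ev.get("n_in_anticodon") is False


class TestTmrnaOverlap:
    def test_prediction_inside_interval(self):
        pred = _pred("c", 1000, 1090, isotype="Und", anticodon="NNN")
        track = [("c", 900, 1300, "ssrA")]
        (ev,) = tmrna_overlap([pred], track)
        assert ev.partner == "ssrA"
        assert ev.get("overlap_bp") == 91

    def test_empty_track(self):
        pred = _pred("c", 1000, 1090)
        assert tmrna_overlap([pred], []) == []

    def test_partial_overlap_measured(self):
        pred = _pred("c", 1000, 1090)
        track = [("c", 1081, 1300, "ssrA")]
        (ev,) = tmrna_overlap([pred], track)
        assert ev.get("overlap_bp") == 10
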