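import itertools

import numpy as np
import pytest

from trnacurate.structure_annotator import (
    Defect,
    StructureConfig,
    StructuralAnnotation,
    annotate_structure,
    find_t_arm,
    is_canonical_structure,
)
from trnacurate.synthetic_fixtures import make_canonical_gene

from .bruteforce import t_arm_scan

_GENE_TYPES = [("Gln", "TTG"), ("Ala", "TGC"), ("Arg", "GCG"),
               ("Val", "CAC"), ("Ser", "CGA"), ("Leu", "CAA")]


class TestFindTArm:
    def test_constructed_motif_found(self):
        assert find_t_arm("GCGGGTTCGAATCCCGC") == (1, 17)

    def test_motif_impossible(self):
        assert find_t_arm("A" * 17) is None

    def test_exhaustive_loop_variants_match_oracle(self):
        # all TTC{A,G}A NN loops inside a fixed perfectly paired stem
        stem5, stem3 = "GCGGG", "CCCGC"
        for r, n1, n2 in itertools.product("AG", "ACGT", "ACGT"):
            seq = stem5 + "TTC" + r + "A" + n1 + n2 + stem3
            assert find_t_arm(seq) == (1, 17) == t_arm_scan(seq)

    def test_all_single_substitutions_match_oracle(self):
        # every single-base substitution of a valid arm agrees with the
        # brute-force scanner (stem mispairings beyond tolerance -> absent)
        seq = "GCGGGTTCGAATCCCGC"
        for pos, base in itertools.product(range(17), "ACGT"):
            mutant = seq[:pos] + base + seq[pos + 1:]
            assert find_t_arm(mutant) == t_arm_scan(mutant), (pos, base)

    def test_rightmost_window_wins(self):
        arm = "GCGGGTTCGAATCCCGC"
        two = arm + "AAAA" + arm
        assert find_t_arm(two) == (22, 38)


class TestAnnotateStructure:
    def test_canonical_gene_annotates_cleanly(self, canonical_gene):
        ann = annotate_structure(canonical_gene)
        assert ann.fatal_defects == []
        assert ann.anticodon_span == (34, 36)
        assert ann.anticodon == "TTG"
        assert ann.cca_present
        assert is_canonical_structure(ann)

    def test_t_arm_acceptor_fragment_fails(self, canonical_gene):
        # a fragment retaining only the T-arm and the acceptor 3' side,
        # the geometry of a spacer-borne viral tRNA gene remnant
        fragment = canonical_gene[-36:]
        ann = annotate_structure(fragment)
        assert ann.t_arm is not None
        codes = {d.code for d in ann.fatal_defects}
        assert "NO_ANTICODON_ARM" in codes
        assert "NO_D_ARM" in codes
        assert not is_canonical_structure(ann)

    @pytest.mark.parametrize("seed", range(100))
    def test_two_deletions_never_annotate_clean(self, seed):
        # deleting positions 2 (acceptor stem) and 15 (D-arm region)
        # must always leave a visible defect
        rng = np.random.default_rng(seed)
        isotype, anticodon = _GENE_TYPES[seed % 4]
        gene = make_canonical_gene(rng, isotype, anticodon)
        mutant = gene[:1] + gene[2:14] + gene[15:]
        ann = annotate_structure(mutant)
        assert ann.defects, "deletion mutant annotated defect-free"

    def test_annotation_deterministic(self, canonical_gene):
        first = annotate_structure(canonical_gene)
        second = annotate_structure(canonical_gene)
        assert first == second

    def test_short_sequence_truncated_not_exception(self):
        ann = annotate_structure("ACGT" * 6)
        assert any(d.code == "TRUNCATED" and d.severity == "fatal"
                   for d in ann.defects)

    def test_n_bases_tolerated_and_tallied(self, canonical_gene):
        masked = canonical_gene[:33] + "N" + canonical_gene[34:]
        ann = annotate_structure(masked)
        assert ann.fatal_defects == []
        assert ann.n_count == 1
        assert ann.n_in_anticodon
        assert ann.anticodon == "NTG"

    @pytest.mark.parametrize("seed", range(30))
    def test_generated_genes_clean_and_ordered(self, seed):
        rng = np.random.default_rng(200 + seed)
        isotype, anticodon = _GENE_TYPES[seed % len(_GENE_TYPES)]
        gene = make_canonical_gene(rng, isotype, anticodon)
        ann = annotate_structure(gene)
        assert ann.fatal_defects == []
        ordered = ann.element_order()
        spans = [span for _, span in ordered]
        # mutually non-overlapping and ordered 5'->3'
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2, (ordered, gene)

    @pytest.mark.parametrize("seed", range(30))
    def test_fragments_always_fail(self, seed):
        rng = np.random.default_rng(400 + seed)
        isotype, anticodon = _GENE_TYPES[seed % len(_GENE_TYPES)]
        gene = make_canonical_gene(rng, isotype, anticodon)
        for fragment in (gene[-44:], gene[:len(gene) // 2]):
            ann = annotate_structure(fragment)
            assert ann.fatal_defects, fragment

    def test_acceptor_mispair_tolerance(self, canonical_gene):
        # one broken acceptor pair stays within tolerance (warning only);
        # position 1 is swapped to a base that can no longer pair with 72
        seq = canonical_gene
        partner = seq[-5]  # position 72 (CCA encoded)
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[partner]
        mutated = bad + seq[1:]
        ann = annotate_structure(mutated)
        assert ann.acceptor_mismatches == 1
        assert any(d.code == "ACCEPTOR_MISPAIR" and d.severity == "warning"
                   for d in ann.defects)
        assert is_canonical_structure(ann)

    def test_acceptor_mispair_beyond_tolerance_fatal(self, canonical_gene):
        seq = canonical_gene
        swap = {"A": "C", "C": "A", "G": "A", "T": "C"}
        bad1 = swap[seq[-5]]
        bad2 = swap[seq[-6]]
        mutated = bad1 + bad2 + seq[2:]
        ann = annotate_structure(mutated)
        assert any(d.code == "ACCEPTOR_MISPAIR" and d.severity == "fatal"
                   for d in ann.defects)


class TestIsCanonical:
    def test_no_defects_true(self):
        ann = StructuralAnnotation(sequence="A" * 76)
        assert is_canonical_structure(ann)

    def test_fatal_defect_false(self):
        ann = StructuralAnnotation(
            sequence="A" * 76,
            defects=[Defect("NO_D_ARM", "fatal")],
        )
        assert not is_canonical_structure(ann)

    def test_warning_only_true(self):
        ann = StructuralAnnotation(
            sequence="A" * 76,
            defects=[Defect("NON_CU_LOOP_START", "warning")],
        )
        assert is_canonical_structure(ann)


def test_config_from_yaml(tmp_path):
    path = tmp_path / "structure.yaml"
    path.write_text(
        "acceptor_mismatch_tolerance: 2\nmin_gene_length: 40\n"
        "d_stem_lengths: [4, 3]\n"
    )
    cfg = StructureConfig.from_yaml(path)
    assert cfg.acceptor_mismatch_tolerance == 2
    assert cfg.min_gene_length == 40
    assert cfg.d_stem_lengths == (4, 3)
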