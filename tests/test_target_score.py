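"""Target Score computation, ranking and annotation-table I/O."""

from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycopull.target_score import (
    DEFAULT_VITAL_ORGANS,
    EXPRESSION_LEVELS,
    ORGAN_VOCABULARY,
    ProteinAnnotation,
    ScoreWeights,
    load_annotations,
    rank_proteins,
    score_protein,
    write_annotations,
)


def annotation(accession="A", cancer=0, prognosis=0, membrane=False, levels=None):
    expression = {o: 0 for o in ORGAN_VOCABULARY}
    expression.update(levels or {})
    return ProteinAnnotation(accession, cancer, prognosis, membrane, expression)


annotations_strategy = st.builds(
    annotation,
    cancer=st.integers(0, 3),
    prognosis=st.integers(0, 10),
    membrane=st.booleans(),
    levels=st.fixed_dictionaries(
        {o: st.integers(0, 3) for o in ORGAN_VOCABULARY}
    ),
)


class TestScoreProtein:
    def test_all_zero_annotation_scores_zero(self):
        assert score_protein(annotation()).total == 0.0

    def test_component_identity(self):
        r = score_protein(
            annotation(cancer=2, prognosis=3, membrane=True, levels={"liver": 2})
        )
        assert r.total == r.cancer_term + r.prognosis_term + r.membrane_term - r.healthy_penalty
        assert (r.cancer_term, r.prognosis_term, r.membrane_term, r.healthy_penalty) == (
            2.0, 3.0, 1.0, 2.0,
        )

    def test_vital_organ_level_shift_changes_total_exactly(self):
        a = annotation(cancer=3, levels={"brain": EXPRESSION_LEVELS["low"]})
        b = annotation(cancer=3, levels={"brain": EXPRESSION_LEVELS["high"]})
        assert score_protein(a).total - score_protein(b).total == 2.0

    def test_hand_computed_toy_table(self):
        table = [
            (annotation("P1", cancer=3, prognosis=5, membrane=True), 9.0),
            (annotation("P2", cancer=1, membrane=True, levels={"lung": 3}), -1.0),
            (annotation("P3", prognosis=2, levels={"brain": 1, "heart": 1}), 0.0),
            (annotation("P4"), 0.0),
        ]
        for a, expected in table:
            assert score_protein(a).total == expected

    def test_missing_vital_organ_errors(self):
        a = ProteinAnnotation("A", 0, 0, False, {"brain": 0})
        with pytest.raises(ValueError, match="liver"):
            score_protein(a, vital_organs=("brain", "liver"))

    def test_restricted_vital_organs_ignore_other_expression(self):
        a = annotation(levels={"colon": 3, "brain": 0})
        assert score_protein(a, vital_organs=("brain",)).healthy_penalty == 0.0

    @given(annotations_strategy)
    def test_reward_monotonicity(self, a):
        base = score_protein(a).total
        if a.cancer_association < 3:
            assert score_protein(
                replace(a, cancer_association=a.cancer_association + 1)
            ).total >= base
        assert score_protein(
            replace(a, n_unfavorable_prognosis=a.n_unfavorable_prognosis + 1)
        ).total >= base
        assert score_protein(replace(a, membrane_localized=True)).total >= base

    @given(annotations_strategy, st.sampled_from(ORGAN_VOCABULARY))
    def test_healthy_expression_monotonicity(self, a, organ):
        if a.healthy_expression[organ] < 3:
            worse = dict(a.healthy_expression)
            worse[organ] += 1
            assert (
                score_protein(replace(a, healthy_expression=worse)).total
                <= score_protein(a).total
            )

    @given(annotations_strategy, st.floats(0.1, 10))
    def test_scale_equivariance(self, a, c):
        w = ScoreWeights()
        assert score_protein(a, w.scaled(c)).total == pytest.approx(
            c * score_protein(a, w).total
        )


class TestRankProteins:
    def test_single_protein_is_rank_one(self):
        (r,) = rank_proteins([annotation("A", cancer=1)])
        assert r.rank == 1

    def test_tie_broken_by_lower_penalty(self):
        # equal totals (3) but different penalty structure
        a = annotation("AAA", cancer=3, levels={"liver": 1, "brain": 1})
        a = replace(a, n_unfavorable_prognosis=2)  # 3 + 2 - 2 = 3
        b = annotation("BBB", cancer=3)  # 3 + 0 - 0 = 3
        ranked = rank_proteins([a, b])
        assert [r.accession for r in ranked] == ["BBB", "AAA"]

    def test_final_tie_broken_lexicographically(self):
        ranked = rank_proteins([annotation("B"), annotation("A")])
        assert [r.accession for r in ranked] == ["A", "B"]

    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_proteins([annotation("A"), annotation("A")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_proteins([])

    @given(st.randoms(use_true_random=False))
    def test_ranking_stable_under_input_shuffling(self, rnd):
        annotations = [
            annotation(f"P{i}", cancer=i % 4, prognosis=i % 3, membrane=bool(i % 2))
            for i in range(12)
        ]
        reference = [(r.rank, r.accession) for r in rank_proteins(annotations)]
        shuffled = list(annotations)
        rnd.shuffle(shuffled)
        assert [(r.rank, r.accession) for r in rank_proteins(shuffled)] == reference

    def test_ranks_are_permutation(self):
        ranked = rank_proteins([annotation(f"P{i}", cancer=i % 4) for i in range(9)])
        assert sorted(r.rank for r in ranked) == list(range(1, 10))

    def test_planted_dominant_annotation_ranks_first(self):
        from glycopull.synthetic import generate_annotations

        accs = [f"P{i:03d}" for i in range(30)]
        annotations = generate_annotations(accs, "P017", seed=4)
        assert rank_proteins(annotations)[0].accession == "P017"


class TestAnnotationIO:
    def test_write_load_round_trip(self, tmp_path):
        annotations = [
            annotation("A", cancer=2, prognosis=1, membrane=True, levels={"lung": 2}),
            annotation("B"),
            annotation("C", cancer=3, levels={o: 3 for o in ORGAN_VOCABULARY}),
        ]
        path = tmp_path / "annotations.tsv"
        write_annotations(annotations, path)
        assert load_annotations(path) == annotations

    def test_well_formed_file_row_count(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_annotations([annotation(f"P{i}") for i in range(3)], path)
        assert len(load_annotations(path)) == 3

    def test_unknown_level_addressed_by_row_and_column(self, tmp_path):
        path = tmp_path / "a.tsv"
        header = "accession\tcancer_association\tn_unfavorable_prognosis\tmembrane_localized\tbrain"
        path.write_text(header + "\nA\t1\t0\tTrue\tvery high\n")
        with pytest.raises(ValueError, match="row 2.*brain|brain.*row 2"):
            load_annotations(path)

    def test_unknown_organ_column_rejected(self, tmp_path):
        path = tmp_path / "a.tsv"
        header = "accession\tcancer_association\tn_unfavorable_prognosis\tmembrane_localized\tspleen"
        path.write_text(header + "\nA\t1\t0\tTrue\tlow\n")
        with pytest.raises(ValueError, match="spleen"):
            load_annotations(path)

    def test_range_violation_addressed(self, tmp_path):
        path = tmp_path / "a.tsv"
        header = "accession\tcancer_association\tn_unfavorable_prognosis\tmembrane_localized\tbrain"
        path.write_text(header + "\nA\t7\t0\tTrue\tlow\n")
        with pytest.raises(ValueError, match="row 2"):
            load_annotations(path)
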