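import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluencyrp import (
    annotate_pair,
    build_recurrence_matrix,
    detect_intrusions,
    reduce_unique,
)

from conftest import INTRUSION_LIST, REPETITION_LIST

tokens_strategy = st.lists(
    st.sampled_from([f"w{k}" for k in range(20)]), max_size=12
)


class TestReduceUnique:
    def test_repetition_example_list(self):
        unique, reps = reduce_unique(REPETITION_LIST)
        assert len(unique) == 10
        assert [(r.position, r.first_position) for r in reps] == [(4, 1)]
        assert reps[0].token == "dog"

    @pytest.mark.parametrize(
        "tokens, n_unique, n_reps",
        [(["a", "a", "a"], 1, 2), ([], 0, 0), (["a", "b"], 2, 0)],
    )
    def test_edge_cases(self, tokens, n_unique, n_reps):
        unique, reps = reduce_unique(tokens)
        assert (len(unique), len(reps)) == (n_unique, n_reps)

    @given(tokens_strategy)
    @settings(max_examples=200, derandomize=True)
    def test_partition_and_idempotence(self, tokens):
        unique, reps = reduce_unique(tokens)
        assert len(unique) + len(reps) == len(tokens)
        assert len(set(unique)) == len(unique)
        again, reps2 = reduce_unique(unique)
        assert again == unique and reps2 == []


class TestDetectIntrusions:
    def test_out_of_category_item(self, vocab):
        assert detect_intrusions(["cat", "dog", "chair"], vocab) == [2]

    def test_clean_list(self, vocab):
        assert detect_intrusions(["cat", "dog"], vocab) == []

    def test_no_vocab_no_flags_is_error(self):
        with pytest.raises(ValueError, match="intrusion detection unavailable"):
            detect_intrusions(["cat"])

    def test_flags_take_precedence(self, vocab):
        # curated flag disagrees with the vocabulary: flag wins
        assert detect_intrusions(["cat", "dog"], vocab, flags=[True, False]) == [0]

    def test_repeated_intrusion_counts_per_occurrence(self, vocab):
        assert detect_intrusions(["chair", "cat", "chair"], vocab) == [0, 2]


class TestRecurrenceMatrix:
    def test_swapped_pair(self):
        m = build_recurrence_matrix(["cat", "dog"], ["dog", "cat"]).m
        assert m.tolist() == [[0, 1], [1, 0]]

    def test_identical_lists_fill_diagonal(self):
        m = build_recurrence_matrix(["cat", "dog", "pig"], ["cat", "dog", "pig"]).m
        assert (m == np.eye(3)).all()

    def test_subset_pair_matches_brute_force(self):
        rm = build_recurrence_matrix(["cat", "dog", "pig"], ["cat", "pig"])
        expected = {(i, j): int(rm.x_tokens[i] == rm.y_tokens[j])
                    for i in range(3) for j in range(2)}
        assert {(0, 0), (2, 1)} == {k for k, v in expected.items() if v}
        assert all(rm.m[i, j] == v for (i, j), v in expected.items())

    def test_empty_sequence_gives_zero_dim(self):
        assert build_recurrence_matrix([], ["cat"]).shape == (0, 1)

    def test_unique_mode_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate-free"):
            build_recurrence_matrix(["a", "a"], ["b"], mode="unique")

    @given(tokens_strategy, tokens_strategy)
    @settings(max_examples=150, derandomize=True)
    def test_transpose_symmetry(self, x, y):
        assert (build_recurrence_matrix(x, y).m
                == build_recurrence_matrix(y, x).m.T).all()

    @given(tokens_strategy, tokens_strategy)
    @settings(max_examples=150, derandomize=True)
    def test_unique_mode_row_col_sums_and_count(self, x, y):
        ux, _ = reduce_unique(x)
        uy, _ = reduce_unique(y)
        m = build_recurrence_matrix(ux, uy, mode="unique").m
        if m.size:
            assert m.sum(axis=0).max(initial=0) <= 1
            assert m.sum(axis=1).max(initial=0) <= 1
        assert m.sum() == len(set(x) & set(y))

    def test_text_export_round_trips_grid(self, tmp_path):
        rm = build_recurrence_matrix(["cat", "dog"], ["dog", "cat", "pig"])
        path = tmp_path / "m.tsv"
        rm.to_text(path)
        grid = [line.split("\t") for line in path.read_text().splitlines()
                if not line.startswith("#")]
        assert [[int(v) for v in row] for row in grid] == rm.m.tolist()


class TestAnnotatePair:
    def test_identical_lists(self, make_list, vocab):
        a = make_list(REPETITION_LIST, visit=1)
        b = make_list(REPETITION_LIST, visit=2)
        pair = annotate_pair(a, b, vocab)
        assert pair.missing_from_a == [] and pair.missing_from_b == []
        assert [(r.position, r.first_position) for r in pair.repetitions_a] == [(4, 1)]
        assert len(pair.unique_a) + len(pair.repetitions_a) == len(pair.tokens_a)

    def test_missing_items_assigned_to_owning_list(self, make_list, vocab):
        a = make_list(["cat", "dog", "pig"], visit=1)
        b = make_list(["cat", "pig"], visit=2)
        pair = annotate_pair(a, b, vocab)
        assert pair.missing_from_b == ["dog"]
        assert pair.missing_from_a == []

    def test_intrusion_row(self, make_list, vocab):
        a = make_list(INTRUSION_LIST, visit=1)
        b = make_list(INTRUSION_LIST, visit=2)
        pair = annotate_pair(a, b, vocab)
        assert pair.intrusions_a == [4] and pair.intrusions_b == [4]

    def test_cross_participant_guard(self, make_list, vocab):
        a = make_list(["cat"], pid="P1", visit=1)
        b = make_list(["cat"], pid="P2", visit=2)
        with pytest.raises(ValueError, match="different participants"):
            annotate_pair(a, b, vocab)
        pair = annotate_pair(a, b, vocab, allow_cross_participant=True)
        assert pair.unique_a == ["cat"]

    def test_wrong_chronology_rejected(self, make_list, vocab):
        a = make_list(["cat"], visit=2)
        b = make_list(["cat"], visit=1)
        with pytest.raises(ValueError, match="precede"):
            annotate_pair(a, b, vocab)

    def test_source_flags_override_vocabulary(self, make_list, vocab):
        # "cat" is in the vocabulary but the transcriber flagged it
        a = make_list(["cat", "dog"], visit=1,
                      annotations={"intrusion": [True, False]})
        b = make_list(["cat", "dog"], visit=2)
        pair = annotate_pair(a, b, vocab)
        assert pair.intrusions_a == [0]
        assert pair.intrusions_b == []
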