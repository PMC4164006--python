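"""Data model, CSV round-trips, CR-history grammar, filters and permutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beelearn import (
    build_cr_matrix,
    filter_spontaneous_responders,
    first_cr_trials,
    parse_cr_history,
    permute_within_trials,
    read_cr_csv,
    subgroup_by_grs,
    write_cr_csv,
)
from beelearn.cr_data import (
    ROLE_CONDITIONING,
    ROLE_CS_ONLY,
    ROLE_RETENTION,
    CRDataError,
    CRHistory,
    CSVFormatError,
    DurationMismatchError,
    GRSError,
    HistoryParseError,
    NonBinaryResponseError,
    RoleError,
    ShapeMismatchError,
    history_of_animal,
)
from conftest import random_cr_matrix


class TestBuild:
    def test_identity_construction(self):
        m = build_cr_matrix(
            [[0, 1, 1], [0, 0, 0]],
            [ROLE_CONDITIONING, ROLE_CONDITIONING, ROLE_RETENTION],
        )
        assert m.n_animals == 2 and m.n_trials == 3
        assert m.trial_roles == (ROLE_CONDITIONING, ROLE_CONDITIONING, ROLE_RETENTION)

    def test_durations_consistent_with_responses_accepted(self):
        m = build_cr_matrix(
            [[0, 1, 1], [0, 0, 0]],
            [ROLE_CONDITIONING] * 3,
            durations=[[np.nan, 1.0, 2.0], [np.nan, np.nan, np.nan]],
        )
        assert np.isnan(m.durations[0, 0]) and m.durations[0, 1] == 1.0

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(responses=[[0, 2]], trial_roles=[ROLE_CONDITIONING] * 2), NonBinaryResponseError),
            (dict(responses=[[0, 1]], trial_roles=[ROLE_CONDITIONING]), ShapeMismatchError),
            (dict(responses=[[0, 1]], trial_roles=[ROLE_RETENTION, ROLE_CONDITIONING]), RoleError),
            (dict(responses=[[0, 1]], trial_roles=[ROLE_CS_ONLY, ROLE_CS_ONLY]), RoleError),
            (
                dict(responses=[[0, 1]], trial_roles=[ROLE_CONDITIONING] * 2,
                     durations=[[3.0, 1.0]]),
                DurationMismatchError,
            ),
            (
                dict(responses=[[0, 1]], trial_roles=[ROLE_CONDITIONING] * 2,
                     grs=[11]),
                GRSError,
            ),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs, err):
        with pytest.raises(err):
            build_cr_matrix(**kwargs)

    def test_error_names_row_and_column(self):
        with pytest.raises(NonBinaryResponseError, match="row 1, column 0"):
            build_cr_matrix([[0, 1], [5, 0]], [ROLE_CONDITIONING] * 2)


class TestCSV:
    def test_round_trip_with_all_optional_fields(self, tmp_path):
        rng = np.random.default_rng(0)
        m = random_cr_matrix(rng, n=5, k=4, with_durations=True, with_grs=True)
        m = build_cr_matrix(
            m.responses, m.trial_roles, durations=m.durations, grs=m.grs,
            meta={"iti_minutes": 10, "cs_label": "1-hexanol"},
        )
        path = tmp_path / "m.csv"
        write_cr_csv(m, path)
        assert read_cr_csv(path) == m
        assert (tmp_path / "m.durations.csv").exists()

    def test_deterministic_bytes(self, tmp_path):
        rng = np.random.default_rng(1)
        m = random_cr_matrix(rng, n=4, k=3, with_durations=True)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cr_csv(m, p1)
        write_cr_csv(m, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_without_role_annotation_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,t1,t2:cond\na1,0,1\n")
        with pytest.raises(CSVFormatError, match="role annotation"):
            read_cr_csv(path)

    def test_non_binary_cell_cites_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,t1:cond\na1,0\na2,7\n")
        with pytest.raises(CSVFormatError, match=":3:"):
            read_cr_csv(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,t1:cond,t2:cond\na1,0\n")
        with pytest.raises(CSVFormatError, match="expected 3 cells"):
            read_cr_csv(path)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.booleans(), st.booleans())
    def test_round_trip_random_matrices(self, seed, with_durations, with_grs):
        import tempfile
        from pathlib import Path

        rng = np.random.default_rng(seed)
        m = random_cr_matrix(rng, with_durations=with_durations, with_grs=with_grs)
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "m.csv"
            write_cr_csv(m, path)
            assert read_cr_csv(path) == m


class TestHistory:
    def test_rewarded_sequence(self):
        h = parse_cr_history("0111")
        assert h.responses == (0, 1, 1, 1)
        assert all(h.rewarded)

    def test_bracket_marks_cs_only_trial(self):
        h = parse_cr_history("0(1)")
        assert h.tokens == ((0, True), (1, False))

    @pytest.mark.parametrize("bad", ["0x1", "(01)", "0(", "", "2"])
    def test_illegal_strings_rejected(self, bad):
        with pytest.raises(HistoryParseError):
            parse_cr_history(bad)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.booleans()), min_size=1, max_size=12
        )
    )
    def test_text_rendering_round_trips(self, tokens):
        h = CRHistory(tokens=tuple(tokens))
        assert parse_cr_history(str(h)) == h

    def test_history_of_animal_stops_before_retention(self, retention_matrix):
        assert str(history_of_animal(retention_matrix, 0)) == "01"


class TestFilters:
    def test_spontaneous_split_partitions(self):
        m = build_cr_matrix([[1, 1, 1], [0, 1, 1]], [ROLE_CONDITIONING] * 3)
        kept, removed = filter_spontaneous_responders(m)
        assert removed.n_animals == 1 and kept.n_animals == 1
        assert np.all(removed.responses[:, 0] == 1)

    def test_all_clean_keeps_everyone(self, toy_matrix):
        kept, removed = filter_spontaneous_responders(toy_matrix)
        assert kept.n_animals == 4 and removed.n_animals == 0

    def test_all_spontaneous_yields_empty_kept(self):
        m = build_cr_matrix([[1, 0], [1, 1]], [ROLE_CONDITIONING] * 2)
        kept, removed = filter_spontaneous_responders(m)
        assert kept.n_animals == 0 and removed.n_animals == 2

    def test_first_cr_indices(self, toy_matrix):
        assert first_cr_trials(toy_matrix) == [2, 2, 3, None]

    def test_first_cr_scope_restriction(self):
        m = build_cr_matrix(
            [[0, 0, 0, 1]],
            [ROLE_CONDITIONING] * 3 + [ROLE_RETENTION],
        )
        assert first_cr_trials(m) == [4]
        assert first_cr_trials(m, {ROLE_CONDITIONING}) == [None]


class TestPermutation:
    def test_single_animal_is_fixed_point(self):
        m = build_cr_matrix([[0, 1, 0]], [ROLE_CONDITIONING] * 3)
        assert permute_within_trials(m, 0) == m

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_column_sums_preserved(self, seed):
        rng = np.random.default_rng(seed)
        m = random_cr_matrix(rng, with_durations=True)
        perm = permute_within_trials(m, seed)
        assert np.array_equal(
            perm.responses.sum(axis=0), m.responses.sum(axis=0)
        )
        # multiset of durations per column preserved too
        for j in range(m.n_trials):
            a = np.sort(m.durations[:, j])
            b = np.sort(perm.durations[:, j])
            assert np.array_equal(a, b, equal_nan=True)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(42)
        m = random_cr_matrix(rng, n=10, k=4)
        assert permute_within_trials(m, 7) == permute_within_trials(m, 7)


class TestGRSSubgroups:
    def test_direct_binning(self):
        m = build_cr_matrix(
            [[0, 1], [0, 1], [0, 0]], [ROLE_CONDITIONING] * 2, grs=[10, 9, 3]
        )
        groups = subgroup_by_grs(m, [(10, 10), (8, 9), (2, 4)])
        assert [g.n_animals for g in groups] == [1, 1, 1]
        assert groups[0].grs.tolist() == [10]

    def test_overlapping_ranges_rejected(self):
        m = build_cr_matrix([[0, 1]], [ROLE_CONDITIONING] * 2, grs=[5])
        with pytest.raises(CRDataError, match="overlapping"):
            subgroup_by_grs(m, [(2, 5), (5, 8)])

    def test_empty_range_gives_empty_matrix(self):
        m = build_cr_matrix([[0, 1]], [ROLE_CONDITIONING] * 2, grs=[5])
        groups = subgroup_by_grs(m, [(9, 10)])
        assert groups[0].n_animals == 0

    def test_missing_grs_rejected(self, toy_matrix):
        with pytest.raises(GRSError):
            subgroup_by_grs(toy_matrix, [(0, 10)])
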