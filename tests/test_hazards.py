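"""Penalty-table loading, validation and penalty-sum arithmetic."""

import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from agreemip.hazards import (
    PenaltyTable,
    PenaltyTableError,
    UnknownHazardError,
    load_penalty_table,
    normalize_code,
    penalty_sum,
)


class TestHazardCode:
    @pytest.mark.parametrize(
        "raw, canon",
        [("H225", "H225"), ("h301", "H301"), ("h360fd", "H360FD"), (" H410 ", "H410")],
    )
    def test_canonicalization_uppercases_and_strips(self, raw, canon):
        assert normalize_code(raw) == canon

    @pytest.mark.parametrize("bad", ["X999", "H22", "225", "H2255", "H 225", "HXXX", ""])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(PenaltyTableError, match="hazard statement"):
            normalize_code(bad)


class TestPenaltyTableLoading:
    def test_packaged_default_is_nonempty_with_nonnegative_points(self, default_table):
        assert len(default_table) > 50
        assert all(p >= 0 for p in default_table.entries.values())
        assert default_table.source_label == "builtin-synthetic"

    def test_csv_round_trip_is_identity(self, tmp_path):
        src = tmp_path / "table.csv"
        src.write_text("code,points\nH225,6\nH301,8\n")
        table = load_penalty_table(src)
        assert table.entries == {"H225": 6, "H301": 8}
        assert table.source_label == str(src)

    def test_yaml_mapping_accepted(self, tmp_path):
        src = tmp_path / "table.yaml"
        src.write_text("H225: 6\nH301: 8\n")
        assert load_penalty_table(src).entries == {"H225": 6, "H301": 8}

    def test_malformed_code_names_offending_row(self, tmp_path):
        src = tmp_path / "bad.csv"
        src.write_text("code,points\nH225,6\nX999,3\n")
        with pytest.raises(PenaltyTableError, match="X999"):
            load_penalty_table(src)

    def test_negative_points_rejected(self, tmp_path):
        src = tmp_path / "neg.csv"
        src.write_text("code,points\nH225,-2\n")
        with pytest.raises(PenaltyTableError, match="nonnegative"):
            load_penalty_table(src)

    def test_duplicate_codes_rejected_even_across_case(self, tmp_path):
        src = tmp_path / "dup.csv"
        src.write_text("code,points\nH225,6\nh225,4\n")
        with pytest.raises(PenaltyTableError, match="duplicate"):
            load_penalty_table(src)

    def test_save_load_save_is_byte_identical(self, tmp_path, tiny_table):
        first = tiny_table.save(tmp_path / "a.csv")
        again = load_penalty_table(first).save(tmp_path / "b.csv")
        assert first.read_bytes() == again.read_bytes()

    def test_unreadable_path_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            load_penalty_table(tmp_path / "missing.csv")


class TestPenaltySum:
    def test_empty_set_sums_to_zero(self, tiny_table):
        assert penalty_sum(set(), tiny_table) == 0

    def test_sum_matches_entry_points(self, tiny_table):
        assert penalty_sum({"H225", "H301"}, tiny_table) == 6 + 8

    def test_duplicates_count_once(self, tiny_table):
        # oracle: deduplicate first, then sum entry by entry
        codes = ["H225", "h225", "H225"]
        oracle = sum(tiny_table.entries[c] for c in {normalize_code(c) for c in codes})
        assert penalty_sum(codes, tiny_table) == oracle == 6

    def test_strict_unknown_code_errors_with_code_name(self, tiny_table):
        with pytest.raises(UnknownHazardError, match="H999"):
            penalty_sum({"H999"}, tiny_table, strict=True)

    def test_lenient_unknown_code_warns_and_counts_zero(self, tiny_table):
        with pytest.warns(UserWarning, match="H999"):
            assert penalty_sum({"H999", "H225"}, tiny_table, strict=False) == 6

    def test_lenient_suffix_falls_back_to_stem(self, tiny_table):
        # H360FD is absent but its stem H360 is present
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert tiny_table.lookup("H360FD", strict=False) == 10
        with pytest.raises(UnknownHazardError):
            tiny_table.lookup("H360FD", strict=True)

    @given(codes=st.sets(st.sampled_from(["H225", "H301", "H360", "H400"]), max_size=4),
           extra=st.sampled_from(["H225", "H301", "H360", "H400"]))
    def test_adding_a_code_never_decreases_the_sum(self, codes, extra, tiny_table):
        base = penalty_sum(codes, tiny_table)
        assert penalty_sum(codes | {extra}, tiny_table) >= base

    @given(ordering=st.permutations(["H400", "H225", "H360", "H301"]))
    def test_permutation_invariance(self, ordering, tiny_table):
        assert penalty_sum(ordering, tiny_table) == 6 + 8 + 10 + 6
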