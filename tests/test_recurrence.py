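import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trapline as tl
from trapline.records import TrialRecord

from _oracle import brute_force_repeats


def _seq(s):
    return list(s)


class TestRecurrencePairs:
    def test_all_distinct_empty(self):
        assert tl.recurrence_pairs(_seq("ABCDEF")) == set()

    def test_repeated_block(self):
        # 0-based pairs for A,B,C,A,B,C
        assert tl.recurrence_pairs(_seq("ABCABC")) == {(0, 3), (1, 4), (2, 5)}

    def test_alternating(self):
        assert tl.recurrence_pairs(_seq("ABAB")) == {(0, 2), (1, 3)}


class TestDet:
    def test_perfect_forward_repeat(self):
        s = tl.det(_seq("ABCABC"), minL=3)
        assert (s.recurrences, s.repeats_forward, s.det) == (3, 3, 1.0)

    def test_short_lines_do_not_count(self):
        s = tl.det(_seq("ABAB"), minL=3)
        assert (s.recurrences, s.repeats_forward, s.det) == (2, 0, 0.0)

    def test_reversed_subsequence(self):
        s = tl.det(_seq("ABCCBA"), minL=3)
        assert s.repeats_forward == 0
        assert s.repeats_reverse == 3

    def test_undefined_without_recurrences(self):
        s = tl.det(_seq("ABCDEF"), minL=3)
        assert not s.defined
        assert math.isnan(s.det)

    def test_minL_lower_bound(self):
        with pytest.raises(ValueError, match="minL"):
            tl.det(_seq("ABC"), minL=1)

    def test_both_direction_capped(self):
        s = tl.det(_seq("ABCABC"), minL=2, direction="both")
        assert s.repeats <= s.recurrences

    @given(
        st.lists(st.sampled_from("ABCD"), min_size=1, max_size=12),
        st.integers(min_value=2, max_value=4),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_window_enumeration_oracle(self, seq, minL):
        rec, fwd, rev = brute_force_repeats(seq, minL)
        s = tl.det(seq, minL=minL)
        assert s.recurrences == rec
        assert s.repeats_forward == fwd
        assert s.repeats_reverse == rev

    @given(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_repeats_bounded_by_recurrences(self, seq):
        s = tl.det(seq, minL=3)
        assert 0 <= s.repeats_forward <= s.recurrences
        assert 0 <= s.repeats_reverse <= s.recurrences


class TestMinLSensitivity:
    def test_exact_line_length_three(self):
        table = tl.minL_sensitivity([_seq("ABCABC")], [2, 3, 4])
        dets = table.set_index("minL")["det"]
        assert dets[2] == 1.0 and dets[3] == 1.0 and dets[4] == 0.0

    @given(st.lists(st.sampled_from("ABC"), min_size=4, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_det_non_increasing_in_minL(self, seq):
        table = tl.minL_sensitivity([seq], [2, 3, 4, 5])
        dets = table["det"].to_numpy()
        defined = ~np.isnan(dets)
        assert np.all(np.diff(dets[defined]) <= 1e-12)

    def test_all_distinct_undefined_everywhere(self):
        table = tl.minL_sensitivity([_seq("ABCDE")], [2, 3, 4])
        assert table["det"].isna().all()


def _records(individual, seqs, species="vervet", source="empirical"):
    return [
        TrialRecord("double_trapezoid", species, individual, t + 1, tuple(s), source, 0.0)
        for t, s in enumerate(seqs)
    ]


class TestDetForIndividual:
    def test_too_few_trials_excluded(self, caplog):
        recs = _records("v1", ["123456"] * 9)
        assert tl.det_for_individual(recs, first_n=10) is None

    def test_no_revisits_no_recurrences(self):
        recs = _records("v1", ["123456"] * 10)
        out = tl.det_for_individual(recs, first_n=10)
        assert len(out) == 10
        assert (out["recurrences"] == 0).all()

    def test_identical_trials_concatenated_det_one(self):
        recs = _records("v1", ["123456"] * 10)
        out = tl.det_for_individual(recs, mode="concatenated", first_n=10)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["recurrences"] > 0
        assert row["repeats_forward"] == row["recurrences"]

    def test_table_collects_and_excludes(self):
        df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "experiment": "double_trapezoid",
                        "species": "vervet",
                        "individual": ind,
                        "trial": range(1, n + 1),
                        "sequence": ["1-2-3-4-5-6"] * n,
                        "source": "empirical",
                        "distance": 1.0,
                    }
                )
                for ind, n in [("a", 10), ("b", 7)]
            ]
        )
        table = tl.det_table(df)
        assert set(table["individual"]) == {"a"}
        assert table.attrs["excluded"] == ["b"]


class TestCollapse:
    def test_consecutive_duplicates_dropped(self):
        assert tl.collapse_consecutive(list("112233121")) == tuple("123121")
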