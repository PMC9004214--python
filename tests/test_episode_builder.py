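"""Episode segmentation: gap-rule semantics, oracle equivalence, and IO."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oatcascade.episode_builder import (
    GapRule,
    build_all_histories,
    build_episodes,
    read_dose_records,
    summarize_history,
    write_episodes,
)
from oatcascade.errors import RowValidationError, SchemaError

from conftest import DAY0, day_scan_oracle, doses_frame, episodes_to_offsets

RULE = GapRule()


@pytest.mark.parametrize(
    "offsets, medication, expected",
    [
        # 4 dose-free days < 5 keeps one methadone episode spanning day 15
        (list(range(11)) + [15], "methadone", [(0, 15)]),
        # 5 dose-free days >= 5 splits into two attempts
        (list(range(11)) + [16], "methadone", [(0, 10), (16, 16)]),
        # buprenorphine tolerates a 5-day hole but not a 6-day one
        ([0, 6], "buprenorphine_naloxone", [(0, 6)]),
        ([0, 7], "buprenorphine_naloxone", [(0, 0), (7, 7)]),
        # a single dose is an episode of duration 1
        ([0], "methadone", [(0, 0)]),
    ],
)
def test_gap_rule_segmentation(offsets, medication, expected):
    eps = build_episodes(doses_frame(offsets, medication), RULE)
    assert episodes_to_offsets(eps) == expected
    for e in eps:
        assert e.duration_days == (e.end_date - e.start_date).days + 1
        assert e.starting_medication == medication


def test_empty_input_gives_empty_list():
    assert build_episodes(doses_frame([]), RULE) == []


def test_unknown_medication_rejected():
    df = doses_frame([0, 1])
    df.loc[1, "medication"] = "heroin"
    with pytest.raises(RowValidationError, match="unknown medication"):
        build_episodes(df, RULE)


def test_duplicate_rows_collapse_to_max_dose():
    df = pd.concat([doses_frame([0, 1], dose_mg=40.0), doses_frame([1], dose_mg=90.0)])
    eps = build_episodes(df, RULE)
    assert len(eps) == 1
    assert eps[0].peak_dose_mg == 90.0
    assert eps[0].start_dose_mg == 40.0


def test_row_order_is_irrelevant():
    offsets = [14, 0, 3, 9, 1, 22]
    base = doses_frame(offsets)
    shuffled = base.sample(frac=1.0, random_state=5).reset_index(drop=True)
    assert episodes_to_offsets(build_episodes(base, RULE)) == episodes_to_offsets(
        build_episodes(shuffled, RULE)
    )


def test_mixed_medication_gap_follows_most_recent_dose():
    # last dose before the hole is buprenorphine -> 6-day gap applies,
    # so a 5-day hole does not split even though methadone appears earlier
    df = doses_frame([(0, "methadone"), (1, "buprenorphine_naloxone"), (7, "methadone")])
    assert len(build_episodes(df, RULE)) == 1
    # last dose methadone -> 5-day hole splits
    df2 = doses_frame([(0, "buprenorphine_naloxone"), (1, "methadone"), (7, "methadone")])
    assert len(build_episodes(df2, RULE)) == 2


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=59),
            st.sampled_from(["methadone", "buprenorphine_naloxone"]),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_matches_day_scan_oracle(dose_days):
    """Vectorized segmentation agrees exactly with the brute-force day scan."""
    eps = build_episodes(doses_frame(dose_days), RULE)
    assert episodes_to_offsets(eps) == day_scan_oracle(dose_days, RULE)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=15),
    st.integers(min_value=1, max_value=10),
)
def test_concatenation_property(offsets, extra):
    """A dose within gap-1 days of the last episode's end never adds an
    attempt; a dose gap-or-more days out adds exactly one."""
    eps = build_episodes(doses_frame(offsets), RULE)
    last_end = max(offsets)
    gap = RULE.methadone_gap_days

    close = build_episodes(doses_frame(offsets + [last_end + gap]), RULE)  # gap-1 free days
    assert len(close) == len(eps)
    far = build_episodes(doses_frame(offsets + [last_end + gap + extra]), RULE)
    assert len(far) == len(eps) + 1


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=59),
            st.sampled_from(["methadone", "buprenorphine_naloxone"]),
        ),
        min_size=1,
        max_size=25,
    )
)
def test_episodes_partition_dose_dates(dose_days):
    """Every dose date falls inside exactly one episode span, and episode
    boundaries are themselves dose dates."""
    eps = build_episodes(doses_frame(dose_days), RULE)
    spans = episodes_to_offsets(eps)
    dose_offsets = {d for d, _ in dose_days}
    for off in dose_offsets:
        containing = [s for s in spans if s[0] <= off <= s[1]]
        assert len(containing) == 1
    for s, e in spans:
        assert s in dose_offsets and e in dose_offsets


class TestHistory:
    def test_attempts_and_longest_retention(self):
        eps = build_episodes(doses_frame(list(range(11)) + [16]), RULE)
        h = summarize_history(eps)
        assert h.n_attempts == 2
        assert h.longest_retention_days == 11
        assert h.first_initiation_date == DAY0

    def test_admin_ltfu_boundary(self):
        eps = build_episodes(doses_frame([0, 1, 2]), RULE)
        h = summarize_history(eps)
        assert h.admin_ltfu(study_end=DAY0 + timedelta(days=2)) is False
        assert h.admin_ltfu(study_end=DAY0 + timedelta(days=102)) is True

    def test_empty_episode_list_is_an_error(self):
        with pytest.raises(ValueError, match="no episodes"):
            summarize_history([])

    def test_doses_after_study_end_are_dropped(self):
        df = doses_frame([0, 1, 2, 50])
        hists = build_all_histories(df, RULE, study_end=DAY0 + timedelta(days=10))
        assert hists["p1"].episodes[-1].end_date <= DAY0 + timedelta(days=10)


class TestIO:
    def _write(self, tmp_path, text):
        p = tmp_path / "doses.csv"
        p.write_text(text)
        return p

    def test_round_trip(self, tmp_path):
        p = self._write(
            tmp_path,
            "patient_id,date,medication,dose_mg\n"
            "p1,2015-01-01,methadone,30\n"
            "p1,2015-01-02,methadone,35\n"
            "p2,2015-03-01,buprenorphine_naloxone,8\n",
        )
        df = read_dose_records(p)
        assert len(df) == 3
        assert df["date"].dt.year.tolist() == [2015, 2015, 2015]

    def test_duplicate_row_deduplicated(self, tmp_path, caplog):
        p = self._write(
            tmp_path,
            "patient_id,date,medication,dose_mg\n"
            "p1,2015-01-01,methadone,30\n"
            "p1,2015-01-01,methadone,40\n",
        )
        with caplog.at_level("WARNING"):
            df = read_dose_records(p)
        assert len(df) == 1
        assert df["dose_mg"].iloc[0] == 40
        assert any("deduplicated 1" in r.message for r in caplog.records)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = self._write(tmp_path, "patient_id,date,med,dose_mg\np1,2015-01-01,methadone,30\n")
        with pytest.raises(SchemaError, match="medication"):
            read_dose_records(p)

    def test_bad_date_reports_row_number(self, tmp_path):
        p = self._write(
            tmp_path,
            "patient_id,date,medication,dose_mg\n"
            "p1,2015-01-01,methadone,30\n"
            "p1,01/02/2015,methadone,30\n",
        )
        with pytest.raises(RowValidationError, match=r"1 unparseable date\(s\) at row\(s\) \[2\]"):
            read_dose_records(p)

    def test_write_episodes(self, tmp_path):
        hists = build_all_histories(doses_frame(list(range(5))), RULE)
        out = tmp_path / "episodes.csv"
        df = write_episodes(out, hists)
        back = pd.read_csv(out)
        assert len(back) == len(df) == 1
        assert back["duration_days"].iloc[0] == 5
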