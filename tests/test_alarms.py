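"""Cut-off tables, age grouping, episode detection and alarm summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alarmscape as asc
from alarmscape.series import VitalSeries

from conftest import brute_force_episodes


@pytest.mark.parametrize(
    ("org", "group", "signal", "expected_lower", "expected_upper"),
    [
        ("WHO", "<1 year", "ECGHR", 100, 160),
        ("WHO", "<1 year", "ECGRR", 20, 50),
        ("WHO", "1-3 years", "ECGHR", 90, 150),
        ("WHO", "3-4 years", "ECGHR", 80, 140),
        ("WHO", "3-4 years", "ECGRR", 10, 40),
        ("GOAL3", "<1 year", "ECGHR", 80, 200),
        ("GOAL3", "1-3 years", "ECGHR", 80, 180),
        ("GOAL3", "1-3 years", "ECGRR", 20, 50),
        ("GOAL3", ">4 years", "ECGHR", 70, 170),
        ("GOAL3", ">4 years", "ECGRR", 20, 40),
    ],
)
def test_builtin_cutoff_limits(org, group, signal, expected_lower, expected_upper):
    table = asc.builtin_cutoffs(org)
    band = next(b for b in table.bands if b.key == group)
    assert band.limits[signal] == (expected_lower, expected_upper)


def test_spo2_has_lower_limit_only_at_90():
    for org in ("WHO", "GOAL3"):
        for band in asc.builtin_cutoffs(org).bands:
            assert band.limits["SPO2"] == (90, None)


def test_unknown_organization_names_valid_options():
    with pytest.raises(ValueError, match="WHO, GOAL3"):
        asc.builtin_cutoffs("NICE")


def test_age_group_assignment_half_open_boundaries(who_table, goal3_table):
    assert asc.assign_age_group(6, who_table) == "<1 year"
    assert asc.assign_age_group(12, who_table) == "1-3 years"  # exactly 1 year
    assert asc.assign_age_group(36, who_table) == "3-4 years"
    assert asc.assign_age_group(40, goal3_table) == "3-4 years"
    assert asc.assign_age_group(48, goal3_table) == ">4 years"


def test_who_top_band_extends_beyond_four_years_with_warning(who_table):
    with pytest.warns(UserWarning, match="extended top band"):
        assert asc.assign_age_group(72, who_table) == "3-4 years"


def _series(signal, values, timestamps=None):
    values = np.asarray(values, dtype=float)
    ts = np.arange(len(values)) if timestamps is None else np.asarray(timestamps)
    return VitalSeries("p1", ts, {signal: values})


class TestDetectEpisodes:
    def test_in_range_series_yields_no_episodes(self, who_table):
        assert asc.detect_episodes(_series("ECGHR", [120] * 10), 6, who_table) == []

    def test_boundary_value_is_normal_not_alarm(self, who_table):
        # violation is strict: exactly at the limit does not alarm
        eps = asc.detect_episodes(_series("ECGHR", [160, 100, 160]), 6, who_table)
        assert eps == []

    def test_single_upper_run_duration_and_median(self, who_table):
        eps = asc.detect_episodes(
            _series("ECGHR", [150, 165, 170, 168, 150]), 6, who_table
        )
        assert len(eps) == 1
        ep = eps[0]
        assert (ep.bound, ep.start, ep.end) == ("upper", 1, 3)
        assert ep.duration == 3.0
        assert ep.rep_value == 168.0
        assert ep.cutoff == 160

    def test_missing_sample_splits_run(self, who_table):
        eps = asc.detect_episodes(
            _series("SPO2", [92, 88, np.nan, 87, 92]), 6, who_table
        )
        assert [(e.bound, e.duration, e.rep_value) for e in eps] == [
            ("lower", 1.0, 88.0),
            ("lower", 1.0, 87.0),
        ]

    def test_timestamp_gap_splits_run(self, who_table):
        eps = asc.detect_episodes(
            _series("SPO2", [85, 85, 85], timestamps=[0, 1, 5]), 6, who_table
        )
        assert [(e.start, e.duration) for e in eps] == [(0, 2.0), (5, 1.0)]

    def test_empty_and_all_missing_series(self, who_table):
        empty = VitalSeries("p", np.array([], dtype=int), {"ECGHR": []})
        assert asc.detect_episodes(empty, 6, who_table) == []
        gone = _series("ECGHR", [np.nan] * 5)
        assert asc.detect_episodes(gone, 6, who_table) == []

    def test_rep_value_variants(self, who_table):
        s = _series("ECGHR", [150, 165, 170, 180, 150])
        extremum = asc.detect_episodes(s, 6, who_table, rep="extremum")[0]
        mean = asc.detect_episodes(s, 6, who_table, rep="mean")[0]
        assert extremum.rep_value == 180.0
        assert mean.rep_value == pytest.approx((165 + 170 + 180) / 3)

    def test_single_violating_sample_has_one_second_duration(self, who_table):
        eps = asc.detect_episodes(_series("ECGRR", [30, 55, 30]), 6, who_table)
        assert len(eps) == 1 and eps[0].duration == 1.0


def _random_series(rng, n):
    """Random short SPO2-free series with NaNs and timestamp gaps."""
    ts = np.cumsum(rng.integers(1, 4, size=n))
    values = rng.normal(120, 40, size=n)
    values[rng.random(n) < 0.2] = np.nan
    return ts, values


def test_detection_matches_brute_force_scan(who_table):
    """Vectorized episode detection equals a naive per-sample run grouper on
    short random series with gaps and missing samples."""
    rng = np.random.default_rng(42)
    band = who_table.band_for_age(6)
    lower, upper = band.limits["ECGHR"]
    for _ in range(200):
        n = int(rng.integers(1, 51))
        ts, values = _random_series(rng, n)
        series = VitalSeries("p", ts, {"ECGHR": values})
        got = [
            (e.bound, e.start, e.end, e.duration)
            for e in asc.detect_episodes(series, 6, who_table)
        ]
        expected = [
            (bound, int(ts[i0]), int(ts[i1]), float(i1 - i0 + 1))
            for bound, i0, i1 in brute_force_episodes(ts, values, lower, upper)
        ]
        assert got == sorted(expected, key=lambda t: t[1])


@settings(deadline=None, max_examples=60)
@given(
    values=st.lists(
        st.one_of(st.floats(min_value=40, max_value=220), st.none()),
        min_size=1,
        max_size=60,
    ),
    age=st.sampled_from([3.0, 20.0, 40.0]),
)
def test_conservation_and_disjointness(values, age):
    """Episode sample counts sum to the violating-sample count, and episodes
    on a (signal, bound) never overlap in time."""
    table = asc.builtin_cutoffs("WHO")
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    series = _series("ECGHR", arr)
    lower, upper = table.band_for_age(age).limits["ECGHR"]
    eps = asc.detect_episodes(series, age, table)
    with np.errstate(invalid="ignore"):
        n_upper = int(np.nansum(arr > upper))
        n_lower = int(np.nansum(arr < lower))
    for bound, n_expected in (("upper", n_upper), ("lower", n_lower)):
        members = [e for e in eps if e.bound == bound]
        assert sum(int(e.duration) for e in members) == n_expected
        spans = sorted((e.start, e.end) for e in members)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # disjoint and separated


@settings(deadline=None, max_examples=40)
@given(
    values=st.lists(st.floats(min_value=40, max_value=220), min_size=1, max_size=60),
    relax=st.integers(min_value=0, max_value=40),
)
def test_relaxing_cutoffs_is_monotone(values, relax):
    """Raising the upper limit never increases the violating-sample count."""
    arr = np.asarray(values)
    base = int(np.sum(arr > 150))
    relaxed = int(np.sum(arr > 150 + relax))
    assert relaxed <= base


class TestSummaries:
    def test_single_episode_is_its_whole_stratum(self):
        frame = asc.episodes_to_frame(
            asc.detect_episodes(_series("ECGRR", [30, 55, 30]), 6, asc.builtin_cutoffs("WHO"))
        )
        manifest = pd.DataFrame({"patient_id": ["p1"], "cie_type": ["none"]})
        table = asc.summarize_alarms(frame, manifest)["WHO"]
        assert table.loc["without_cie", "total"] == 1
        assert table.loc["without_cie", "pct_ecgrr"] == 100

    def test_empty_input_gives_zero_table(self):
        manifest = pd.DataFrame({"patient_id": ["p1"], "cie_type": ["none"]})
        tables = asc.summarize_alarms(asc.episodes_to_frame([]), manifest)
        for table in tables.values():
            assert table["total"].sum() == 0

    def test_stratum_percentages_round_to_int(self):
        counts = pd.DataFrame(
            {"ECGHR": [1, 0], "ECGRR": [1, 0], "SPO2": [1, 0]},
            index=["without_cie", "with_cie"],
        )
        table = asc.tabulate_counts(counts)
        assert table.loc["without_cie", "pct_ecghr"] == 33
        assert table.loc["all", "total"] == 3
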