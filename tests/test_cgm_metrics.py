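"""CGM metric operations against hand values and brute-force references."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycovar import (
    ClockWindow,
    WINDOW_24H,
    WINDOW_DIURNAL,
    WINDOW_NOCTURNAL,
    conga,
    glucose_range,
    modd,
    read_cgm_csv,
    sd_24h,
    summarize,
    trim_to_analysis_days,
    window_mean,
)
from conftest import MIDNIGHT, make_series, random_series

# ---------------------------------------------------------------------------
# brute-force reference implementations (independent of the module's
# vectorised code paths: explicit loops, two-pass variance)


def ref_sd(values):
    v = [x for x in values if not np.isnan(x)]
    if len(v) < 2:
        return float("nan")
    m = sum(v) / len(v)
    return (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5


def ref_window_mean(series, window, min_coverage=0.7):
    cm = series.clock_minutes
    picked = []
    n_slots = 0
    for i in range(series.n_samples):
        c = cm[i]
        if window.wraps_midnight:
            inside = c >= window.start_minute or c < window.end_minute
        else:
            inside = window.start_minute <= c < window.end_minute
        if inside:
            n_slots += 1
            if not np.isnan(series.values[i]):
                picked.append(series.values[i])
    if n_slots == 0 or len(picked) / n_slots < min_coverage:
        return float("nan")
    return sum(picked) / len(picked)


def ref_conga(series, lag_hours=4):
    lag = int(lag_hours * 60 / series.interval)
    diffs = []
    for t in range(lag, series.n_samples):
        a, b = series.values[t], series.values[t - lag]
        if not (np.isnan(a) or np.isnan(b)):
            diffs.append(a - b)
    return ref_sd(diffs)


def ref_modd(series):
    days = sorted(set(series.day_index.tolist()))
    slots = series.clock_minutes // series.interval
    diffs = []
    for d0, d1 in zip(days[:-1], days[1:]):
        if d1 - d0 != 1:
            continue
        for i in range(series.n_samples):
            if series.day_index[i] != d1:
                continue
            for j in range(series.n_samples):
                if series.day_index[j] == d0 and slots[j] == slots[i]:
                    a, b = series.values[i], series.values[j]
                    if not (np.isnan(a) or np.isnan(b)):
                        diffs.append(abs(a - b))
    if not diffs:
        return float("nan")
    return sum(diffs) / len(diffs)


def ref_range(series):
    v = sorted(x for x in series.values if not np.isnan(x))
    return v[-1] - v[0] if v else float("nan")


# ---------------------------------------------------------------------------
# golden hand-computed values


def test_sd_of_three_values():
    s = make_series([4, 5, 6], trimmed=True)
    assert sd_24h(s) == pytest.approx(1.0, abs=1e-12)


def test_conga_lag2_hourly_golden():
    """Hourly [5,6,5,7,6], lag 2 h -> differences [0,1,1], SD = 0.5774."""
    s = make_series([5, 6, 5, 7, 6], interval=60, trimmed=True)
    assert conga(s, lag_hours=2) == pytest.approx(0.5774, abs=5e-5)


def test_modd_two_day_golden():
    """day1=[5,6,7], day2=[5.5,6.5,6.5] at the same clock slots -> 0.5."""
    vals = np.full(2 * 288, np.nan)
    vals[0:3] = [5, 6, 7]
    vals[288:291] = [5.5, 6.5, 6.5]
    s = make_series(vals, trimmed=True)
    assert modd(s) == pytest.approx(0.5, abs=1e-12)


def test_range_golden():
    s = make_series([3.9, 5.0, 8.9], trimmed=True)
    assert glucose_range(s) == pytest.approx(5.0, abs=1e-12)


def test_constant_series_statistics():
    s = make_series(np.full(3 * 288, 5.0), trimmed=True)
    summ = summarize(s)
    assert summ.mean_24h == pytest.approx(5.0)
    assert summ.mean_nocturnal == pytest.approx(5.0)
    assert summ.mean_diurnal == pytest.approx(5.0)
    for f in ("sd_24h", "conga4", "modd", "range"):
        assert getattr(summ, f) == pytest.approx(0.0, abs=1e-12)


def test_piecewise_constant_nocturnal_mean():
    vals = np.full(3 * 288, 6.0)
    s0 = make_series(vals, trimmed=True)
    noct = WINDOW_NOCTURNAL.contains(s0.clock_minutes)
    vals[noct] = 4.0
    s = make_series(vals, trimmed=True)
    assert window_mean(s, WINDOW_NOCTURNAL) == pytest.approx(4.0)
    assert window_mean(s, WINDOW_DIURNAL) == pytest.approx(6.0)


def test_conga_sinusoid_against_numeric_oracle(rng):
    """Pure 24-h sinusoid: CONGA equals the SD of the sampled lagged diffs."""
    t = np.arange(3 * 288) * 5 / 60.0
    vals = 6.0 + 1.5 * np.sin(2 * np.pi * t / 24.0)
    s = make_series(vals, trimmed=True)
    assert conga(s, 4) == pytest.approx(ref_conga(s, 4), rel=1e-12)


# ---------------------------------------------------------------------------
# randomized equivalence with the brute-force references


@pytest.mark.parametrize("missing", [0.0, 0.2])
def test_metrics_match_bruteforce_references(rng, missing):
    for _ in range(5):
        s = random_series(rng, n_days=3, missing=missing)
        assert sd_24h(s) == pytest.approx(ref_sd(s.values), rel=1e-12)
        assert conga(s, 4) == pytest.approx(ref_conga(s, 4), rel=1e-12)
        assert modd(s) == pytest.approx(ref_modd(s), rel=1e-12)
        assert glucose_range(s) == pytest.approx(ref_range(s), rel=1e-12)
        for w in (WINDOW_24H, WINDOW_NOCTURNAL, WINDOW_DIURNAL):
            got, want = window_mean(s, w), ref_window_mean(s, w)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


# ---------------------------------------------------------------------------
# invariance properties


def test_shift_invariance(rng):
    s = random_series(rng, missing=0.1)
    shifted = make_series(s.values + 2.5, trimmed=True)
    for w in (WINDOW_24H, WINDOW_NOCTURNAL, WINDOW_DIURNAL):
        assert window_mean(shifted, w) == pytest.approx(
            window_mean(s, w) + 2.5, abs=1e-9
        )
    assert sd_24h(shifted) == pytest.approx(sd_24h(s), abs=1e-9)
    assert conga(shifted, 4) == pytest.approx(conga(s, 4), abs=1e-9)
    assert modd(shifted) == pytest.approx(modd(s), abs=1e-9)
    assert glucose_range(shifted) == pytest.approx(glucose_range(s), abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(
        st.floats(min_value=2.0, max_value=20.0), min_size=5, max_size=200
    ),
    c=st.floats(min_value=-1.5, max_value=3.0),
)
def test_shift_invariance_property(values, c):
    """For arbitrary physiologic traces, adding c shifts every window mean
    by c and leaves the four variability statistics unchanged."""
    s = make_series(values, trimmed=True)
    t = make_series(np.asarray(values) + c, trimmed=True)
    assert window_mean(t, WINDOW_24H) == pytest.approx(
        window_mean(s, WINDOW_24H) + c, abs=1e-9
    )
    for f, args in ((sd_24h, ()), (conga, (1,)), (modd, ()), (glucose_range, ())):
        a, b = f(s, *args), f(t, *args)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(a, abs=1e-9)


def test_scale_equivariance(rng):
    s = random_series(rng, missing=0.1)
    k = 1.8
    scaled = make_series(s.values * k, trimmed=True)
    a, b = summarize(s), summarize(scaled)
    for f in (
        "mean_24h",
        "mean_nocturnal",
        "mean_diurnal",
        "sd_24h",
        "conga4",
        "modd",
        "range",
    ):
        assert getattr(b, f) == pytest.approx(k * getattr(a, f), rel=1e-9)


# ---------------------------------------------------------------------------
# trimming


def test_trim_five_days_keeps_72h():
    s = make_series(np.full(5 * 288, 5.0))
    t = trim_to_analysis_days(s)
    assert t.n_samples == 3 * 288
    assert t.start == MIDNIGHT + pd.Timedelta(days=1)
    assert sorted(set(t.day_index.tolist())) == [0, 1, 2]


def test_trim_idempotent_on_five_day_input():
    s = make_series(np.full(5 * 288, 5.0))
    once = trim_to_analysis_days(s)
    twice = trim_to_analysis_days(once)
    assert twice.n_samples == once.n_samples
    np.testing.assert_array_equal(twice.values, once.values)


def test_trim_three_day_series_warns_and_keeps_middle_day():
    s = make_series(np.full(3 * 288, 5.0))
    with pytest.warns(UserWarning, match="one analysis day"):
        t = trim_to_analysis_days(s)
    assert t.n_samples == 288


def test_trim_two_day_series_errors():
    s = make_series(np.full(2 * 288, 5.0))
    with pytest.raises(ValueError, match="insufficient monitoring data"):
        trim_to_analysis_days(s)


# ---------------------------------------------------------------------------
# missingness rules


def test_missing_nocturnal_window_only_drops_that_metric():
    vals = np.full(3 * 288, 5.0)
    s0 = make_series(vals, trimmed=True)
    vals[WINDOW_NOCTURNAL.contains(s0.clock_minutes)] = np.nan
    s = make_series(vals, trimmed=True)
    summ = summarize(s)
    assert np.isnan(summ.mean_nocturnal)
    assert summ.mean_24h == pytest.approx(5.0)
    assert summ.mean_diurnal == pytest.approx(5.0)
    assert summ.range == pytest.approx(0.0)


def test_window_mean_coverage_threshold():
    vals = np.full(288, np.nan)
    noct = WINDOW_NOCTURNAL.contains(make_series(vals, trimmed=True).clock_minutes)
    idx = np.flatnonzero(noct)
    vals[idx[: int(0.5 * idx.size)]] = 5.0  # 50% coverage < 70%
    s = make_series(vals, trimmed=True)
    assert np.isnan(window_mean(s, WINDOW_NOCTURNAL, min_coverage=0.7))
    assert window_mean(s, WINDOW_NOCTURNAL, min_coverage=0.4) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# CSV parsing


def _csv(text: str) -> io.StringIO:
    return io.StringIO("participant_id,timestamp,glucose\n" + text)


def test_read_two_participants():
    txt = "".join(
        f"A,2024-01-01T00:{m:02d}:00,5.0\n" for m in (0, 5, 10)
    ) + "".join(f"B,2024-01-01T00:{m:02d}:00,6.0\n" for m in (0, 5, 10))
    series = read_cgm_csv(_csv(txt))
    assert [s.participant_id for s in series] == ["A", "B"]
    assert all(s.n_samples == 3 for s in series)


def test_duplicate_grid_slot_keeps_first(caplog):
    txt = (
        "A,2024-01-01T00:00:00,5.0\n"
        "A,2024-01-01T00:01:00,9.0\n"  # rounds to slot 0 again
        "A,2024-01-01T00:05:00,6.0\n"
    )
    with caplog.at_level("WARNING"):
        (s,) = read_cgm_csv(_csv(txt))
    assert s.values[0] == 5.0
    assert "duplicate" in caplog.text


def test_gap_becomes_missing_slot():
    txt = "A,2024-01-01T00:00:00,5.0\nA,2024-01-01T00:10:00,6.0\n"
    (s,) = read_cgm_csv(_csv(txt))
    assert s.n_samples == 3
    assert np.isnan(s.values[1])


def test_out_of_range_glucose_dropped(caplog):
    txt = "A,2024-01-01T00:00:00,5.0\nA,2024-01-01T00:05:00,45.0\n"
    with caplog.at_level("WARNING"):
        (s,) = read_cgm_csv(_csv(txt))
    assert s.n_samples == 1


def test_malformed_timestamp_hard_error():
    txt = "A,2024-01-01T00:00:00,5.0\nA,not-a-time,5.0\n"
    with pytest.raises(ValueError, match="row 3"):
        read_cgm_csv(_csv(txt))


def test_physiologic_bounds_enforced_on_series():
    with pytest.raises(ValueError, match="physiologic"):
        make_series([5.0, 41.0])


def test_clock_window_wrapping():
    w = ClockWindow(23 * 60, 60)  # 23:00-01:00
    assert w.wraps_midnight
    cm = np.array([0, 30, 60, 12 * 60, 23 * 60])
    np.testing.assert_array_equal(
        w.contains(cm), [True, True, False, False, True]
    )
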