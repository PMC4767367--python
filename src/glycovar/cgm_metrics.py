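"""Per-participant glycemia and glycemic-variability statistics from CGM traces.

A continuous glucose monitor samples interstitial glucose on a nominal
5-minute grid for several days. This module parses long-format CSV traces,
snaps them to the grid, drops the first and last (least accurate) recording
days, and computes the seven per-participant summary statistics used in the
analysis:

glycemia
    mean 24-h glucose, mean nocturnal glucose (3:00-6:00), mean diurnal
    glucose (6:00-24:00) -- all window means pooled across analysis days.

glycemic variability
    24-h SD (pooled sample SD over the trimmed record), CONGA-4 (SD of
    differences between each observation and the observation 4 h earlier),
    MODD (mean absolute difference between values at the same clock time on
    consecutive days) and range (max - min).

All glucose values are in mmol/L. Missing samples are explicit NaN slots on
the grid; each statistic skips them according to its own rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

#: physiologic sanity bounds on interstitial glucose, mmol/L (exclusive)
GLUCOSE_MIN = 0.0
GLUCOSE_MAX = 40.0

#: default fraction of a window's grid slots that must be valid for its mean
DEFAULT_MIN_COVERAGE = 0.7


@dataclass(frozen=True)
class ClockWindow:
    """Half-open window of clock time, [start, end), possibly wrapping midnight.

    Times are minutes since midnight; ``end == 1440`` with ``start == 0``
    denotes the full day.
    """

    start_minute: int
    end_minute: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_minute < MINUTES_PER_DAY):
            raise ValueError(f"start_minute {self.start_minute} out of range")
        if not (0 < self.end_minute <= MINUTES_PER_DAY):
            raise ValueError(f"end_minute {self.end_minute} out of range")
        if self.start_minute == self.end_minute:
            raise ValueError("degenerate window; use (0, 1440) for full day")

    @property
    def wraps_midnight(self) -> bool:
        return self.end_minute < self.start_minute

    def contains(self, clock_minutes: np.ndarray) -> np.ndarray:
        """Boolean mask over clock times (minutes since midnight)."""
        cm = np.asarray(clock_minutes)
        if self.wraps_midnight:
            return (cm >= self.start_minute) | (cm < self.end_minute)
        return (cm >= self.start_minute) & (cm < self.end_minute)

    @property
    def n_minutes(self) -> int:
        if self.wraps_midnight:
            return MINUTES_PER_DAY - self.start_minute + self.end_minute
        return self.end_minute - self.start_minute


#: the analysis windows: full day, nocturnal 3:00-6:00, diurnal 6:00-24:00.
#: 0:00-3:00 deliberately belongs to neither the nocturnal nor the diurnal
#: window; that gap is part of the analysis definition and is reproduced.
WINDOW_24H = ClockWindow(0, MINUTES_PER_DAY)
WINDOW_NOCTURNAL = ClockWindow(3 * 60, 6 * 60)
WINDOW_DIURNAL = ClockWindow(6 * 60, MINUTES_PER_DAY)


@dataclass
class CgmSeries:
    """One participant's glucose trace aligned to a fixed sampling grid.

    ``values`` holds glucose in mmol/L with NaN for missing slots; slot ``i``
    is at ``start + i * interval`` minutes. ``day_index`` counts calendar days
    from the first sample's calendar date.
    """

    participant_id: str
    start: pd.Timestamp
    interval: int  # minutes
    values: np.ndarray
    day_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    trimmed: bool = False

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        self.values = np.asarray(self.values, dtype=float)
        v = self.values[~np.isnan(self.values)]
        if v.size and (v.min() <= GLUCOSE_MIN or v.max() >= GLUCOSE_MAX):
            raise ValueError(
                f"{self.participant_id}: glucose outside physiologic bounds "
                f"({GLUCOSE_MIN}, {GLUCOSE_MAX}) mmol/L"
            )
        if self.day_index is None:
            self.day_index = self._compute_day_index()
        else:
            self.day_index = np.asarray(self.day_index, dtype=int)
            if self.day_index.shape != self.values.shape:
                raise ValueError("day_index and values must align")

    def _compute_day_index(self) -> np.ndarray:
        start_min = self.start.hour * 60 + self.start.minute
        abs_minutes = start_min + np.arange(self.values.size) * self.interval
        return (abs_minutes // MINUTES_PER_DAY).astype(int)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    @property
    def fraction_missing(self) -> float:
        if self.values.size == 0:
            return float("nan")
        return float(np.mean(np.isnan(self.values)))

    @property
    def clock_minutes(self) -> np.ndarray:
        """Minutes since midnight for every slot."""
        start_min = self.start.hour * 60 + self.start.minute
        return (start_min + np.arange(self.values.size) * self.interval) % MINUTES_PER_DAY

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.values.size) * self.interval, unit="m"
        )


@dataclass
class GlycemicSummary:
    """The seven per-participant CGM statistics (NaN where not computable)."""

    participant_id: str
    mean_24h: float
    mean_nocturnal: float
    mean_diurnal: float
    sd_24h: float
    conga4: float
    modd: float
    range: float
    n_valid_samples: int
    fraction_missing: float

    METRIC_FIELDS = (
        "mean_24h",
        "mean_nocturnal",
        "mean_diurnal",
        "sd_24h",
        "conga4",
        "modd",
        "range",
    )


# ---------------------------------------------------------------------------
# parsing


def read_cgm_csv(path, expected_interval: int = 5) -> list[CgmSeries]:
    """Read a long-format CGM CSV into one grid-aligned series per participant.

    Columns: ``participant_id, timestamp, glucose`` (mmol/L; ISO-8601
    timestamps). Each participant's timestamps are snapped to the nominal
    grid anchored at clock multiples of ``expected_interval`` (tolerance half
    an interval). When two rows land in the same grid slot the first is kept
    and a warning logged; interior gaps become explicit NaN slots. Rows with
    glucose outside the physiologic bounds are dropped and logged; a
    malformed timestamp is a hard error naming the row.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "timestamp", "glucose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CGM CSV missing columns: {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: header line and 1-based numbering
        raise ValueError(
            f"malformed timestamp at row {bad[0] + 2}: "
            f"{df['timestamp'].iloc[bad[0]]!r}"
        )
    df = df.assign(_ts=ts)

    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    out_of_range = (
        glucose.isna() | (glucose <= GLUCOSE_MIN) | (glucose >= GLUCOSE_MAX)
    )
    if out_of_range.any():
        n_bad = int(out_of_range.sum())
        logger.warning(
            "dropping %d rows with glucose outside (%g, %g) mmol/L",
            n_bad,
            GLUCOSE_MIN,
            GLUCOSE_MAX,
        )
        df = df.loc[~out_of_range.to_numpy()]
        glucose = glucose.loc[~out_of_range.to_numpy()]
    df = df.assign(_glucose=glucose)

    series: list[CgmSeries] = []
    step = pd.Timedelta(minutes=expected_interval)
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("_ts")
        # snap each timestamp to the nearest grid slot (grid anchored at
        # clock multiples of the interval)
        snapped = grp["_ts"].dt.round(step)
        slots = ((snapped - snapped.iloc[0]) / step).round().astype(int).to_numpy()
        keep = np.ones(slots.size, dtype=bool)
        dup = np.flatnonzero(np.diff(slots) == 0)
        if dup.size:
            keep[dup + 1] = False
            logger.warning(
                "%s: %d duplicate grid slots, keeping first occurrence",
                pid,
                dup.size,
            )
        slots = slots[keep]
        vals = grp["_glucose"].to_numpy()[keep]
        n_slots = slots[-1] + 1 if slots.size else 0
        grid = np.full(n_slots, np.nan)
        grid[slots] = vals
        series.append(
            CgmSeries(
                participant_id=str(pid),
                start=snapped.iloc[0],
                interval=expected_interval,
                values=grid,
            )
        )
    return series


def write_summary_csv(summaries: list[GlycemicSummary], path) -> pd.DataFrame:
    """Write one row per participant with all summary fields; returns the frame."""
    rows = [
        {
            "participant_id": s.participant_id,
            **{f: getattr(s, f) for f in GlycemicSummary.METRIC_FIELDS},
            "n_valid_samples": s.n_valid_samples,
            "fraction_missing": s.fraction_missing,
        }
        for s in summaries
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.10g")
    return frame


# ---------------------------------------------------------------------------
# trimming


def trim_to_analysis_days(series: CgmSeries) -> CgmSeries:
    """Drop the first and last recorded calendar day (sensor run-in/run-out).

    For a 5-day recording this retains days 2-4, i.e. the 72-h analysis span.
    Calendar-day boundaries are local midnight. Idempotent: an
    already-trimmed series is returned unchanged, so the retained span is
    stable under re-application.
    """
    if series.trimmed:
        return series
    days = np.unique(series.day_index)
    if days.size < 3:
        raise ValueError(
            f"{series.participant_id}: insufficient monitoring data "
            f"({days.size} calendar days, need >= 3)"
        )
    keep = (series.day_index != days[0]) & (series.day_index != days[-1])
    if not keep.any():
        raise ValueError(f"{series.participant_id}: insufficient monitoring data")
    if days.size == 3:
        warnings.warn(
            f"{series.participant_id}: only one analysis day remains after "
            "trimming; interday statistics will be missing",
            stacklevel=2,
        )
    first = int(np.flatnonzero(keep)[0])
    last = int(np.flatnonzero(keep)[-1])
    new_start = series.start + pd.Timedelta(minutes=first * series.interval)
    new_day = series.day_index[first : last + 1]
    return CgmSeries(
        participant_id=series.participant_id,
        start=new_start,
        interval=series.interval,
        values=series.values[first : last + 1].copy(),
        day_index=new_day - new_day[0],
        trimmed=True,
    )


# ---------------------------------------------------------------------------
# statistics


def window_mean(
    series: CgmSeries,
    window: ClockWindow,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> float:
    """Mean glucose over a clock window, pooled across all analysis days.

    Returns NaN (missing) when fewer than ``min_coverage`` of the window's
    grid slots hold a valid sample.
    """
    mask = window.contains(series.clock_minutes)
    in_win = series.values[mask]
    if in_win.size == 0:
        return float("nan")
    valid = ~np.isnan(in_win)
    coverage = valid.mean()
    if coverage < min_coverage:
        logger.info(
            "%s: window [%d,%d) coverage %.2f below %.2f -> missing",
            series.participant_id,
            window.start_minute,
            window.end_minute,
            coverage,
            min_coverage,
        )
        return float("nan")
    return float(in_win[valid].mean())


def sd_24h(series: CgmSeries, per_day_average: bool = False) -> float:
    """Sample SD (n-1) of glucose over the trimmed record.

    Default is one pooled SD over the full 72-h record; ``per_day_average``
    instead averages the per-calendar-day SDs (the alternative reading of a
    daily SD metric).
    """
    if per_day_average:
        sds = []
        for d in np.unique(series.day_index):
            v = series.values[series.day_index == d]
            v = v[~np.isnan(v)]
            if v.size >= 2:
                sds.append(np.std(v, ddof=1))
        return float(np.mean(sds)) if sds else float("nan")
    v = series.values[~np.isnan(series.values)]
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1))


def conga(series: CgmSeries, lag_hours: float = 4) -> float:
    """Continuous overlapping net glycemic action (intraday variability).

    For every observation with a valid partner ``lag_hours`` earlier, take
    the difference current − lagged; CONGA is the sample SD (n−1) of those
    differences. Pairs with either member missing are skipped.
    """
    lag_slots = lag_hours * 60 / series.interval
    if abs(lag_slots - round(lag_slots)) > 1e-9:
        raise ValueError("lag must be a whole number of sampling intervals")
    lag = int(round(lag_slots))
    if lag <= 0 or series.n_samples <= lag:
        return float("nan")
    d = series.values[lag:] - series.values[:-lag]
    d = d[~np.isnan(d)]
    if d.size < 2:
        return float("nan")
    return float(np.std(d, ddof=1))


def modd(series: CgmSeries) -> float:
    """Mean of daily differences (interday variability).

    For each pair of consecutive calendar days and each grid slot valid on
    both, accumulate the absolute difference between the two days' values at
    that slot; return the mean over all accumulated pairs, pooled across all
    consecutive-day pairs. "Same time of day" means the same grid slot; no
    interpolation.
    """
    days = np.unique(series.day_index)
    if days.size < 2:
        return float("nan")
    slot_in_day = series.clock_minutes // series.interval
    diffs: list[np.ndarray] = []
    for d0, d1 in zip(days[:-1], days[1:]):
        if d1 - d0 != 1:  # non-adjacent calendar days: not "consecutive"
            continue
        m0 = series.day_index == d0
        m1 = series.day_index == d1
        s0 = pd.Series(series.values[m0], index=slot_in_day[m0])
        s1 = pd.Series(series.values[m1], index=slot_in_day[m1])
        joined = pd.concat([s0, s1], axis=1, join="inner")
        dd = (joined.iloc[:, 1] - joined.iloc[:, 0]).abs().dropna().to_numpy()
        if dd.size:
            diffs.append(dd)
    if not diffs:
        return float("nan")
    return float(np.mean(np.concatenate(diffs)))


def glucose_range(series: CgmSeries) -> float:
    """max − min over valid samples of the trimmed record."""
    v = series.values[~np.isnan(series.values)]
    if v.size == 0:
        return float("nan")
    return float(v.max() - v.min())


def summarize(
    series: CgmSeries,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    conga_lag_hours: float = 4,
) -> GlycemicSummary:
    """All seven statistics for one (trimmed) series.

    Per-metric missingness propagates as NaN; the cohort run never aborts on
    a single participant's gaps.
    """
    return GlycemicSummary(
        participant_id=series.participant_id,
        mean_24h=window_mean(series, WINDOW_24H, min_coverage),
        mean_nocturnal=window_mean(series, WINDOW_NOCTURNAL, min_coverage),
        mean_diurnal=window_mean(series, WINDOW_DIURNAL, min_coverage),
        sd_24h=sd_24h(series),
        conga4=conga(series, conga_lag_hours),
        modd=modd(series),
        range=glucose_range(series),
        n_valid_samples=series.n_valid,
        fraction_missing=series.fraction_missing,
    )
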