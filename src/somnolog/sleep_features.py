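"""Per-night sleep metrics and windowed physiological features.

Interval annotations (bed-rest vs. asleep) are grouped into *metric days*
— 24-hour windows running 15:00 local time to 15:00 the next day, with an
interval attributed to the day containing its start — and reduced to one
:class:`NightRecord` per participant-day.  Records inside an 8- or 28-day
window before a self-report are then aggregated into the 27 windowed
physiological features used for modelling, alongside watch-wear fraction
(hours with at least one heart-rate log) used only for quality control.

Conventions (documented because the underlying device export does not pin
them down):

- the metric-day boundary is half-open, ``[15:00, next-day 15:00)``;
- when several bed-rest blocks fall on one metric day, the longest block
  is the night and shorter blocks (naps) are ignored;
- an awakening is a gap of at least one minute between consecutive asleep
  intervals inside the bed-rest block; sleep-onset latency and terminal
  wakefulness are not awakenings;
- clock-time statistics (bedtime/waketime medians and SDs) are computed
  on an anchored linear scale — hours since the window's 15:00 boundary —
  so bedtimes spanning midnight stay contiguous; medians are reported
  back as clock times;
- standard deviations use the sample (n-1) denominator and are emitted
  only when at least two nights contribute;
- a night with bed rest but no asleep intervals has sleep duration 0,
  efficiency 0 and *missing* latency.

Internally all interval arithmetic runs on wall-clock int64 nanoseconds
(timestamps carry a fixed UTC offset; attribution and clock times use the
wall-clock reading the offset implies).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from somnolog.timeutil import DAY_ANCHOR_HOUR, anchor_to_clock, clock_to_anchor

__all__ = [
    "SleepState",
    "SleepAnnotation",
    "NightRecord",
    "FEATURE_COLUMNS",
    "CLOCK_MEDIAN_COLUMNS",
    "assign_metric_day",
    "compute_night_record",
    "annotations_to_night_records",
    "aggregate_features",
    "wear_fraction",
    "feature_table",
    "qc_filter",
    "model_matrix",
]

_NS_H = 3_600_000_000_000
_NS_DAY = 24 * _NS_H
_NS_MIN = 60_000_000_000
_ANCHOR_NS = DAY_ANCHOR_HOUR * _NS_H


class SleepState(str, Enum):
    IN_BED = "inBed"
    ASLEEP = "asleep"


@dataclass(frozen=True)
class SleepAnnotation:
    """One timestamped interval with state (bed rest or asleep)."""

    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    state: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"interval end must follow start: {self.start} .. {self.end}")


@dataclass(frozen=True)
class NightRecord:
    """Sleep metrics for one participant metric-day.

    Clock times are hours in [0, 24); durations in hours; latency in
    minutes; noise in dB.  Fields are NaN where undefined.
    """

    participant_id: str
    metric_day: date
    bedrest_onset: float
    bedrest_offset: float
    sleep_onset: float
    sleep_offset: float
    bedrest_duration: float
    sleep_duration: float
    sleep_efficiency: float
    sleep_onset_latency: float
    night_awake_time: float
    awakenings_count: int
    bedrest_ambient_noise: float


#: The 27 model features, in canonical (report-table) column order.
FEATURE_COLUMNS = (
    "min_sleep_duration",
    "max_sleep_duration",
    "median_sleep_duration",
    "std_sleep_duration",
    "min_sleep_efficiency",
    "max_sleep_efficiency",
    "median_sleep_efficiency",
    "std_sleep_efficiency",
    "mean_awake_time",
    "awake_count",
    "min_sleep_onset_latency",
    "max_sleep_onset_latency",
    "median_sleep_onset_latency",
    "std_sleep_onset_latency",
    "std_sleep_onset",
    "median_sleep_onset",
    "std_sleep_offset",
    "median_sleep_offset",
    "std_bedrest_offset",
    "median_bedrest_offset",
    "std_bedrest_onset",
    "median_bedrest_onset",
    "median_bedrest_duration",
    "min_bedrest_duration",
    "max_bedrest_duration",
    "std_bedrest_duration",
    "mean_bedrest_ambient_noise",
)

#: Feature columns holding clock-time medians (wrapped at midnight); these
#: are mapped onto the anchored scale before entering a model matrix.
CLOCK_MEDIAN_COLUMNS = (
    "median_sleep_onset",
    "median_sleep_offset",
    "median_bedrest_onset",
    "median_bedrest_offset",
)


def assign_metric_day(start: pd.Timestamp, tz=None) -> date:
    """Metric day for an interval: the day D with start in [D-1 15:00, D 15:00).

    The timestamp must carry a UTC offset; attribution uses its wall-clock
    local time (optionally converted to ``tz`` first).
    """
    ts = pd.Timestamp(start)
    if ts.tzinfo is None:
        raise ValueError(f"timestamp lacks timezone information: {start!r}")
    if tz is not None:
        ts = ts.tz_convert(tz)
    d = ts.date()
    if ts.hour >= DAY_ANCHOR_HOUR:
        d = d + timedelta(days=1)
    return d


def _wall_ns(ts: pd.Timestamp) -> int:
    """Wall-clock nanoseconds since the epoch (offset applied, tz dropped)."""
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        raise ValueError(f"timestamp lacks timezone information: {ts!r}")
    return ts.tz_localize(None).value


def _clock_h(wall_ns: int) -> float:
    return (wall_ns % _NS_DAY) / _NS_H


def _night_core(
    bedrest: list[tuple[int, int]],
    asleep: list[tuple[int, int]],
    noise_values: np.ndarray | None = None,
    noise_ns: np.ndarray | None = None,
) -> dict | None:
    """Numeric night reduction on wall-clock ns intervals.

    Returns None when no positive-duration bed-rest block exists.
    """
    blocks = [(s, e) for s, e in bedrest if e > s]
    if not blocks:
        return None
    b_start, b_end = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))

    in_main: list[tuple[int, int]] = []
    outside = 0
    for s, e in sorted(asleep):
        cs, ce = max(s, b_start), min(e, b_end)
        if ce > cs:
            in_main.append((cs, ce))
        elif not any(bs <= s and e <= be for bs, be in blocks):
            outside += 1
    merged: list[list[int]] = []
    for s, e in in_main:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    bed_h = (b_end - b_start) / _NS_H
    sleep_h = sum(e - s for s, e in merged) / _NS_H
    if merged:
        latency_min = (merged[0][0] - b_start) / _NS_MIN
        gaps = [
            nxt[0] - cur[1]
            for cur, nxt in zip(merged, merged[1:])
            if nxt[0] - cur[1] >= _NS_MIN
        ]
        awake_h = sum(gaps) / _NS_H
        n_awake = len(gaps)
        s_on_ns, s_off_ns = merged[0][0], merged[-1][1]
        s_on, s_off = _clock_h(s_on_ns), _clock_h(s_off_ns)
        onset_anchor = (b_start - _ANCHOR_NS) % _NS_DAY / _NS_H
        sleep_onset_anchor = onset_anchor + (s_on_ns - b_start) / _NS_H
        sleep_offset_anchor = onset_anchor + (s_off_ns - b_start) / _NS_H
    else:
        latency_min = float("nan")
        awake_h, n_awake = 0.0, 0
        s_on = s_off = float("nan")
        onset_anchor = (b_start - _ANCHOR_NS) % _NS_DAY / _NS_H
        sleep_onset_anchor = sleep_offset_anchor = float("nan")

    noise = float("nan")
    if noise_values is not None and len(noise_values):
        lo = np.searchsorted(noise_ns, b_start, side="left")
        hi = np.searchsorted(noise_ns, b_end, side="left")
        if hi > lo:
            noise = float(np.mean(noise_values[lo:hi]))
    return {
        "bedrest_start_ns": b_start,
        "bedrest_onset": _clock_h(b_start),
        "bedrest_offset": _clock_h(b_end),
        "sleep_onset": s_on,
        "sleep_offset": s_off,
        "bedrest_duration": bed_h,
        "sleep_duration": sleep_h,
        "sleep_efficiency": sleep_h / bed_h,
        "sleep_onset_latency": latency_min,
        "night_awake_time": awake_h,
        "awakenings_count": n_awake,
        "bedrest_ambient_noise": noise,
        "onset_anchor": onset_anchor,
        "offset_anchor": onset_anchor + bed_h,
        "sleep_onset_anchor": sleep_onset_anchor,
        "sleep_offset_anchor": sleep_offset_anchor,
        "n_asleep_outside": outside,
    }


def compute_night_record(
    participant_id: str,
    metric_day: date,
    bedrest: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    asleep: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    noise_samples: Sequence[tuple[pd.Timestamp, float]] = (),
) -> tuple[NightRecord | None, list[str]]:
    """Reduce one participant-day's intervals to a :class:`NightRecord`.

    The longest bed-rest block is the night; asleep intervals are clipped
    to it, asleep intervals inside shorter (nap) blocks are ignored, and
    asleep intervals outside any block are reported as issues.  Returns
    ``(record, issues)``; the record is None when every bed-rest block on
    the day has zero duration.
    """
    issues = [
        f"{participant_id} {metric_day}: zero-duration bedrest at {s}"
        for s, e in bedrest
        if e <= s
    ]
    bed_ns = [(_wall_ns(s), _wall_ns(e)) for s, e in bedrest]
    asleep_ns = [(_wall_ns(s), _wall_ns(e)) for s, e in asleep]
    if noise_samples:
        order = sorted(noise_samples, key=lambda p: p[0])
        noise_ns = np.array([_wall_ns(t) for t, _ in order], dtype=np.int64)
        noise_values = np.array([v for _, v in order], dtype=float)
    else:
        noise_ns = noise_values = None
    core = _night_core(bed_ns, asleep_ns, noise_values, noise_ns)
    if core is None:
        return None, issues
    if core["n_asleep_outside"]:
        issues.append(
            f"{participant_id} {metric_day}: {core['n_asleep_outside']} asleep "
            "interval(s) outside bedrest; ignored"
        )
    fields = {k: core[k] for k in NightRecord.__dataclass_fields__ if k in core}
    rec = NightRecord(participant_id=participant_id, metric_day=metric_day, **fields)
    return rec, issues


def annotations_to_night_records(
    annotations: pd.DataFrame,
    noise_logs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Convert an interval-annotation table into one record per night.

    ``annotations`` columns: participant_id, start, end, state (inBed or
    asleep); timestamps must be timezone-aware.  Returns a DataFrame of
    :class:`NightRecord` fields plus bookkeeping columns (``bedrest_start``
    timestamp and continuous anchored clock hours used for aggregation),
    and a list of logged anomalies.
    """
    if len(annotations) == 0:
        return pd.DataFrame(), []
    if getattr(annotations["start"].dtype, "tz", None) is None:
        raise ValueError("annotation timestamps must be timezone-aware")
    start_ns = annotations["start"].dt.tz_localize(None).to_numpy().astype("int64")
    end_ns = annotations["end"].dt.tz_localize(None).to_numpy().astype("int64")
    day_idx = (start_ns - _ANCHOR_NS) // _NS_DAY + 1  # metric date, days since epoch
    is_bed = (annotations["state"] == "inBed").to_numpy()
    pids = annotations["participant_id"].to_numpy()

    noise_by_pid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if noise_logs is not None and len(noise_logs):
        ns = noise_logs["timestamp"].dt.tz_localize(None).to_numpy().astype("int64")
        vals = noise_logs["db"].to_numpy(float)
        npids = noise_logs["participant_id"].to_numpy()
        order = np.lexsort((ns, npids))
        ns, vals, npids = ns[order], vals[order], npids[order]
        bounds = np.nonzero(np.r_[True, npids[1:] != npids[:-1], True])[0]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            noise_by_pid[npids[lo]] = (ns[lo:hi], vals[lo:hi])

    order = np.lexsort((start_ns, day_idx, pids))
    pids, day_idx = pids[order], day_idx[order]
    start_ns, end_ns, is_bed = start_ns[order], end_ns[order], is_bed[order]
    group_starts = np.nonzero(
        np.r_[True, (pids[1:] != pids[:-1]) | (day_idx[1:] != day_idx[:-1]), True]
    )[0]

    rows: list[dict] = []
    issues: list[str] = []
    epoch = date(1970, 1, 1)
    for gi in range(len(group_starts) - 1):
        lo, hi = group_starts[gi], group_starts[gi + 1]
        pid = pids[lo]
        day = epoch + timedelta(days=int(day_idx[lo]))
        bed = [
            (int(s), int(e))
            for s, e, b in zip(start_ns[lo:hi], end_ns[lo:hi], is_bed[lo:hi])
            if b
        ]
        asl = [
            (int(s), int(e))
            for s, e, b in zip(start_ns[lo:hi], end_ns[lo:hi], is_bed[lo:hi])
            if not b
        ]
        for s, e in bed + asl:
            if e <= s:
                issues.append(f"{pid} {day}: zero-duration interval")
        n_ns, n_vals = noise_by_pid.get(pid, (None, None))
        core = _night_core(bed, asl, n_vals, n_ns)
        if core is None:
            continue
        if core["n_asleep_outside"]:
            issues.append(
                f"{pid} {day}: {core['n_asleep_outside']} asleep interval(s) "
                "outside bedrest; ignored"
            )
        core.pop("n_asleep_outside")
        core["participant_id"] = pid
        core["metric_day"] = day
        rows.append(core)
    out = pd.DataFrame(rows)
    if len(out):
        out["bedrest_start"] = pd.to_datetime(out.pop("bedrest_start_ns"))
    return out, issues


# ---------------------------------------------------------------------------
# Windowed aggregation
# ---------------------------------------------------------------------------

def _agg_minmaxmedstd(values: np.ndarray, name: str, out: dict) -> None:
    v = values[~np.isnan(values)]
    if v.size == 0:
        out[f"min_{name}"] = out[f"max_{name}"] = out[f"median_{name}"] = float("nan")
        out[f"std_{name}"] = float("nan")
        return
    out[f"min_{name}"] = float(np.min(v))
    out[f"max_{name}"] = float(np.max(v))
    out[f"median_{name}"] = float(np.median(v))
    out[f"std_{name}"] = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")


def _agg_clock(anchored: np.ndarray, name: str, out: dict) -> None:
    v = anchored[~np.isnan(anchored)]
    if v.size == 0:
        out[f"median_{name}"] = out[f"std_{name}"] = float("nan")
        return
    out[f"median_{name}"] = float(anchor_to_clock(np.median(v) % 24.0))
    out[f"std_{name}"] = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")


_NIGHT_ARRAY_COLS = (
    "sleep_duration", "sleep_efficiency", "sleep_onset_latency", "bedrest_duration",
    "night_awake_time", "awakenings_count", "bedrest_ambient_noise",
    "onset_anchor", "offset_anchor", "sleep_onset_anchor", "sleep_offset_anchor",
)


def _aggregate_arrays(arr: dict[str, np.ndarray], sel: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    n = int(sel.sum()) if sel.dtype == bool else len(sel)
    if n == 0:
        out = {c: float("nan") for c in FEATURE_COLUMNS}
        out["n_nights"] = 0
        return out
    _agg_minmaxmedstd(arr["sleep_duration"][sel], "sleep_duration", out)
    _agg_minmaxmedstd(arr["sleep_efficiency"][sel], "sleep_efficiency", out)
    out["mean_awake_time"] = float(np.nanmean(arr["night_awake_time"][sel]))
    out["awake_count"] = float(np.nansum(arr["awakenings_count"][sel]))
    _agg_minmaxmedstd(arr["sleep_onset_latency"][sel], "sleep_onset_latency", out)
    _agg_clock(arr["sleep_onset_anchor"][sel], "sleep_onset", out)
    _agg_clock(arr["sleep_offset_anchor"][sel], "sleep_offset", out)
    _agg_clock(arr["offset_anchor"][sel], "bedrest_offset", out)
    _agg_clock(arr["onset_anchor"][sel], "bedrest_onset", out)
    _agg_minmaxmedstd(arr["bedrest_duration"][sel], "bedrest_duration", out)
    noise = arr["bedrest_ambient_noise"][sel]
    out["mean_bedrest_ambient_noise"] = (
        float(np.nanmean(noise)) if np.any(~np.isnan(noise)) else float("nan")
    )
    result = {k: out[k] for k in FEATURE_COLUMNS}
    result["n_nights"] = n
    return result


def aggregate_features(
    night_records: pd.DataFrame,
    event_time: pd.Timestamp,
    window_days: int,
) -> dict[str, float]:
    """The 27 windowed features for one self-report event.

    Nights whose bed-rest block starts within ``[event_time - window_days,
    event_time)`` contribute.  Duration, efficiency, latency and bed-rest
    duration aggregate as min/max/median/sample-SD; nightly awakenings as
    mean awake hours and summed count; clock times as median/SD on the
    anchored scale; ambient noise as the mean over nights.  Returns the
    feature dict plus ``n_nights`` bookkeeping (wear fraction is computed
    separately from heart-rate logs).
    """
    if len(night_records) == 0:
        return _aggregate_arrays({}, np.zeros(0, dtype=bool))
    lo = event_time - pd.Timedelta(days=window_days)
    m = (
        (night_records["bedrest_start"] >= _naive(lo))
        & (night_records["bedrest_start"] < _naive(event_time))
    ).to_numpy()
    arr = {c: night_records[c].to_numpy(float) for c in _NIGHT_ARRAY_COLS}
    return _aggregate_arrays(arr, m)


def _naive(ts: pd.Timestamp) -> pd.Timestamp:
    ts = pd.Timestamp(ts)
    return ts.tz_localize(None) if ts.tzinfo is not None else ts


def wear_fraction(
    hr_timestamps: Iterable[pd.Timestamp] | pd.Series,
    event_time: pd.Timestamp,
    window_days: int,
) -> float:
    """Fraction of wall-clock hours before ``event_time`` with >= 1 HR log.

    Logs inside ``[event_time - window_days, event_time)`` are binned by
    the calendar hour they fall in; the fraction is distinct hit hours
    over the ``24 * window_days`` hours the window spans (capped at 1 for
    the sliver hours at the window edges).
    """
    if isinstance(hr_timestamps, pd.DatetimeIndex):
        ts = hr_timestamps
    elif isinstance(hr_timestamps, pd.Series):
        ts = pd.DatetimeIndex(hr_timestamps.dropna())
    else:
        ts = pd.DatetimeIndex(pd.Series(list(hr_timestamps), dtype="object").dropna())
    n_bins = 24 * int(window_days)
    if len(ts) == 0:
        return 0.0
    lo_ns = pd.Timestamp(event_time - pd.Timedelta(days=window_days)).value
    hi_ns = pd.Timestamp(event_time).value
    ns = ts.asi8
    hours = ns[(ns >= lo_ns) & (ns < hi_ns)] // _NS_H
    return min(1.0, float(len(np.unique(hours))) / n_bins)


_DEFAULT_WINDOWS = {"phq14": 8, "psqi": 28}


def feature_table(
    night_records: pd.DataFrame,
    hr_logs: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int | None = None,
) -> pd.DataFrame:
    """Feature vectors for every survey event.

    ``events`` needs participant_id, week, event_time and (if
    ``window_days`` is None) an ``instrument`` column mapped through the
    standard windows: 8 days before a PHQ-14, 28 before a PSQI.
    """
    nights_by_pid: dict[str, tuple[np.ndarray, dict[str, np.ndarray]]] = {}
    if len(night_records):
        for pid, grp in night_records.groupby("participant_id", sort=False):
            grp = grp.sort_values("bedrest_start")
            starts = grp["bedrest_start"].to_numpy().astype("int64")
            nights_by_pid[pid] = (
                starts,
                {c: grp[c].to_numpy(float) for c in _NIGHT_ARRAY_COLS},
            )
    hr_by_pid = {
        pid: np.sort(pd.DatetimeIndex(grp["timestamp"]).asi8)
        for pid, grp in hr_logs.groupby("participant_id", sort=False)
    }
    rows = []
    for pid, week, event_time, *rest in events[
        ["participant_id", "week", "event_time"]
        + (["instrument"] if window_days is None else [])
    ].itertuples(index=False):
        w_days = _DEFAULT_WINDOWS[rest[0]] if window_days is None else window_days
        ev_ns = _naive(event_time).value
        lo_ns = ev_ns - w_days * _NS_DAY
        if pid in nights_by_pid:
            starts, arr = nights_by_pid[pid]
            a = np.searchsorted(starts, lo_ns, side="left")
            b = np.searchsorted(starts, ev_ns, side="left")
            feats = _aggregate_arrays(arr, np.arange(a, b))
        else:
            feats = _aggregate_arrays({}, np.zeros(0, dtype=bool))
        hr = hr_by_pid.get(pid)
        if hr is None:
            wf = 0.0
        else:
            # HR log timestamps are tz-aware UTC ns; window bounds likewise
            ev_utc = pd.Timestamp(event_time).value
            lo_utc = ev_utc - w_days * _NS_DAY
            in_win = hr[(hr >= lo_utc) & (hr < ev_utc)] // _NS_H
            wf = min(1.0, float(len(np.unique(in_win))) / (24 * w_days))
        rows.append(
            {
                "participant_id": pid,
                "week": week,
                "event_time": event_time,
                "window_days": w_days,
                **feats,
                "wear_fraction": wf,
            }
        )
    return pd.DataFrame(rows)


def qc_filter(
    feature_events: pd.DataFrame,
    wear_threshold: float = 0.80,
    drop_baseline: bool = True,
    baseline_week: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality control for sensor-based modelling.

    Keeps events with wear fraction >= ``wear_threshold`` (the device study
    removes events below 80 % wear) and at least one annotated night in
    the window; baseline/intake events are excluded from sensor-based
    modelling when ``drop_baseline``.  Returns ``(kept, exclusions)`` where
    exclusions carry one mutually exclusive reason per dropped event, so
    counts reconcile: ``n_input == n_kept + sum(per-reason counts)``.
    """
    reasons = pd.Series("", index=feature_events.index, dtype=object)
    if drop_baseline:
        reasons[feature_events["week"] == baseline_week] = "baseline"
    no_ann = (feature_events["n_nights"] == 0) & (reasons == "")
    reasons[no_ann] = "no sleep annotations"
    low_wear = (feature_events["wear_fraction"] < wear_threshold) & (reasons == "")
    reasons[low_wear] = f"wear<{wear_threshold:.2f}"
    kept = feature_events[reasons == ""].copy()
    excl = feature_events[reasons != ""].copy()
    excl["reason"] = reasons[reasons != ""]
    return kept, excl[["participant_id", "week", "event_time", "reason"]]


def model_matrix(feature_events: pd.DataFrame) -> pd.DataFrame:
    """Numeric 27-column model matrix.

    Clock-time medians are mapped onto the anchored scale (hours since
    15:00) so that a bedtime of 23:30 and one of 00:30 are one hour apart
    for the models; all other columns pass through.
    """
    X = feature_events.loc[:, list(FEATURE_COLUMNS)].copy()
    for c in CLOCK_MEDIAN_COLUMNS:
        X[c] = clock_to_anchor(X[c].to_numpy(float))
    return X
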