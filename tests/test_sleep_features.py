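"""Metric-day attribution, night reduction, aggregation and QC."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from oracles import minute_grid_night
from somnolog.sleep_features import (
    FEATURE_COLUMNS,
    aggregate_features,
    annotations_to_night_records,
    assign_metric_day,
    compute_night_record,
    feature_table,
    model_matrix,
    qc_filter,
    wear_fraction,
)
from somnolog.timeutil import STUDY_TZ

TZ = "-08:00"


def ts(s):
    return pd.Timestamp(f"{s}{TZ}")


@pytest.mark.parametrize(
    "start, expected",
    [
        ("2023-06-01 23:00", date(2023, 6, 2)),
        ("2023-06-02 14:59", date(2023, 6, 2)),
        ("2023-06-02 15:00", date(2023, 6, 3)),  # half-open boundary
        ("2023-06-02 00:00", date(2023, 6, 2)),
        ("2023-06-02 14:59:59", date(2023, 6, 2)),
    ],
)
def test_assign_metric_day(start, expected):
    assert assign_metric_day(ts(start)) == expected


def test_assign_metric_day_requires_offset():
    with pytest.raises(ValueError, match="timezone"):
        assign_metric_day(pd.Timestamp("2023-06-01 23:00"))


class TestNightRecord:
    def test_interrupted_night_hand_example(self):
        rec, issues = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
            asleep=[
                (ts("2023-06-01 23:20"), ts("2023-06-02 03:00")),
                (ts("2023-06-02 03:15"), ts("2023-06-02 06:50")),
            ],
        )
        assert not issues
        assert rec.bedrest_duration == 8.0
        assert rec.sleep_duration == pytest.approx(7.25)
        assert rec.sleep_onset_latency == 20.0
        assert rec.awakenings_count == 1
        assert rec.night_awake_time == pytest.approx(0.25)
        assert rec.sleep_efficiency == pytest.approx(0.90625)
        assert rec.sleep_onset == pytest.approx(23 + 20 / 60)
        assert rec.sleep_offset == pytest.approx(6 + 50 / 60)

    def test_perfect_night(self):
        rec, _ = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
            asleep=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
        )
        assert rec.sleep_onset_latency == 0.0
        assert rec.awakenings_count == 0
        assert rec.sleep_efficiency == 1.0

    def test_sleepless_night_degenerate(self):
        rec, _ = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
            asleep=[],
        )
        assert rec.sleep_duration == 0.0
        assert rec.sleep_efficiency == 0.0
        assert np.isnan(rec.sleep_onset_latency)
        assert rec.awakenings_count == 0

    def test_zero_duration_bedrest_rejected(self):
        rec, issues = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-01 23:00"))],
            asleep=[],
        )
        assert rec is None
        assert any("zero-duration" in m for m in issues)

    def test_asleep_outside_bedrest_logged(self):
        rec, issues = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
            asleep=[
                (ts("2023-06-01 23:10"), ts("2023-06-02 06:00")),
                (ts("2023-06-02 09:00"), ts("2023-06-02 09:30")),
            ],
        )
        assert any("outside bedrest" in m for m in issues)
        assert rec.sleep_duration == pytest.approx(6 + 50 / 60)

    def test_longest_block_wins_over_nap(self):
        rec, _ = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[
                (ts("2023-06-01 16:00"), ts("2023-06-01 17:00")),  # nap
                (ts("2023-06-01 23:00"), ts("2023-06-02 07:00")),
            ],
            asleep=[
                (ts("2023-06-01 16:05"), ts("2023-06-01 16:55")),
                (ts("2023-06-01 23:10"), ts("2023-06-02 06:30")),
            ],
        )
        assert rec.bedrest_onset == 23.0
        assert rec.sleep_duration == pytest.approx(7 + 20 / 60)

    def test_noise_mean_within_bedrest_only(self):
        rec, _ = compute_night_record(
            "p", date(2023, 6, 2),
            bedrest=[(ts("2023-06-01 23:00"), ts("2023-06-02 07:00"))],
            asleep=[(ts("2023-06-01 23:10"), ts("2023-06-02 06:30"))],
            noise_samples=[
                (ts("2023-06-01 12:00"), 60.0),  # daytime, ignored
                (ts("2023-06-02 01:00"), 30.0),
                (ts("2023-06-02 03:00"), 40.0),
            ],
        )
        assert rec.bedrest_ambient_noise == pytest.approx(35.0)


def test_night_records_match_minute_grid_oracle(small_cohort):
    """Bulk reduction agrees exactly with minute-by-minute counting."""
    nights, _ = annotations_to_night_records(small_cohort.annotations)
    ann = small_cohort.annotations
    local = ann["start"].dt.tz_localize(None)
    mday = local.dt.normalize() + pd.to_timedelta((local.dt.hour >= 15).astype(int), unit="D")
    ann = ann.assign(metric_day=mday.dt.date)
    checked = 0
    for (pid, day), grp in list(ann.groupby(["participant_id", "metric_day"]))[:250]:
        bed = [(s, e) for s, e, st in zip(grp["start"], grp["end"], grp["state"]) if st == "inBed"]
        asl = [(s, e) for s, e, st in zip(grp["start"], grp["end"], grp["state"]) if st == "asleep"]
        oracle = minute_grid_night(bed, asl)
        row = nights[(nights["participant_id"] == pid) & (nights["metric_day"] == day)]
        assert len(row) == 1
        row = row.iloc[0]
        for k, v in oracle.items():
            got = row[k]
            assert (np.isnan(v) and np.isnan(got)) or got == v, (pid, day, k, got, v)
        checked += 1
    assert checked > 100


class TestAggregation:
    @staticmethod
    def _nights(**overrides):
        base = {
            "participant_id": "p",
            "sleep_duration": [6.0, 7.0, 9.0],
            "sleep_efficiency": [0.9, 0.95, 0.85],
            "sleep_onset_latency": [10.0, 20.0, 30.0],
            "bedrest_duration": [7.0, 8.0, 10.0],
            "night_awake_time": [0.2, 0.0, 0.4],
            "awakenings_count": [1, 0, 2],
            "bedrest_ambient_noise": [30.0, np.nan, 40.0],
            "onset_anchor": [8.0, 8.5, 9.0],
            "offset_anchor": [15.0, 16.5, 19.0],
            "sleep_onset_anchor": [8.2, 8.8, 9.5],
            "sleep_offset_anchor": [14.9, 16.4, 18.8],
            "bedrest_start": pd.to_datetime(
                ["2023-01-10 23:00", "2023-01-11 23:30", "2023-01-13 00:00"]
            ),
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_min_median_max_std(self):
        f = aggregate_features(self._nights(), pd.Timestamp("2023-01-14 18:00"), 8)
        assert f["min_sleep_duration"] == 6.0
        assert f["max_sleep_duration"] == 9.0
        assert f["median_sleep_duration"] == 7.0
        assert f["std_sleep_duration"] == pytest.approx(np.std([6, 7, 9], ddof=1))
        assert f["awake_count"] == 3.0
        assert f["mean_awake_time"] == pytest.approx(0.2)
        assert f["mean_bedrest_ambient_noise"] == pytest.approx(35.0)
        assert f["n_nights"] == 3

    def test_single_night_has_no_std(self):
        nights = self._nights()
        f = aggregate_features(nights.iloc[:1], pd.Timestamp("2023-01-14 18:00"), 8)
        assert np.isnan(f["std_sleep_duration"])
        assert f["min_sleep_duration"] == f["median_sleep_duration"] == f["max_sleep_duration"]

    def test_clock_median_crosses_midnight(self):
        """Bedtimes 23:30 and 00:30 must summarise near midnight, not noon."""
        nights = self._nights(onset_anchor=[8.5, 9.5, 9.0])  # 23:30, 00:30, 00:00
        f = aggregate_features(nights, pd.Timestamp("2023-01-14 18:00"), 8)
        assert f["median_bedrest_onset"] == pytest.approx(0.0)

    def test_window_excludes_event_time_and_older_nights(self):
        nights = self._nights()
        f = aggregate_features(nights, pd.Timestamp("2023-01-12 18:00"), 1)
        assert f["n_nights"] == 1
        assert f["median_sleep_duration"] == 7.0

    def test_permutation_invariance(self):
        nights = self._nights()
        shuffled = nights.sample(frac=1, random_state=3)
        a = aggregate_features(nights, pd.Timestamp("2023-01-14 18:00"), 8)
        b = aggregate_features(shuffled, pd.Timestamp("2023-01-14 18:00"), 8)
        assert a == b

    def test_empty_window_fully_missing(self):
        f = aggregate_features(self._nights(), pd.Timestamp("2024-06-01 18:00"), 8)
        assert f["n_nights"] == 0
        assert all(np.isnan(f[c]) for c in FEATURE_COLUMNS)

    def test_min_le_median_le_max_on_generated_features(self, small_tables):
        feats = small_tables.features
        feats = feats[feats["n_nights"] > 0]
        for m in ("sleep_duration", "sleep_efficiency", "sleep_onset_latency", "bedrest_duration"):
            assert (feats[f"min_{m}"] <= feats[f"median_{m}"] + 1e-12).all()
            assert (feats[f"median_{m}"] <= feats[f"max_{m}"] + 1e-12).all()
        eff = feats[["min_sleep_efficiency", "max_sleep_efficiency"]].to_numpy()
        assert ((eff >= 0) & (eff <= 1)).all()


class TestWearFraction:
    def test_every_hour_covered(self):
        event = pd.Timestamp("2023-01-09 00:00", tz=STUDY_TZ)
        logs = pd.date_range(
            event - pd.Timedelta(days=8) + pd.Timedelta(minutes=30), periods=192, freq="1h"
        )
        assert wear_fraction(logs, event, 8) == 1.0

    def test_partial_count(self):
        event = pd.Timestamp("2023-01-09 00:00", tz=STUDY_TZ)
        start = event - pd.Timedelta(days=8)
        logs = [start + pd.Timedelta(hours=h, minutes=12) for h in range(154)]
        assert wear_fraction(logs, event, 8) == pytest.approx(154 / 192)

    def test_no_logs(self):
        event = pd.Timestamp("2023-01-09 00:00", tz=STUDY_TZ)
        assert wear_fraction([], event, 8) == 0.0


class TestQC:
    @staticmethod
    def _events():
        return pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "week": [1, 1, 1, 0],
                "event_time": pd.to_datetime(["2023-01-09"] * 4),
                "n_nights": [5, 5, 0, 5],
                "wear_fraction": [0.79, 0.80, 0.95, 0.99],
            }
        )

    def test_boundaries_and_reasons(self):
        kept, excl = qc_filter(self._events())
        assert list(kept["participant_id"]) == ["b"]
        reasons = dict(zip(excl["participant_id"], excl["reason"]))
        assert reasons["a"] == "wear<0.80"
        assert reasons["c"] == "no sleep annotations"
        assert reasons["d"] == "baseline"

    def test_accounting_reconciles(self):
        ev = self._events()
        kept, excl = qc_filter(ev)
        assert len(ev) == len(kept) + len(excl)

    def test_threshold_monotonicity(self):
        ev = self._events()
        kept_counts = [
            len(qc_filter(ev, wear_threshold=t)[0]) for t in (0.5, 0.7, 0.8, 0.9, 1.0)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)


def test_model_matrix_anchors_clock_medians(small_tables):
    feats = small_tables.phq_features
    X = model_matrix(feats)
    assert list(X.columns) == list(FEATURE_COLUMNS)
    # anchored onset (hours after 15:00) for a ~23:00 bedtime sits near 8
    med = X["median_bedrest_onset"].dropna()
    assert ((med >= 0) & (med < 24)).all()


def test_feature_table_matches_aggregate(small_tables, small_cohort):
    """The fast bulk path equals the per-event aggregation API."""
    feats = small_tables.features
    nights = small_tables.night_records
    sample = feats.sample(6, random_state=0)
    for _, r in sample.iterrows():
        sub = nights[nights["participant_id"] == r["participant_id"]]
        ref = aggregate_features(sub, r["event_time"].tz_localize(None), int(r["window_days"]))
        for k, v in ref.items():
            got = r[k]
            assert (isinstance(v, float) and np.isnan(v) and np.isnan(got)) or got == pytest.approx(v), k
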