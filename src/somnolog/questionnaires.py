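"""Scoring and binarization of the PSQI and PHQ-14, plus neurocognitive metrics.

PSQI
----
The Pittsburgh Sleep Quality Index asks 19 questions about the prior month
of sleep; 18 numeric responses enter scoring (the 19th is the free-text
description attached to the "other disturbance" item).  They are reduced to
seven 0-3 components — subjective quality, latency, duration, habitual
sleep efficiency, disturbances, medication use, daytime dysfunction — whose
sum is the 0-21 global score.  Component algorithms follow the original
published scoring sheet.

PHQ-14
------
A 14-item variant of the Patient Health Questionnaire that splits the
compound PHQ-9 items (sleep, appetite, psychomotor, mood) into separate
symptoms, adds irritability and libido, and drops the suicidality item.
A PHQ-8-style severity total is recomposed by taking the max of each split
pair and excluding the two added items; the depression-screening threshold
on that total is >= 10.

Every item, domain and total score also has a binary detection target used
by the classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PHQ_ITEMS",
    "PHQ_PAIRS",
    "PHQ_EXCLUDED",
    "PSQI_ITEMS",
    "PSQI_DISTURBANCE_ITEMS",
    "PSQI_COMPONENTS",
    "PsqiResponse",
    "PsqiScores",
    "score_psqi",
    "binarize_psqi",
    "score_psqi_events",
    "phq14_to_phq8_total",
    "binarize_phq",
    "score_phq_events",
    "rate_correct_score",
    "habitual_sleep_efficiency",
]


class ScoringError(ValueError):
    """A questionnaire response cannot be scored (e.g. missing item)."""


# ---------------------------------------------------------------------------
# PHQ-14
# ---------------------------------------------------------------------------

#: Canonical item order.  Names describe the symptom stem.
PHQ_ITEMS = (
    "interest_pleasure",
    "down_depressed",
    "hopeless",
    "trouble_sleep",
    "sleep_too_much",
    "tired",
    "poor_appetite",
    "overeating",
    "feeling_bad",
    "concentrating",
    "moving_slowly",
    "fidgety",
    "irritable",
    "low_libido",
)

#: Split compound symptoms recombined by max() for the PHQ-8-style total.
PHQ_PAIRS = (
    ("down_depressed", "hopeless"),
    ("trouble_sleep", "sleep_too_much"),
    ("poor_appetite", "overeating"),
    ("moving_slowly", "fidgety"),
)

#: Singleton items that enter the total directly.
PHQ_SINGLETONS = ("interest_pleasure", "tired", "feeling_bad", "concentrating")

#: Added items excluded from the severity total.
PHQ_EXCLUDED = ("irritable", "low_libido")

PHQ_TOTAL_THRESHOLD = 10


def phq14_to_phq8_total(items: Mapping[str, float]) -> int:
    """Recompose a PHQ-8-style severity total (0-24) from PHQ-14 items.

    Takes the max of each split symptom pair, adds the four unsplit items,
    and excludes the added irritability and libido items.  Raises
    :class:`ScoringError` if any of the 12 needed items is missing.
    """
    needed = PHQ_SINGLETONS + tuple(i for pair in PHQ_PAIRS for i in pair)
    for name in needed:
        v = items.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ScoringError(f"missing PHQ item required for total: {name!r}")
        if v not in (0, 1, 2, 3):
            raise ScoringError(f"PHQ item {name!r} out of range 0-3: {v!r}")
    total = sum(int(items[name]) for name in PHQ_SINGLETONS)
    total += sum(max(int(items[a]), int(items[b])) for a, b in PHQ_PAIRS)
    return total


def binarize_phq(items: Mapping[str, float]) -> dict[str, float]:
    """15 binary detection targets: 14 item endorsements plus the total.

    An item is positive when its score exceeds 0; the total is positive at
    the >= 10 screening threshold.  Items with missing scores (libido may be
    skipped) yield NaN so that rows can be dropped per-target downstream.
    """
    out: dict[str, float] = {}
    for name in PHQ_ITEMS:
        v = items.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[name] = float("nan")
        else:
            out[name] = float(v > 0)
    out["phq_total"] = float(phq14_to_phq8_total(items) >= PHQ_TOTAL_THRESHOLD)
    return out


# ---------------------------------------------------------------------------
# PSQI
# ---------------------------------------------------------------------------

#: Disturbance-frequency items (instrument question 5).  The first — cannot
#: fall asleep within 30 minutes — feeds the latency component; the other
#: nine feed the disturbances component.  All coded 0 (not during the past
#: month), 1 (less than once a week), 2 (once or twice a week),
#: 3 (three or more times a week).
PSQI_DISTURBANCE_ITEMS = (
    "cant_sleep_30min",
    "wake_middle_night",
    "bathroom",
    "cant_breathe",
    "cough_snore",
    "too_cold",
    "too_hot",
    "bad_dreams",
    "pain",
    "other_disturbance",
)

PSQI_ITEMS = (
    "bedtime",
    "minutes_to_sleep",
    "waketime",
    "hours_of_sleep",
) + PSQI_DISTURBANCE_ITEMS + (
    "sleep_quality",
    "sleep_medication",
    "trouble_staying_awake",
    "low_enthusiasm",
)

PSQI_COMPONENTS = (
    "quality",
    "latency",
    "duration",
    "efficiency",
    "disturbances",
    "medication",
    "daytime_dysfunction",
)

PSQI_ORDINAL_ITEMS = PSQI_DISTURBANCE_ITEMS + (
    "sleep_quality",
    "sleep_medication",
    "trouble_staying_awake",
    "low_enthusiasm",
)


@dataclass(frozen=True)
class PsqiResponse:
    """One PSQI administration (numeric responses only).

    ``bedtime``/``waketime`` are clock hours in [0, 24); ``minutes_to_sleep``
    and ``hours_of_sleep`` are the self-estimated quantities; all remaining
    items are 0-3 ordinals (see :data:`PSQI_ITEMS` for the coding).
    """

    participant_id: str
    event_time: object  # timestamp-like; opaque to scoring
    bedtime: float
    minutes_to_sleep: float
    waketime: float
    hours_of_sleep: float
    cant_sleep_30min: int
    wake_middle_night: int
    bathroom: int
    cant_breathe: int
    cough_snore: int
    too_cold: int
    too_hot: int
    bad_dreams: int
    pain: int
    other_disturbance: int
    sleep_quality: int
    sleep_medication: int
    trouble_staying_awake: int
    low_enthusiasm: int

    def item(self, name: str):
        return getattr(self, name)


@dataclass(frozen=True)
class PsqiScores:
    """Seven 0-3 PSQI components and the 0-21 global score."""

    components: dict[str, int] = field(default_factory=dict)
    global_score: int = 0


def _require(response: PsqiResponse, name: str) -> float:
    v = response.item(name)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise ScoringError(f"missing PSQI item: {name!r}")
    return v


def _check_ordinal(name: str, v) -> int:
    if v not in (0, 1, 2, 3):
        raise ScoringError(f"PSQI item {name!r} out of range 0-3: {v!r}")
    return int(v)


def time_in_bed_hours(bedtime: float, waketime: float) -> float:
    """Hours between reported bedtime and rise time, wrapping midnight.

    A reported 23:00 -> 07:00 gives 8 h; identical times are read as a full
    24 h cycle being absent (0 would make efficiency undefined), so they are
    rejected upstream by requiring hours_of_sleep <= time in bed anyway.
    """
    return (float(waketime) - float(bedtime)) % 24.0


def habitual_sleep_efficiency(response: PsqiResponse) -> float:
    """Self-reported sleep efficiency: hours asleep / hours in bed (%)."""
    tib = time_in_bed_hours(_require(response, "bedtime"), _require(response, "waketime"))
    if tib <= 0:
        raise ScoringError("reported time in bed is zero")
    return 100.0 * float(_require(response, "hours_of_sleep")) / tib


def _map_latency_minutes(minutes: float) -> int:
    if minutes <= 15:
        return 0
    if minutes <= 30:
        return 1
    if minutes <= 60:
        return 2
    return 3


def _map_duration_hours(hours: float) -> int:
    if hours > 7:
        return 0
    if hours >= 6:
        return 1
    if hours >= 5:
        return 2
    return 3


def _map_hse(hse_percent: float) -> int:
    if hse_percent >= 85:
        return 0
    if hse_percent >= 75:
        return 1
    if hse_percent >= 65:
        return 2
    return 3


def _map_sum(total: int, band: int) -> int:
    # 0 -> 0; 1..band -> 1; band+1..2*band -> 2; above -> 3
    if total == 0:
        return 0
    if total <= band:
        return 1
    if total <= 2 * band:
        return 2
    return 3


def score_psqi(response: PsqiResponse) -> PsqiScores:
    """Score one PSQI response into its seven components and global score.

    Follows the published instrument algorithms: latency combines the
    mapped minutes-to-sleep with the >= 30-minute frequency item; habitual
    sleep efficiency divides reported sleep hours by the bed window derived
    from reported bed and rise times; disturbances sum the nine disturbance
    causes; daytime dysfunction combines staying-awake trouble with low
    enthusiasm.  Missing items raise :class:`ScoringError` — no imputation.
    """
    for name in PSQI_ITEMS:
        _require(response, name)
    ordinals = {name: _check_ordinal(name, response.item(name)) for name in PSQI_ORDINAL_ITEMS}
    minutes = float(response.minutes_to_sleep)
    hours = float(response.hours_of_sleep)
    if minutes < 0:
        raise ScoringError("minutes_to_sleep must be >= 0")
    if hours < 0:
        raise ScoringError("hours_of_sleep must be >= 0")

    c: dict[str, int] = {}
    c["quality"] = ordinals["sleep_quality"]
    c["latency"] = _map_sum(_map_latency_minutes(minutes) + ordinals["cant_sleep_30min"], 2)
    c["duration"] = _map_duration_hours(hours)
    c["efficiency"] = _map_hse(habitual_sleep_efficiency(response))
    disturbance_sum = sum(ordinals[k] for k in PSQI_DISTURBANCE_ITEMS[1:])
    c["disturbances"] = _map_sum(disturbance_sum, 9)
    c["medication"] = ordinals["sleep_medication"]
    c["daytime_dysfunction"] = _map_sum(
        ordinals["trouble_staying_awake"] + ordinals["low_enthusiasm"], 2
    )
    return PsqiScores(components=c, global_score=sum(c.values()))


#: Binary target names for the PSQI (7 domains + total).
PSQI_TARGETS = PSQI_COMPONENTS + ("psqi_total",)


def binarize_psqi(
    scores: PsqiScores,
    response: PsqiResponse,
    latency_rule: str = "as_printed",
) -> dict[str, bool]:
    """Eight binary PSQI detection targets (7 domains + total).

    Rules:

    - ``duration``: reported sleep < 7 h (strict; adult recommendation 7-9 h)
    - ``efficiency``: habitual sleep efficiency < 85 % (strict)
    - ``latency``: with ``latency_rule="as_printed"``, the >= 30-minute
      frequency item is *less than weekly* (score <= 1) AND reported average
      minutes-to-sleep >= 15; ``"frequency_geq_weekly"`` flips the frequency
      clause to at-least-weekly (score >= 2), the direction many scoring
      conventions would suggest.
    - ``disturbances``: at least 3 disturbance causes occurring >= 3 times a
      week (item score 3)
    - ``medication``: any vs. no sleep medication
    - ``quality``: quality rated fairly bad or very bad (item 2 or 3)
    - ``daytime_dysfunction``: a dysfunction cause at least weekly (item >= 2)
    - ``psqi_total``: global score >= 5 (sleep-disorder screening cutoff)
    """
    if latency_rule not in ("as_printed", "frequency_geq_weekly"):
        raise ValueError(f"unknown latency_rule: {latency_rule!r}")
    hse = habitual_sleep_efficiency(response)
    freq = int(response.cant_sleep_30min)
    freq_clause = freq <= 1 if latency_rule == "as_printed" else freq >= 2
    disturbance_3x = sum(
        int(response.item(k)) == 3 for k in PSQI_DISTURBANCE_ITEMS[1:]
    )
    return {
        "quality": int(response.sleep_quality) >= 2,
        "latency": bool(freq_clause and float(response.minutes_to_sleep) >= 15),
        "duration": float(response.hours_of_sleep) < 7,
        "efficiency": hse < 85,
        "disturbances": disturbance_3x >= 3,
        "medication": int(response.sleep_medication) > 0,
        "daytime_dysfunction": (
            int(response.trouble_staying_awake) >= 2 or int(response.low_enthusiasm) >= 2
        ),
        "psqi_total": scores.global_score >= 5,
    }


# ---------------------------------------------------------------------------
# Bulk (DataFrame) interfaces
# ---------------------------------------------------------------------------

def _wide_surveys(surveys: pd.DataFrame, instrument: str) -> pd.DataFrame:
    sub = surveys[surveys["instrument"] == instrument]
    wide = sub.pivot_table(
        index=["participant_id", "week", "event_time"],
        columns="item",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide


def score_psqi_events(surveys: pd.DataFrame, latency_rule: str = "as_printed") -> pd.DataFrame:
    """Score every PSQI event in a long-format survey table.

    Input columns: participant_id, week, event_time, instrument, item, value.
    Returns one row per event with raw items, the seven components, the
    global score, habitual sleep efficiency (%), and boolean target columns
    prefixed ``target_``.
    """
    wide = _wide_surveys(surveys, "psqi")
    rows = []
    for _, r in wide.iterrows():
        resp = PsqiResponse(
            participant_id=r["participant_id"],
            event_time=r["event_time"],
            **{name: r[name] for name in PSQI_ITEMS},
        )
        scores = score_psqi(resp)
        out = {
            "participant_id": r["participant_id"],
            "week": r["week"],
            "event_time": r["event_time"],
            **{name: r[name] for name in PSQI_ITEMS},
            **{f"comp_{k}": v for k, v in scores.components.items()},
            "global_score": scores.global_score,
            "hse_percent": habitual_sleep_efficiency(resp),
        }
        out.update(
            {f"target_{k}": v for k, v in binarize_psqi(scores, resp, latency_rule).items()}
        )
        rows.append(out)
    return pd.DataFrame(rows)


def score_phq_events(surveys: pd.DataFrame) -> pd.DataFrame:
    """Score every PHQ-14 event in a long-format survey table.

    Returns one row per event with item scores, the PHQ-8-style total, and
    binary target columns prefixed ``target_`` (NaN where the underlying
    item is missing, e.g. skipped libido).
    """
    wide = _wide_surveys(surveys, "phq14")
    rows = []
    for _, r in wide.iterrows():
        items = {name: r.get(name, float("nan")) for name in PHQ_ITEMS}
        targets = binarize_phq(items)
        rows.append(
            {
                "participant_id": r["participant_id"],
                "week": r["week"],
                "event_time": r["event_time"],
                **items,
                "phq8_total": phq14_to_phq8_total(items),
                **{f"target_{k}": v for k, v in targets.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neurocognitive metrics
# ---------------------------------------------------------------------------

def rate_correct_score(accuracy: float, median_rt_ms: float) -> float:
    """Combined speed-accuracy metric: 1000 * accuracy / median RT (ms).

    Units work out to correct responses per second.  ``median_rt_ms`` must
    be positive.
    """
    if median_rt_ms <= 0:
        raise ValueError(f"median reaction time must be > 0 ms, got {median_rt_ms!r}")
    return 1000.0 * float(accuracy) / float(median_rt_ms)
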