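"""Synthetic digital-phenotyping cohort generator.

Emulates the data streams of a 13-week smartphone + smartwatch study of
adults with depression:

- nightly bed-rest / asleep interval annotations on a 1-minute grid,
- hourly heart-rate log timestamps (watch-wear proxy),
- ambient-noise samples (dB) during bed rest plus sparse daytime samples,
- scheduled PHQ-14 (9 waves) and PSQI (3 waves) self-reports,
- neurocognitive task metrics collected alongside each PSQI wave.

A small set of per-participant latent traits (habitual bedtime, bed-rest
duration, sleep-onset latency, awakening rate, efficiency, and a shared
"distress" factor loading on questionnaire items) drives both the
physiology and the questionnaires.  Configurable effect sizes inject
links from standardized physiological latents into the log-odds of
endorsing specific PHQ-14 symptoms, so planted physiology->symptom
signal can be recovered — or shown absent — by the downstream pipeline.

Self-report misperception is modelled as additive Gaussian noise on
reported durations and clock times, additive Gaussian noise on
log-latency (reproducing the tendency to overestimate how long falling
asleep takes once a bias is configured), and binomial thinning of
perceived awakenings (consumer devices and sleepers both miss brief
arousals).

Each participant draws from an RNG stream keyed by (master seed,
participant index), so cohorts are reproducible under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from somnolog.questionnaires import PHQ_ITEMS, PSQI_DISTURBANCE_ITEMS
from somnolog.timeutil import STUDY_TZ, anchor_to_clock, clock_to_anchor

__all__ = [
    "GeneratorConfig",
    "LatentTraits",
    "CohortTruth",
    "CohortDataset",
    "generate_cohort",
    "generate_wear_pattern",
    "PHYSIO_LATENTS",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


#: Names of standardized physiological latents that effect sizes may target.
PHYSIO_LATENTS = (
    "bedrest_onset",
    "bedrest_duration",
    "sleep_offset",
    "latency",
    "awakenings",
    "efficiency",
)

# Population-level trait distributions (means/SDs used both to draw traits
# and to standardize them exactly for effect injection).
_ONSET_CLOCK_MEAN = 23.0  # habitual bed-rest onset, clock hours
_ONSET_SD = 1.1
_DUR_MEAN = 8.0  # habitual bed-rest duration, hours
_DUR_SD = 0.8
_LAT_LOG_MEAN = math.log(15.0)  # habitual sleep-onset latency, minutes
_LAT_LOG_SD = 0.5
_AWAKE_LOG_MEAN = math.log(1.2)  # nightly awakening rate
_AWAKE_LOG_SD = 0.6
_EFF_LOGIT_MEAN = 2.4  # efficiency baseline on the logit scale
_EFF_LOGIT_SD = 0.6

# Night-to-night within-person variability.
_NIGHT_ONSET_SD = 0.5  # h
_NIGHT_DUR_SD = 0.5  # h
_NIGHT_EFF_SD = 0.04
_NIGHT_LAT_LOG_SD = 0.45

# Ordered-logit cutpoint offsets for 0-3 item scores: P(score > k) =
# logistic(eta - _CUTS[k]), so P(score > 0) is exactly logistic(eta).
_CUTS = (0.0, 1.3, 2.6)

#: Baseline endorsement log-odds per PHQ-14 item (documentation defaults
#: giving a mostly moderate-to-severe cohort; not calibration targets).
DEFAULT_PHQ_BASELINES: dict[str, float] = {
    "interest_pleasure": 1.6,
    "down_depressed": 1.7,
    "hopeless": 0.9,
    "trouble_sleep": 1.2,
    "sleep_too_much": 0.2,
    "tired": 2.3,
    "poor_appetite": 0.2,
    "overeating": 0.3,
    "feeling_bad": 1.1,
    "concentrating": 1.5,
    "moving_slowly": -0.9,
    "fidgety": 0.1,
    "irritable": 1.4,
    "low_libido": 1.0,
}

_NEUROCOG_TASKS = ("dsc", "crt", "vat", "ert", "gradcpt", "mot")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study design: 13 weeks, PHQ-14 at weeks
    0, 1, 2, 4, 6, 7, 8, 10 and 12, PSQI at weeks 0, 6 and 12, and 27 % of
    participants lacking sleep annotations entirely (the availability gap
    between enrolled and analyzable participants).
    """

    n_participants: int
    study_weeks: int = 13
    phq_weeks: Sequence[int] = (0, 1, 2, 4, 6, 7, 8, 10, 12)
    psqi_weeks: Sequence[int] = (0, 6, 12)
    #: symptom name -> (physiological latent name, signed log-odds per SD)
    effect_sizes: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    #: SD (hours) of misperception noise on reported durations/clock times;
    #: also used as the SD of the additive noise on log-latency.  The
    #: default is deliberately large relative to between-person spread so
    #: that objective-subjective concordance sits in the weak-to-moderate
    #: regime typical of retrospective sleep self-report.
    misperception_sd: float = 1.5
    #: multiplicative bias on reported latency, on the log scale (0 = none)
    latency_report_log_bias: float = 0.0
    #: additive bias (h) on reported sleep duration (0 = none)
    duration_report_bias_h: float = 0.0
    #: per-hour probability of at least one heart-rate log
    wear_prob: float = 0.92
    #: per-day probability of a secondary (nap) bed-rest block
    nap_rate: float = 0.05
    #: fraction of participants who emit no sleep annotations at all
    missing_annotation_frac: float = 0.27
    #: loading of the shared distress factor on questionnaire items
    symptom_loading: float = 0.8
    #: SD of per-participant, per-item propensity noise
    propensity_sd: float = 0.8
    #: probability that a true awakening is perceived and hence reportable
    awakening_report_prob: float = 0.5
    #: link from disturbance propensity to neurocognitive ability (a
    #: positive value lowers ability for participants with more
    #: self-reported disturbances; 0 = no link)
    neurocog_link: float = 0.0
    start_date: str = "2023-01-02"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.study_weeks < 1:
            raise ConfigError(f"study_weeks must be >= 1, got {self.study_weeks}")
        for name in ("wear_prob", "nap_rate", "missing_annotation_frac", "awakening_report_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("phq_weeks", "psqi_weeks"):
            weeks = list(getattr(self, name))
            if any(b <= a for a, b in zip(weeks, weeks[1:])):
                raise ConfigError(f"{name} must be strictly increasing, got {weeks}")
            if weeks and (weeks[0] < 0 or weeks[-1] >= self.study_weeks):
                raise ConfigError(f"{name} must lie in [0, study_weeks), got {weeks}")
        if self.misperception_sd < 0:
            raise ConfigError(f"misperception_sd must be >= 0, got {self.misperception_sd}")
        for symptom, link in self.effect_sizes.items():
            if symptom not in PHQ_ITEMS:
                raise ConfigError(f"effect_sizes: unknown symptom {symptom!r}")
            latent, _beta = link
            if latent not in PHYSIO_LATENTS:
                raise ConfigError(f"effect_sizes[{symptom!r}]: unknown latent {latent!r}")


@dataclass(frozen=True)
class LatentTraits:
    """Ground-truth per-participant traits (kept for recovery tests)."""

    participant_id: str
    mean_bedrest_onset: float  # clock h
    mean_bedrest_duration: float  # h
    mean_latency: float  # min
    awakening_rate: float  # expected awakenings/night
    efficiency_baseline: float  # fraction in (0, 1]
    symptom_propensities: dict[str, float]
    neurocog_ability: float
    distress: float
    latent_z: dict[str, float]  # standardized physiological latents
    quietness_db: float
    has_annotations: bool


@dataclass
class CohortTruth:
    """Everything the generator knows that the pipeline must not see."""

    traits: dict[str, LatentTraits]
    night_truth: pd.DataFrame  # per-night true metrics incl. anchored clocks
    latent_z: pd.DataFrame  # one row per participant, standardized latents


@dataclass
class CohortDataset:
    """One generated cohort, raw-stream side only (plus hidden truth)."""

    config: GeneratorConfig
    participants: list[str]
    annotations: pd.DataFrame  # participant_id, start, end, state
    hr_logs: pd.DataFrame  # participant_id, timestamp
    noise_logs: pd.DataFrame  # participant_id, timestamp, db
    surveys: pd.DataFrame  # participant_id, week, event_time, instrument, item, value
    neurocog: pd.DataFrame  # participant_id, week, event_time, task, metrics...
    annotation_free: tuple[str, ...]
    truth: CohortTruth


def _composition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into ``parts`` positive integers, uniformly at random."""
    if parts <= 0:
        return np.zeros(0, dtype=int)
    if parts == 1:
        return np.array([total], dtype=int)
    return rng.multinomial(total - parts, np.full(parts, 1.0 / parts)) + 1


def generate_wear_pattern(
    n_hours: int, wear_prob: float, rng: np.random.Generator, start_minute: int = 0
) -> np.ndarray:
    """Hourly heart-rate log minutes over a window of ``n_hours`` hours.

    Each hour independently contains one log with probability ``wear_prob``,
    placed at a uniform minute within the hour; returns minutes offsets
    from ``start_minute``.  The expected wear fraction over the window is
    therefore exactly ``wear_prob``.
    """
    if not 0.0 <= wear_prob <= 1.0:
        raise ConfigError(f"wear_prob must be in [0, 1], got {wear_prob}")
    worn = rng.random(n_hours) < wear_prob
    offsets = rng.integers(0, 60, size=n_hours)
    hours = np.nonzero(worn)[0]
    return start_minute + hours * 60 + offsets[hours]


def _draw_traits(pid: str, cfg: GeneratorConfig, rng: np.random.Generator) -> LatentTraits:
    z_onset, z_dur, z_lat, z_awk, z_eff = rng.standard_normal(5)
    g = rng.standard_normal()
    onset_sd_total = math.hypot(_ONSET_SD, _DUR_SD)
    latent_z = {
        "bedrest_onset": z_onset,
        "bedrest_duration": z_dur,
        "sleep_offset": (_ONSET_SD * z_onset + _DUR_SD * z_dur) / onset_sd_total,
        "latency": z_lat,
        "awakenings": z_awk,
        "efficiency": z_eff,
    }
    item_noise = rng.standard_normal(len(PHQ_ITEMS))
    propensities = {
        item: DEFAULT_PHQ_BASELINES[item] + cfg.symptom_loading * g + cfg.propensity_sd * n
        for item, n in zip(PHQ_ITEMS, item_noise)
    }
    for symptom, (latent, beta) in cfg.effect_sizes.items():
        propensities[symptom] += beta * latent_z[latent]
    z_disturb = rng.standard_normal()
    z_neuro = rng.standard_normal()
    link = cfg.neurocog_link
    ability = -link * z_disturb + math.sqrt(max(0.0, 1.0 - link * link)) * z_neuro
    return LatentTraits(
        participant_id=pid,
        mean_bedrest_onset=(_ONSET_CLOCK_MEAN + _ONSET_SD * z_onset) % 24.0,
        mean_bedrest_duration=float(np.clip(_DUR_MEAN + _DUR_SD * z_dur, 5.0, 11.5)),
        mean_latency=float(np.clip(math.exp(_LAT_LOG_MEAN + _LAT_LOG_SD * z_lat), 1.0, 120.0)),
        awakening_rate=float(math.exp(_AWAKE_LOG_MEAN + _AWAKE_LOG_SD * z_awk)),
        efficiency_baseline=float(_expit(_EFF_LOGIT_MEAN + _EFF_LOGIT_SD * z_eff)),
        symptom_propensities=propensities,
        neurocog_ability=float(ability),
        distress=float(g),
        latent_z={**latent_z, "disturbance": z_disturb},
        quietness_db=float(30.0 + 5.0 * rng.standard_normal()),
        has_annotations=bool(rng.random() >= cfg.missing_annotation_frac),
    )


def _generate_nights(
    traits: LatentTraits, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[tuple], list[tuple], dict[str, np.ndarray]]:
    """Minute-grid intervals plus true per-night metrics for one participant.

    Returns (interval rows, noise rows, night-truth arrays); interval rows
    are (start_min, end_min, state) with minutes counted from local
    midnight of the study start date.
    """
    n_days = cfg.study_weeks * 7
    anchor_mean = clock_to_anchor(traits.mean_bedrest_onset)
    z = rng.standard_normal((n_days, 5))  # onset, duration, efficiency, latency, terminal
    k_awake = rng.poisson(traits.awakening_rate, n_days)
    nap_today = rng.random(n_days) < cfg.nap_rate

    intervals: list[tuple] = []
    noise_rows: list[tuple] = []
    tr: dict[str, list] = {k: [] for k in (
        "day_index", "bedrest_start_min", "bedrest_min", "sleep_min", "latency_min",
        "awakenings", "awake_in_bed_min", "onset_anchor_h", "offset_anchor_h",
        "sleep_onset_anchor_h", "sleep_offset_anchor_h",
    )}
    prev_end = -1
    for d in range(n_days):
        onset_anchor = float(np.clip(anchor_mean + _NIGHT_ONSET_SD * z[d, 0], 3.5, 14.0))
        onset = d * 1440 + 900 + int(round(onset_anchor * 60.0))
        b_min = int(round(np.clip(traits.mean_bedrest_duration + _NIGHT_DUR_SD * z[d, 1], 4.0, 13.0) * 60.0))
        eff = float(np.clip(traits.efficiency_baseline + _NIGHT_EFF_SD * z[d, 2], 0.35, 0.999))
        awake_budget = int(round(b_min * (1.0 - eff)))
        awake_budget = min(awake_budget, b_min - 1)
        lat = int(round(math.exp(math.log(traits.mean_latency) + _NIGHT_LAT_LOG_SD * z[d, 3])))
        lat = max(0, min(lat, awake_budget))
        terminal = int(round(math.exp(1.2 + 0.7 * z[d, 4])))
        terminal = max(0, min(terminal, awake_budget - lat))
        mid = awake_budget - lat - terminal
        k = int(k_awake[d])
        if k == 0 and mid > 0:
            k = 1
        k = min(k, mid)  # each awakening needs >= 1 minute
        sleep_total = b_min - awake_budget
        k = min(k, sleep_total - 1)
        gaps = _composition(mid, k, rng) if k > 0 else np.zeros(0, dtype=int)
        if k == 0:
            terminal += mid
        segs = _composition(sleep_total, k + 1, rng)

        # optional nap before tonight's main block (skipped if the previous
        # night ran so late it would overlap)
        if nap_today[d]:
            nap_start = d * 1440 + 13 * 60 + int(rng.integers(0, 90))
            nap_len = 30 + int(rng.integers(0, 61))
            nap_sleep_delay = int(rng.integers(0, 6))
            nap_sleep_len = max(1, int(round((nap_len - nap_sleep_delay) * (0.85 + 0.15 * rng.random()))))
            if nap_start > prev_end:
                intervals.append((nap_start, nap_start + nap_len, "inBed"))
                intervals.append(
                    (nap_start + nap_sleep_delay, nap_start + nap_sleep_delay + nap_sleep_len, "asleep")
                )

        intervals.append((onset, onset + b_min, "inBed"))
        t = onset + lat
        for i, s in enumerate(segs):
            intervals.append((t, t + int(s), "asleep"))
            t += int(s)
            if i < k:
                t += int(gaps[i])
        prev_end = onset + b_min

        for m in range(onset + 30, onset + b_min, 60):
            noise_rows.append((m, traits.quietness_db + 3.0 * rng.standard_normal()))
        for _ in range(2):
            noise_rows.append(
                (d * 1440 + int(rng.integers(600, 840)), 45.0 + 5.0 * rng.standard_normal())
            )

        tr["day_index"].append(d)
        tr["bedrest_start_min"].append(onset)
        tr["bedrest_min"].append(b_min)
        tr["sleep_min"].append(sleep_total)
        tr["latency_min"].append(lat)
        tr["awakenings"].append(k)
        tr["awake_in_bed_min"].append(int(mid if k > 0 else 0))
        tr["onset_anchor_h"].append(onset_anchor)
        tr["offset_anchor_h"].append(onset_anchor + b_min / 60.0)
        tr["sleep_onset_anchor_h"].append(onset_anchor + lat / 60.0)
        tr["sleep_offset_anchor_h"].append(onset_anchor + (b_min - terminal) / 60.0)
    return intervals, noise_rows, {k: np.asarray(v) for k, v in tr.items()}


def _freq_ordinal(events_per_week: float) -> int:
    """Map a weekly occurrence rate onto the 0-3 PSQI frequency coding."""
    if events_per_week <= 0:
        return 0
    if events_per_week < 1:
        return 1
    if events_per_week < 3:
        return 2
    return 3


def _ordinal_from_eta(eta: float, u: float) -> int:
    probs = _expit(eta - np.asarray(_CUTS))
    return int(np.sum(u < probs))


def _psqi_report(
    traits: LatentTraits,
    cfg: GeneratorConfig,
    night: dict[str, np.ndarray],
    event_min: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Self-reported PSQI quantities for the 28 days before ``event_min``.

    Reports are the realized window means plus misperception noise; when no
    nights fall in the window (the baseline wave), trait expectations stand
    in for the realized means.
    """
    lo = event_min - 28 * 1440
    sel = (night["bedrest_start_min"] >= lo) & (night["bedrest_start_min"] < event_min)
    mis = cfg.misperception_sd
    e = rng.standard_normal(4)
    if sel.any():
        true_dur = float(np.mean(night["sleep_min"][sel])) / 60.0
        true_onset = float(np.mean(night["onset_anchor_h"][sel]))
        true_offset = float(np.mean(night["offset_anchor_h"][sel]))
        true_lat = float(np.mean(night["latency_min"][sel]))
        n_nights = int(sel.sum())
        weeks = n_nights / 7.0
        lat30_rate = float(np.sum(night["latency_min"][sel] >= 30)) / weeks
        perceived = rng.binomial(night["awakenings"][sel].astype(int), cfg.awakening_report_prob)
        awake_rate = float(np.sum(perceived >= 1)) / weeks
    else:
        true_dur = traits.mean_bedrest_duration * traits.efficiency_baseline
        true_onset = float(clock_to_anchor(traits.mean_bedrest_onset))
        true_offset = true_onset + traits.mean_bedrest_duration
        true_lat = traits.mean_latency
        p30 = float(norm.sf((math.log(30.0) - math.log(traits.mean_latency)) / _NIGHT_LAT_LOG_SD))
        lat30_rate = 7.0 * p30
        p_any = 1.0 - math.exp(-traits.awakening_rate * cfg.awakening_report_prob)
        awake_rate = 7.0 * p_any
    hours_of_sleep = max(0.0, true_dur + cfg.duration_report_bias_h + mis * e[0])
    bedtime = anchor_to_clock((true_onset + mis * e[1]) % 24.0)
    waketime = anchor_to_clock((true_offset + mis * e[2]) % 24.0)
    if true_lat <= 0:
        minutes_to_sleep = 0.0
    else:
        minutes_to_sleep = math.exp(math.log(true_lat) + cfg.latency_report_log_bias + mis * e[3])
    return {
        "bedtime": bedtime,
        "waketime": waketime,
        "minutes_to_sleep": minutes_to_sleep,
        "hours_of_sleep": hours_of_sleep,
        "cant_sleep_30min": _freq_ordinal(lat30_rate),
        "wake_middle_night": _freq_ordinal(awake_rate),
    }


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate one cohort.  Deterministic given ``config`` (incl. seed)."""
    config.validate()
    cfg = config
    n_days = cfg.study_weeks * 7
    base = pd.Timestamp(cfg.start_date, tz=STUDY_TZ)

    ann_rows: list[tuple] = []
    hr_rows: list[tuple] = []
    noise_all: list[tuple] = []
    survey_rows: list[tuple] = []
    neuro_rows: list[dict] = []
    night_frames: list[pd.DataFrame] = []
    traits_by_pid: dict[str, LatentTraits] = {}
    latent_rows: list[dict] = []
    participants: list[str] = []
    annotation_free: list[str] = []

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:04d}"
        participants.append(pid)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
        traits = _draw_traits(pid, cfg, rng)
        traits_by_pid[pid] = traits
        latent_rows.append({"participant_id": pid, **traits.latent_z, "distress": traits.distress})
        if not traits.has_annotations:
            annotation_free.append(pid)

        intervals, noise_rows, night = _generate_nights(traits, cfg, rng)
        nf = pd.DataFrame(night)
        nf.insert(0, "participant_id", pid)
        night_frames.append(nf)
        if traits.has_annotations:
            ann_rows.extend((pid, s, e, st) for s, e, st in intervals)
        noise_all.extend((pid, m, db) for m, db in noise_rows)

        # watch wear starts at intake, 8 days before the first study week,
        # so early-week QC windows are not truncated by enrollment
        hr_minutes = generate_wear_pattern(
            (n_days + 8) * 24, cfg.wear_prob, rng, start_minute=-8 * 1440
        )
        hr_rows.extend((pid, int(m)) for m in hr_minutes)

        # ---- questionnaire propensities beyond the PHQ items ----
        g = traits.distress
        z = traits.latent_z
        disturb_prop = (
            0.5 + 0.7 * cfg.symptom_loading * g + 0.4 * z["awakenings"] + 0.6 * z["disturbance"]
        )
        item_noise = {
            item: 0.8 * rng.standard_normal() for item in PSQI_DISTURBANCE_ITEMS[1:]
        }
        quality_prop = 0.4 + cfg.symptom_loading * g + 0.4 * z["latency"] - 0.3 * z["efficiency"]
        medication_prop = -1.2 + 0.5 * g + 0.8 * rng.standard_normal()
        daytime_prop = 0.3 + cfg.symptom_loading * g + 0.5 * rng.standard_normal()

        # ---- PHQ-14 waves ----
        for w in cfg.phq_weeks:
            event_min = w * 7 * 1440 + 18 * 60 + int(rng.integers(-120, 121))
            recall = 2 if w in (0, 6) else 1
            survey_rows.append((pid, w, event_min, "phq14", "recall_weeks", float(recall)))
            for item in PHQ_ITEMS:
                if item == "low_libido" and rng.random() < 0.04:
                    survey_rows.append((pid, w, event_min, "phq14", item, float("nan")))
                    continue
                score = _ordinal_from_eta(traits.symptom_propensities[item], rng.random())
                survey_rows.append((pid, w, event_min, "phq14", item, float(score)))

        # ---- PSQI waves (+ neurocognitive session the same day) ----
        for w in cfg.psqi_weeks:
            event_min = w * 7 * 1440 + 18 * 60 + int(rng.integers(-120, 121))
            report = _psqi_report(traits, cfg, night, event_min, rng)
            for item, value in report.items():
                survey_rows.append((pid, w, event_min, "psqi", item, float(value)))
            for item in PSQI_DISTURBANCE_ITEMS[1:]:
                score = _ordinal_from_eta(disturb_prop + item_noise[item], rng.random())
                survey_rows.append((pid, w, event_min, "psqi", item, float(score)))
            for item, prop in (
                ("sleep_quality", quality_prop),
                ("sleep_medication", medication_prop),
                ("trouble_staying_awake", daytime_prop),
                ("low_enthusiasm", daytime_prop + 0.3 * g),
            ):
                survey_rows.append(
                    (pid, w, event_min, "psqi", item, float(_ordinal_from_eta(prop, rng.random())))
                )

            ability = traits.neurocog_ability
            en = rng.standard_normal(10)
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="dsc",
                     accuracy=float(np.clip(0.90 + 0.04 * ability + 0.03 * en[0], 0.0, 1.0)),
                     median_rt=900.0 * math.exp(-0.15 * ability + 0.10 * en[1])))
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="crt",
                     accuracy=float(np.clip(0.95 + 0.02 * ability + 0.02 * en[2], 0.0, 1.0)),
                     median_rt=450.0 * math.exp(-0.12 * ability + 0.08 * en[3])))
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="vat",
                     accuracy=float(_expit(1.5 + 0.5 * ability + 0.3 * en[4]))))
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="ert",
                     accuracy=float(_expit(1.2 + 0.5 * ability + 0.3 * en[5]))))
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="gradcpt",
                     d_prime=2.0 + 0.5 * ability + 0.3 * en[6], crit=0.1 + 0.2 * en[7]))
            neuro_rows.append(
                dict(participant_id=pid, week=w, event_min=event_min, task="mot",
                     mot_correct=float(_expit(1.0 + 0.4 * ability + 0.3 * en[8]))))

    def _ts(minutes):
        return base + pd.to_timedelta(np.asarray(minutes, dtype="int64"), unit="m")

    annotations = pd.DataFrame(ann_rows, columns=["participant_id", "start", "end", "state"])
    annotations["start"] = _ts(annotations["start"]) if len(annotations) else pd.to_datetime([])
    annotations["end"] = _ts(annotations["end"]) if len(annotations) else pd.to_datetime([])
    annotations = annotations.sort_values(
        ["participant_id", "start", "state"], kind="mergesort"
    ).reset_index(drop=True)

    hr_logs = pd.DataFrame(hr_rows, columns=["participant_id", "minute"])
    hr_logs["timestamp"] = _ts(hr_logs["minute"]) if len(hr_logs) else pd.to_datetime([])
    hr_logs = hr_logs.drop(columns=["minute"])

    noise_logs = pd.DataFrame(noise_all, columns=["participant_id", "minute", "db"])
    noise_logs["timestamp"] = _ts(noise_logs["minute"]) if len(noise_logs) else pd.to_datetime([])
    noise_logs = noise_logs[["participant_id", "timestamp", "db"]]

    surveys = pd.DataFrame(
        survey_rows,
        columns=["participant_id", "week", "event_min", "instrument", "item", "value"],
    )
    surveys["event_time"] = _ts(surveys["event_min"])
    surveys = surveys[["participant_id", "week", "event_time", "instrument", "item", "value"]]

    neurocog = pd.DataFrame(neuro_rows)
    if len(neurocog):
        neurocog["event_time"] = _ts(neurocog["event_min"])
        neurocog = neurocog.drop(columns=["event_min"])

    night_truth = pd.concat(night_frames, ignore_index=True)
    night_truth["bedrest_start"] = _ts(night_truth["bedrest_start_min"])

    return CohortDataset(
        config=cfg,
        participants=participants,
        annotations=annotations,
        hr_logs=hr_logs,
        noise_logs=noise_logs,
        surveys=surveys,
        neurocog=neurocog,
        annotation_free=tuple(annotation_free),
        truth=CohortTruth(
            traits=traits_by_pid,
            night_truth=night_truth,
            latent_z=pd.DataFrame(latent_rows),
        ),
    )
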