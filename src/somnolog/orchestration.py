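"""End-to-end experiment drivers.

Four analyses run on a (generated or loaded) cohort:

- ``concordance``: Spearman correlation of physiological 28-day sleep
  aggregates against their self-reported PSQI counterparts;
- ``symptom-detection``: nested-CV detection of each PHQ-14 symptom from
  passive sleep features or same-day PSQI responses;
- ``neurocog``: Spearman cross-correlation of sleep measures (watch
  medians and PSQI domains) with neurocognitive task metrics;
- ``psqi-change``: detection of PSQI domain/total binaries from passive
  features, the prior response, or both, with paired augmentation tests.

All randomness flows from one master seed through named substreams
(generator, folds/search, resampling, shapley), each recorded in the run
manifest so a run is reproducible artifact-by-artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from somnolog import io as sio
from somnolog.ml_pipeline import ModelSpace, TargetSkipped, nested_cv_fit_predict
from somnolog.questionnaires import (
    PHQ_ITEMS,
    PSQI_COMPONENTS,
    PSQI_ITEMS,
    score_phq_events,
    score_psqi_events,
)
from somnolog.sleep_features import (
    annotations_to_night_records,
    feature_table,
    model_matrix,
    qc_filter,
)
from somnolog.stats_eval import (
    bh_adjust,
    compare_feature_sets,
    neurocog_correlations,
    neurocog_metric_table,
    paired_sleep_correlations,
    resampled_fold_metrics,
    test_above_chance,
)
from somnolog.synthetic_data import CohortDataset, GeneratorConfig, generate_cohort

log = logging.getLogger("somnolog")

__all__ = [
    "STREAMS",
    "derive_seed",
    "CohortTables",
    "prepare_cohort_tables",
    "run_symptom_detection",
    "run_concordance",
    "run_neurocog",
    "run_psqi_change",
    "run_experiment",
    "validate_inputs",
]

#: Named substreams of the master seed (stable order).
STREAMS = ("generator", "folds", "search", "resampling", "shapley")


def derive_seed(master_seed: int, stream: str) -> int:
    """A stable sub-seed (< 2**31) for one named randomness stream."""
    idx = STREAMS.index(stream)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)


class CohortTables:
    """Derived tables for one cohort: nights, features, scored surveys."""

    def __init__(self, cohort: CohortDataset, latency_rule: str = "as_printed"):
        self.cohort = cohort
        self.night_records, self.annotation_issues = annotations_to_night_records(
            cohort.annotations, cohort.noise_logs
        )
        surveys = cohort.surveys
        self.phq_scored = score_phq_events(surveys)
        self.psqi_scored = score_psqi_events(surveys, latency_rule=latency_rule)
        events = surveys[["participant_id", "week", "event_time", "instrument"]].drop_duplicates()
        self.features = feature_table(self.night_records, cohort.hr_logs, events_with_instrument(events))
        phq_feat = self.features[self.features["window_days"] == 8]
        psqi_feat = self.features[self.features["window_days"] == 28]
        self.phq_features, self.phq_exclusions = qc_filter(phq_feat)
        self.psqi_features, self.psqi_exclusions = qc_filter(psqi_feat)


def events_with_instrument(events: pd.DataFrame) -> pd.DataFrame:
    return events[events["instrument"].isin(["phq14", "psqi"])].reset_index(drop=True)


def prepare_cohort_tables(cohort: CohortDataset, **kw) -> CohortTables:
    return CohortTables(cohort, **kw)


# ---------------------------------------------------------------------------
# Feature-set assembly
# ---------------------------------------------------------------------------

_PSQI_PREDICTOR_COLS = (
    [c for c in PSQI_ITEMS] + [f"comp_{c}" for c in PSQI_COMPONENTS] + ["global_score"]
)


def _xy_for_phq_target(tables: CohortTables, target: str, feature_set: str):
    """Design matrix, labels and groups for one PHQ-14 item target."""
    scored = tables.phq_scored
    col = f"target_{target}"
    if feature_set == "passive":
        merged = tables.phq_features.merge(
            scored[["participant_id", "week", col]], on=["participant_id", "week"]
        )
        merged = merged[~merged[col].isna()]
        X = model_matrix(merged)
    elif feature_set == "psqi":
        # same-day PSQI item-level responses; baseline included (this
        # pairing involves no sensor window)
        merged = scored.merge(
            tables.psqi_scored[["participant_id", "week"] + _PSQI_PREDICTOR_COLS],
            on=["participant_id", "week"],
        )
        merged = merged[~merged[col].isna()]
        X = merged[_PSQI_PREDICTOR_COLS].astype(float)
    else:
        raise ValueError(f"unknown feature set for symptom detection: {feature_set!r}")
    y = merged[col].astype(int).to_numpy()
    groups = merged["participant_id"].to_numpy()
    return X, y, groups, merged


def run_symptom_detection(
    tables: CohortTables,
    feature_set: str = "passive",
    targets=None,
    space: ModelSpace = ModelSpace(),
    seed: int = 0,
    n_folds: int = 10,
    inner_folds: int = 5,
    grouped_inner: bool = True,
    n_draws: int = 100,
    fdr: float = 0.05,
):
    """Detect each PHQ-14 symptom; one row per target plus dummy baseline.

    Returns ``(results, predictions)``: results hold the winning family,
    median resampled fold AUROC/AUPRC, raw and BH-adjusted (per survey
    family) Wilcoxon p-values against chance, and the dummy baseline's
    median AUROC and p; predictions map target name to
    :class:`~somnolog.ml_pipeline.CVPredictions`.
    """
    targets = list(targets) if targets is not None else list(PHQ_ITEMS)
    fold_seed = derive_seed(seed, "folds")
    resample_seed = derive_seed(seed, "resampling")
    rows = []
    predictions = {}
    for t in targets:
        try:
            X, y, groups, _ = _xy_for_phq_target(tables, t, feature_set)
            pred = nested_cv_fit_predict(
                X, y, groups, space=space, n_folds=n_folds, inner_folds=inner_folds,
                grouped_inner=grouped_inner, seed=fold_seed, target=t, feature_set=feature_set,
            )
        except TargetSkipped as err:
            log.info("target %s skipped: %s", t, err)
            rows.append({"target": t, "skipped": str(err)})
            continue
        predictions[t] = pred
        fm = resampled_fold_metrics(pred, n_draws=n_draws, seed=resample_seed)
        fm_dummy = resampled_fold_metrics(
            pred.for_scores("score_dummy"), n_draws=n_draws, seed=resample_seed
        )
        families = [w["family"] for w in pred.winners.values()]
        rows.append(
            {
                "target": t,
                "model": max(set(families), key=families.count),
                "median_auroc": float(fm["auroc"].median()),
                "median_auprc": float(fm["auprc"].median()),
                "p_raw": test_above_chance(fm["auroc"]),
                "dummy_median_auroc": float(fm_dummy["auroc"].median()),
                "dummy_p_raw": test_above_chance(fm_dummy["auroc"]),
                "n_events": int(len(y)),
                "n_participants": int(len(np.unique(groups))),
            }
        )
    results = pd.DataFrame(rows)
    if "p_raw" in results.columns:
        results["p_adjusted"] = np.nan
        results["dummy_p_adjusted"] = np.nan
        results["significant"] = False
        run_mask = ~results["p_raw"].isna()
        if run_mask.any():
            adj, rej = bh_adjust(results.loc[run_mask, "p_raw"], fdr=fdr)
            results.loc[run_mask, "p_adjusted"] = adj
            results.loc[run_mask, "significant"] = rej
            d_adj, _ = bh_adjust(results.loc[run_mask, "dummy_p_raw"], fdr=fdr)
            results.loc[run_mask, "dummy_p_adjusted"] = d_adj
    return results, predictions


def run_concordance(tables: CohortTables, fdr: float = 0.05) -> pd.DataFrame:
    """Fig-1-style physiological vs. self-reported concordance table."""
    return paired_sleep_correlations(tables.psqi_features, tables.psqi_scored, fdr=fdr)


def run_neurocog(tables: CohortTables, fdr: float = 0.05) -> pd.DataFrame:
    """Sleep (watch medians + PSQI domains) vs. neurocognition correlations."""
    median_cols = [
        "median_sleep_duration", "median_sleep_efficiency", "median_sleep_onset_latency",
        "median_sleep_onset", "median_sleep_offset", "median_bedrest_onset",
        "median_bedrest_offset", "median_bedrest_duration",
    ]
    domain_cols = [f"comp_{c}" for c in PSQI_COMPONENTS] + ["global_score"]
    sleep = tables.psqi_features.merge(
        tables.psqi_scored[["participant_id", "week"] + domain_cols],
        on=["participant_id", "week"],
    )
    neuro = neurocog_metric_table(tables.cohort.neurocog)
    return neurocog_correlations(sleep, neuro, median_cols + domain_cols, fdr=fdr)


def _psqi_change_design(tables: CohortTables, target: str, feature_set: str):
    col = f"target_{target}"
    scored = tables.psqi_scored.copy()
    current = tables.psqi_features.merge(
        scored[["participant_id", "week", col]], on=["participant_id", "week"]
    )
    prior = scored[["participant_id", "week"] + _PSQI_PREDICTOR_COLS].copy()
    prior["week"] = prior["week"] + 6  # align each response to the next wave
    prior = prior.rename(columns={c: f"prior_{c}" for c in _PSQI_PREDICTOR_COLS})
    merged = current.merge(prior, on=["participant_id", "week"])
    merged = merged[~merged[col].isna()]
    passive_X = model_matrix(merged)
    prior_X = merged[[f"prior_{c}" for c in _PSQI_PREDICTOR_COLS]].astype(float)
    if feature_set == "passive":
        X = passive_X
    elif feature_set == "prior":
        X = prior_X
    elif feature_set == "passive+prior":
        X = pd.concat([passive_X.reset_index(drop=True), prior_X.reset_index(drop=True)], axis=1)
    else:
        raise ValueError(f"unknown feature set for psqi-change: {feature_set!r}")
    y = merged[col].astype(int).to_numpy()
    groups = merged["participant_id"].to_numpy()
    return X, y, groups, merged


def run_psqi_change(
    tables: CohortTables,
    targets=None,
    feature_sets=("passive", "passive+prior", "prior"),
    space: ModelSpace = ModelSpace(),
    seed: int = 0,
    n_folds: int = 10,
    inner_folds: int = 5,
    grouped_inner: bool = True,
    n_draws: int = 100,
    fdr: float = 0.05,
):
    """PSQI domain/total detection with and without passive data.

    Returns ``(results, augmentation, predictions)``.  ``results`` has one
    row per target x feature set with median fold AUROC/AUPRC and
    above-chance p-values (BH-adjusted within feature set); ``augmentation``
    holds the paired one-sided t-tests that passive+prior beats prior, per
    target and metric, BH-adjusted across targets within metric.
    """
    from somnolog.questionnaires import PSQI_TARGETS

    targets = list(targets) if targets is not None else list(PSQI_TARGETS)
    fold_seed = derive_seed(seed, "folds")
    resample_seed = derive_seed(seed, "resampling")
    rows = []
    fold_metrics: dict[tuple[str, str], pd.DataFrame] = {}
    predictions: dict[tuple[str, str], object] = {}
    for t in targets:
        for fs in feature_sets:
            try:
                X, y, groups, _ = _psqi_change_design(tables, t, fs)
                pred = nested_cv_fit_predict(
                    X, y, groups, space=space, n_folds=n_folds, inner_folds=inner_folds,
                    grouped_inner=grouped_inner, seed=fold_seed, target=t, feature_set=fs,
                )
            except TargetSkipped as err:
                log.info("psqi-change %s/%s skipped: %s", t, fs, err)
                rows.append({"target": t, "feature_set": fs, "skipped": str(err)})
                continue
            predictions[(t, fs)] = pred
            fm = resampled_fold_metrics(pred, n_draws=n_draws, seed=resample_seed)
            fold_metrics[(t, fs)] = fm
            families = [w["family"] for w in pred.winners.values()]
            rows.append(
                {
                    "target": t,
                    "feature_set": fs,
                    "model": max(set(families), key=families.count),
                    "median_auroc": float(fm["auroc"].median()),
                    "median_auprc": float(fm["auprc"].median()),
                    "p_raw": test_above_chance(fm["auroc"]),
                    "n_events": int(len(y)),
                }
            )
    results = pd.DataFrame(rows)
    if "p_raw" in results.columns:
        results["p_adjusted"] = np.nan
        results["significant"] = False
        for fs in feature_sets:
            m = (results["feature_set"] == fs) & (~results["p_raw"].isna())
            if m.any():
                adj, rej = bh_adjust(results.loc[m, "p_raw"], fdr=fdr)
                results.loc[m, "p_adjusted"] = adj
                results.loc[m, "significant"] = rej

    aug_rows = []
    for metric in ("auroc", "auprc"):
        for t in targets:
            a = fold_metrics.get((t, "passive+prior"))
            b = fold_metrics.get((t, "prior"))
            if a is None or b is None:
                continue
            delta = a[metric].to_numpy(float) - b[metric].to_numpy(float)
            aug_rows.append(
                {
                    "target": t,
                    "metric": metric,
                    "median_delta": float(np.nanmedian(delta)),
                    "p_raw": compare_feature_sets(a[metric], b[metric]),
                }
            )
    augmentation = pd.DataFrame(aug_rows)
    if len(augmentation):
        augmentation["p_adjusted"] = np.nan
        augmentation["significant"] = False
        for metric in ("auroc", "auprc"):
            m = augmentation["metric"] == metric
            if m.any():
                adj, rej = bh_adjust(augmentation.loc[m, "p_raw"], fdr=fdr)
                augmentation.loc[m, "p_adjusted"] = adj
                augmentation.loc[m, "significant"] = rej
    return results, augmentation, predictions


# ---------------------------------------------------------------------------
# Top-level runner
# ---------------------------------------------------------------------------

ANALYSES = ("concordance", "symptom-detection", "neurocog", "psqi-change")


def _manifest(config: GeneratorConfig, seed: int, tables: CohortTables, extra: dict) -> dict:
    cfg_yaml = {k: str(getattr(config, k)) for k in GeneratorConfig.__dataclass_fields__}
    cfg_hash = hashlib.sha256(json.dumps(cfg_yaml, sort_keys=True).encode()).hexdigest()
    return {
        "config_hash": cfg_hash,
        "master_seed": seed,
        "stream_seeds": {s: derive_seed(seed, s) for s in STREAMS},
        "exclusions": {
            "phq": tables.phq_exclusions["reason"].value_counts().to_dict(),
            "psqi": tables.psqi_exclusions["reason"].value_counts().to_dict(),
        },
        "n_participants": len(tables.cohort.participants),
        "n_annotation_free": len(tables.cohort.annotation_free),
        "annotation_issues": len(tables.annotation_issues),
        **extra,
    }


def run_experiment(
    config: GeneratorConfig | str,
    analysis: str,
    out_dir,
    seed: int | None = None,
    space: ModelSpace | None = None,
    feature_set: str = "passive",
    targets=None,
) -> Path:
    """Run one named analysis end-to-end and persist its artifacts.

    ``config`` is a :class:`GeneratorConfig` or a path to its YAML form;
    ``seed`` overrides the config seed as the master seed.  Writes result
    CSVs, the exclusion log and a JSON run manifest under ``out_dir`` and
    returns that directory.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    if not isinstance(config, GeneratorConfig):
        config = sio.load_config(config)
    if seed is None:
        seed = config.seed
    gen_cfg = GeneratorConfig(
        **{
            **{k: getattr(config, k) for k in GeneratorConfig.__dataclass_fields__},
            "seed": derive_seed(seed, "generator"),
        }
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating cohort: n=%d seed=%d", gen_cfg.n_participants, gen_cfg.seed)
    cohort = generate_cohort(gen_cfg)
    tables = prepare_cohort_tables(cohort)
    log.info(
        "cohort ready: %d PHQ events kept (%d excluded), %d PSQI events kept (%d excluded)",
        len(tables.phq_features), len(tables.phq_exclusions),
        len(tables.psqi_features), len(tables.psqi_exclusions),
    )
    space = space or ModelSpace()
    extra: dict = {"analysis": analysis}

    if analysis == "concordance":
        run_concordance(tables).to_csv(out / "concordance.csv", index=False)
    elif analysis == "neurocog":
        run_neurocog(tables).to_csv(out / "neurocog_correlations.csv", index=False)
    elif analysis == "symptom-detection":
        results, _ = run_symptom_detection(
            tables, feature_set=feature_set, targets=targets, space=space, seed=seed
        )
        results.to_csv(out / f"symptom_detection_{feature_set}.csv", index=False)
    elif analysis == "psqi-change":
        results, augmentation, _ = run_psqi_change(tables, targets=targets, space=space, seed=seed)
        results.to_csv(out / "psqi_change.csv", index=False)
        augmentation.to_csv(out / "psqi_change_augmentation.csv", index=False)

    pd.concat([tables.phq_exclusions, tables.psqi_exclusions]).to_csv(
        out / "exclusions.csv", index=False
    )
    (out / "manifest.json").write_text(json.dumps(_manifest(config, seed, tables, extra), indent=2))
    return out


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(
    annotations: pd.DataFrame, surveys: pd.DataFrame | None = None
) -> dict:
    """Schema, overlap and timezone checks; never mutates inputs.

    Returns a report dict with ``errors`` (malformed rows, overlapping
    same-state intervals), ``warnings`` (asleep intervals outside any
    bed-rest block), and a per-participant coverage summary.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    required = {"participant_id", "start", "end", "state"}
    missing = required - set(annotations.columns)
    if missing:
        return {"errors": [f"missing annotation columns: {sorted(missing)}"],
                "warnings": [], "participants": {}}
    if len(annotations) and getattr(annotations["start"].dtype, "tz", None) is None:
        errors.append("annotation timestamps lack timezone information")
    bad_state = ~annotations["state"].isin(["inBed", "asleep"])
    for i in annotations.index[bad_state]:
        errors.append(f"row {i}: unknown state {annotations.loc[i, 'state']!r}")
    inverted = annotations["end"] <= annotations["start"]
    for i in annotations.index[inverted]:
        errors.append(f"row {i}: end does not follow start")
    coverage: dict[str, dict] = {}
    ok = annotations[~(bad_state | inverted)]
    for (pid, state), grp in ok.groupby(["participant_id", "state"], sort=True):
        grp = grp.sort_values("start")
        overlap = grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()
        for j in np.nonzero(overlap)[0]:
            errors.append(
                f"{pid}: overlapping {state} intervals at "
                f"{grp['start'].iloc[j + 1].isoformat()}"
            )
        cov = coverage.setdefault(pid, {})
        cov[f"n_{state}"] = int(len(grp))
    for pid, grp in ok.groupby("participant_id", sort=True):
        beds = grp[grp["state"] == "inBed"]
        sleeps = grp[grp["state"] == "asleep"]
        for _, r in sleeps.iterrows():
            inside = ((beds["start"] <= r["start"]) & (r["end"] <= beds["end"])).any()
            if not inside:
                warnings_.append(
                    f"{pid}: asleep interval {r['start'].isoformat()} outside any bedrest block"
                )
    if surveys is not None:
        req = {"participant_id", "week", "event_time", "instrument", "item", "value"}
        miss = req - set(surveys.columns)
        if miss:
            errors.append(f"missing survey columns: {sorted(miss)}")
    return {"errors": errors, "warnings": warnings_, "participants": coverage}
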