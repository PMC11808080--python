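"""Repeated-measures resampled metrics, tests against chance, FDR, and
per-prediction Shapley attributions.

Test-set folds contain several events per participant.  To neutralize the
repeated measures, fold-level AUROC/AUPRC are computed by drawing one
test event per participant, 100 times per fold, and aggregating the
draws (mean by default).  Fold values feed a one-sided Wilcoxon
signed-rank test against the chance level 0.5, with Benjamini-Hochberg
FDR control applied per questionnaire family.

Conventions: AUROC uses the midrank (trapezoidal) tie convention, so a
constant-score predictor scores exactly 0.5 in every draw; the Wilcoxon
test returns p = 1 when every fold sits exactly at chance (no evidence);
a paired t-statistic of exactly 0 maps to a one-sided p of 0.5.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from somnolog.questionnaires import rate_correct_score
from somnolog.timeutil import clock_to_anchor

__all__ = [
    "resampled_fold_metrics",
    "test_above_chance",
    "bh_adjust",
    "compare_feature_sets",
    "subgroup_performance",
    "Attribution",
    "shapley_attributions",
    "paired_sleep_correlations",
    "neurocog_correlations",
    "CONCORDANCE_PAIRS",
]


# ---------------------------------------------------------------------------
# Resampled fold metrics
# ---------------------------------------------------------------------------

def _single_draw_feasible(labels_by_pid: list[np.ndarray]) -> bool:
    has_pos = [i for i, l in enumerate(labels_by_pid) if (l == 1).any()]
    has_neg = [i for i, l in enumerate(labels_by_pid) if (l == 0).any()]
    if not has_pos or not has_neg:
        return False
    return len(set(has_pos) | set(has_neg)) >= 2


def _auroc_rows(y_mat: np.ndarray, s_mat: np.ndarray) -> np.ndarray:
    """Row-wise AUROC with the midrank tie convention (constant -> 0.5)."""
    ranks = stats.rankdata(s_mat, axis=1)
    n_pos = y_mat.sum(axis=1)
    n_neg = y_mat.shape[1] - n_pos
    pos_rank_sum = np.where(y_mat == 1, ranks, 0.0).sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _ap_row(y: np.ndarray, s: np.ndarray) -> float:
    """Average precision with threshold groups at distinct score values.

    Matches the step-interpolation convention AP = sum (R_k - R_{k-1}) P_k;
    a constant-score predictor scores the positive prevalence.
    """
    order = np.argsort(-s, kind="stable")
    y_o = y[order]
    s_o = s[order]
    ends = np.r_[np.nonzero(np.diff(s_o))[0], len(s_o) - 1]
    tp = np.cumsum(y_o)[ends].astype(float)
    fp = (ends + 1) - tp
    precision = tp / (tp + fp)
    recall_steps = np.diff(np.r_[0.0, tp]) / tp[-1]
    return float(np.sum(precision * recall_steps))


def resampled_fold_metrics(
    predictions,
    n_draws: int = 100,
    seed: int = 0,
    statistic: str = "mean",
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Per-fold AUROC/AUPRC from one-event-per-participant resampling.

    ``predictions`` is a :class:`~somnolog.ml_pipeline.CVPredictions` or a
    DataFrame with columns fold, participant_id, y_true, score.  Each of
    the ``n_draws`` draws selects one test event uniformly per participant
    and computes both metrics; the fold value aggregates the draws with
    ``statistic`` ("mean" or "median").  Draws containing a single class
    are redrawn (up to ``max_redraws`` rounds); a fold where no draw can
    contain both classes yields NaN metrics.
    """
    frame = predictions.frame if hasattr(predictions, "frame") else predictions
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    agg = np.mean if statistic == "mean" else np.median
    rng = np.random.default_rng(seed)
    rows = []
    for fold, grp in frame.groupby("fold", sort=True):
        labels, scores = [], []
        for _, sub in grp.groupby("participant_id", sort=True):
            labels.append(sub["y_true"].to_numpy(int))
            scores.append(sub["score"].to_numpy(float))
        if not _single_draw_feasible(labels):
            rows.append({"fold": fold, "auroc": np.nan, "auprc": np.nan, "n_draws": 0})
            continue
        sizes = np.array([len(l) for l in labels])
        offsets = np.r_[0, np.cumsum(sizes[:-1])]
        y_all = np.concatenate(labels)
        s_all = np.concatenate(scores)
        pick = rng.integers(0, sizes, size=(n_draws, len(sizes)))
        idx = offsets[None, :] + pick
        y_mat = y_all[idx]
        for _ in range(max_redraws):
            bad = np.nonzero((y_mat.sum(axis=1) == 0) | (y_mat.sum(axis=1) == len(sizes)))[0]
            if len(bad) == 0:
                break
            pick_bad = rng.integers(0, sizes, size=(len(bad), len(sizes)))
            idx[bad] = offsets[None, :] + pick_bad
            y_mat = y_all[idx]
        s_mat = s_all[idx]
        ok = (y_mat.sum(axis=1) > 0) & (y_mat.sum(axis=1) < len(sizes))
        aurocs = _auroc_rows(y_mat[ok], s_mat[ok])
        auprcs = np.array([_ap_row(y, s) for y, s in zip(y_mat[ok], s_mat[ok])])
        rows.append(
            {
                "fold": fold,
                "auroc": float(agg(aurocs)),
                "auprc": float(agg(auprcs)),
                "n_draws": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank vs. chance
# ---------------------------------------------------------------------------

def _signed_rank_p(diffs: np.ndarray, alternative: str = "greater") -> float:
    """One-sided signed-rank p with midranks; exact enumeration for n <= 15."""
    d = diffs[diffs != 0]
    n = len(d)
    if n == 0:
        return 1.0  # no evidence in either direction
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if alternative == "less":
        w = ranks.sum() - w  # symmetry: test the other tail
    if n <= 15:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        dist = signs @ ranks
        return float(np.mean(dist >= w - 1e-9))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w - mean - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def test_above_chance(
    fold_values, null: float = 0.5, alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p that the fold median exceeds ``null``.

    NaN folds are dropped; all-at-chance folds (every difference zero)
    return p = 1; otherwise zero differences are dropped per Wilcoxon's
    convention.  Small samples (n <= 15 nonzero differences, the usual
    10-fold case) use exact enumeration of the signed-rank distribution.
    """
    v = np.asarray(list(fold_values), dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("need at least one non-missing fold value")
    return _signed_rank_p(v - null, alternative=alternative)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    Returns ``(p_adjusted, reject)`` in the input order; the discovery set
    ``{p_adj <= fdr}`` equals the classic step-up rule's.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= fdr


# ---------------------------------------------------------------------------
# Paired feature-set comparison and subgroup tests
# ---------------------------------------------------------------------------

def compare_feature_sets(augmented, baseline) -> float:
    """One-sided paired t-test p that ``augmented`` beats ``baseline``.

    Inputs are fold-aligned metric vectors (e.g. per-fold AUPRC with and
    without passive data).  Identical vectors give t = 0, hence p = 0.5;
    a constant nonzero difference has an undefined t and maps to p -> 0
    (improvement) or 1 (decline) with a warning.
    """
    a = np.asarray(list(augmented), dtype=float)
    b = np.asarray(list(baseline), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched fold structure: {a.shape} vs {b.shape}")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if len(d) < 2:
        raise ValueError("need >= 2 paired folds")
    if np.all(d == 0):
        return 0.5
    if np.std(d, ddof=1) == 0:
        warnings.warn("zero-variance nonzero paired differences; t undefined")
        return 0.0 if d.mean() > 0 else 1.0
    t = d.mean() / (np.std(d, ddof=1) / math.sqrt(len(d)))
    return float(stats.t.sf(t, df=len(d) - 1))


def subgroup_performance(
    predictions,
    subgroups: dict,
    n_draws: int = 100,
    seed: int = 0,
) -> dict:
    """Mann-Whitney U comparison of fold AUROC between two subgroups.

    ``subgroups`` maps participant_id to one of exactly two labels.  Per
    fold and subgroup, one event per participant is drawn ``n_draws``
    times and AUROC computed; the two collections of fold values are then
    compared with a two-sided Mann-Whitney U test.  Folds where a
    subgroup cannot yield both classes contribute no value for it.
    """
    frame = predictions.frame if hasattr(predictions, "frame") else predictions
    levels = sorted(set(subgroups.values()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 subgroup levels, got {levels}")
    frame = frame.assign(_grp=frame["participant_id"].map(subgroups))
    values: dict[object, list[float]] = {lv: [] for lv in levels}
    for lv in levels:
        sub = frame[frame["_grp"] == lv]
        fm = resampled_fold_metrics(sub, n_draws=n_draws, seed=seed)
        values[lv] = fm["auroc"].dropna().tolist()
    a, b = values[levels[0]], values[levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both subgroups must be represented in >= 2 folds")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"levels": levels, "fold_values": values, "U": float(u), "p": float(p)}


# ---------------------------------------------------------------------------
# Monte-Carlo Shapley attributions
# ---------------------------------------------------------------------------

@dataclass
class Attribution:
    """Per-prediction feature attributions with Monte-Carlo error bars.

    ``values[j] + ... + base`` reconstructs the model score for the
    explained row up to Monte-Carlo error (the efficiency property).
    """

    values: np.ndarray  # signed contribution per feature
    se: np.ndarray  # convergence standard error per feature
    base: float  # mean model score over the background
    prediction: float  # model score for the explained row


def shapley_attributions(
    score_fn,
    background: np.ndarray,
    X_explain: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> list[Attribution]:
    """Permutation-sampling Shapley values with background imputation.

    For each explained row, ``n_samples`` random feature orderings are
    walked from a random background row toward the explained row; the
    score increments are unbiased estimates of the Shapley value of each
    feature under the background-marginal value function.  ``score_fn``
    must map a 2-D float array of rows to a 1-D array of scores.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    d = background.shape[1]
    rng = np.random.default_rng(seed)
    base = float(np.mean(score_fn(background)))
    out: list[Attribution] = []
    for x in X_explain:
        perms = np.array([rng.permutation(d) for _ in range(n_samples)])
        bg_idx = rng.integers(0, background.shape[0], size=n_samples)
        rows = np.empty((n_samples * (d + 1), d))
        for s in range(n_samples):
            z = background[bg_idx[s]].copy()
            rows[s * (d + 1)] = z
            for j, feat in enumerate(perms[s]):
                z[feat] = x[feat]
                rows[s * (d + 1) + j + 1] = z
        preds = np.asarray(score_fn(rows), dtype=float).reshape(n_samples, d + 1)
        marginals = np.diff(preds, axis=1)  # (n_samples, d) in permutation order
        per_feature = np.empty((n_samples, d))
        for s in range(n_samples):
            per_feature[s, perms[s]] = marginals[s]
        values = per_feature.mean(axis=0)
        se = per_feature.std(axis=0, ddof=1) / math.sqrt(n_samples) if n_samples > 1 else np.full(d, np.nan)
        out.append(
            Attribution(
                values=values,
                se=se,
                base=base,
                prediction=float(np.asarray(score_fn(x[None, :]))[0]),
            )
        )
    return out


def attribution_ranking(attributions: list[Attribution]) -> np.ndarray:
    """Summary feature ranking: mean |Shapley value| across explained rows."""
    return np.mean([np.abs(a.values) for a in attributions], axis=0)


# ---------------------------------------------------------------------------
# Concordance and neurocognition correlation analyses
# ---------------------------------------------------------------------------

#: The six physiological <-> self-reported pairs with direct counterparts.
#: Clock-time pairs are compared on the anchored scale so that bedtimes
#: spanning midnight do not wrap.
CONCORDANCE_PAIRS = (
    ("sleep_duration", "median_sleep_duration", "hours_of_sleep"),
    ("bedtime", "median_bedrest_onset", "bedtime"),
    ("wakeup_time", "median_sleep_offset", "waketime"),
    ("sleep_efficiency", "median_sleep_efficiency", "hse_percent"),
    ("sleep_latency", "median_sleep_onset_latency", "minutes_to_sleep"),
    ("awakenings", "awake_count", "wake_middle_night"),
)

_CLOCK_COLUMNS = {
    "median_bedrest_onset",
    "median_sleep_offset",
    "median_bedrest_offset",
    "median_sleep_onset",
    "bedtime",
    "waketime",
}


def _participant_means(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    work = df.loc[:, ["participant_id"] + columns].copy()
    for c in columns:
        if c in _CLOCK_COLUMNS:
            work[c] = clock_to_anchor(work[c].to_numpy(float))
    return work.groupby("participant_id", sort=True).mean()


def paired_sleep_correlations(
    psqi_features: pd.DataFrame,
    psqi_scored: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Spearman concordance between physiological and self-reported sleep.

    ``psqi_features`` holds QC-passing 28-day feature vectors for PSQI
    events; ``psqi_scored`` the scored responses.  Both sides are averaged
    per participant across available administrations before correlating
    the six counterpart pairs; p-values are BH-adjusted across the six.
    Fewer than 3 participants leaves a pair undefined (NaN, flagged).
    """
    feat_cols = sorted({f for _, f, _ in CONCORDANCE_PAIRS})
    rep_cols = sorted({r for _, _, r in CONCORDANCE_PAIRS})
    merged = psqi_features.merge(
        psqi_scored, on=["participant_id", "week"], suffixes=("", "_rep")
    )
    left = _participant_means(merged, feat_cols)
    right = _participant_means(merged, rep_cols)
    rows = []
    for name, f, r in CONCORDANCE_PAIRS:
        x = left[f].to_numpy(float)
        y = right[r].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3:
            rows.append({"pair": name, "spearman_r": np.nan, "p_raw": np.nan, "n": n})
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"pair": name, "spearman_r": float(rho), "p_raw": float(p), "n": n})
    out = pd.DataFrame(rows)
    valid = ~out["p_raw"].isna()
    adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if valid.any():
        adj_v, rej_v = bh_adjust(out.loc[valid, "p_raw"], fdr=fdr)
        adj[valid.to_numpy()] = adj_v
        rej[valid.to_numpy()] = rej_v
    out["p_adjusted"] = adj
    out["significant"] = rej
    return out


def neurocog_metric_table(neurocog: pd.DataFrame) -> pd.DataFrame:
    """One row per (participant, week) with the per-task output metrics.

    Rate correct scores are computed for the processing-speed tasks (DSC,
    CRT); accuracy, d-prime/crit and MOT correct pass through.
    """
    rows = []
    for (pid, week), grp in neurocog.groupby(["participant_id", "week"], sort=True):
        rec: dict = {"participant_id": pid, "week": week}
        for _, r in grp.iterrows():
            task = r["task"]
            if task in ("dsc", "crt"):
                rec[f"rcs_{task}"] = rate_correct_score(r["accuracy"], r["median_rt"])
            elif task in ("vat", "ert"):
                rec[f"accuracy_{task}"] = r["accuracy"]
            elif task == "gradcpt":
                rec["d_prime"] = r["d_prime"]
                rec["crit"] = r["crit"]
            elif task == "mot":
                rec["mot_correct"] = r["mot_correct"]
        rows.append(rec)
    return pd.DataFrame(rows)


def neurocog_correlations(
    sleep_table: pd.DataFrame,
    neurocog_table: pd.DataFrame,
    sleep_columns: list[str],
    neurocog_columns: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full Spearman cross-correlation of sleep measures vs. neurocognition.

    Rows are matched by (participant_id, week); every (sleep measure,
    neurocognitive metric) pair is correlated, p-values BH-adjusted across
    the whole matrix, and pairs with adjusted p < ``fdr`` flagged.
    Constant columns yield undefined (NaN) correlations.
    """
    merged = sleep_table.merge(neurocog_table, on=["participant_id", "week"])
    if neurocog_columns is None:
        neurocog_columns = [
            c for c in neurocog_table.columns if c not in ("participant_id", "week")
        ]
    rows = []
    for sc in sleep_columns:
        x_all = merged[sc].to_numpy(float)
        if sc in _CLOCK_COLUMNS:
            x_all = clock_to_anchor(x_all)
        for nc in neurocog_columns:
            y_all = merged[nc].to_numpy(float)
            ok = ~(np.isnan(x_all) | np.isnan(y_all))
            n = int(ok.sum())
            x, y = x_all[ok], y_all[ok]
            if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                rows.append({"sleep": sc, "neurocog": nc, "spearman_r": np.nan,
                             "p_raw": np.nan, "n": n})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"sleep": sc, "neurocog": nc, "spearman_r": float(rho),
                         "p_raw": float(p), "n": n})
    out = pd.DataFrame(rows)
    valid = ~out["p_raw"].isna()
    adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if valid.any():
        adj_v, rej_v = bh_adjust(out.loc[valid, "p_raw"], fdr=fdr)
        adj[valid.to_numpy()] = adj_v
        rej[valid.to_numpy()] = rej_v
    out["p_adjusted"] = adj
    out["significant"] = rej
    return out
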