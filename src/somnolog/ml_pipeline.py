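"""Nested cross-validated classification of binary self-report targets.

Outer loop: stratified *group* 10-fold cross-validation keyed by
participant, so no participant appears in both the train and test side of
a fold.  Inner loop: 5-fold (participant-grouped by default) random
search over the model/hyperparameter space, scored by mean inner-fold
AUROC.  The preprocessing chain — median imputation, zero-variance
removal, select-K-best, robust scaling on the 5th-95th percentile range —
is fitted inside each training split only, so no statistics leak from
test rows.

Model families are logistic regression, random forest, gradient-boosted
trees, and a train-prevalence dummy baseline (always fitted alongside the
search winner).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold, f_classif, mutual_info_classif
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, KFold, StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler

__all__ = [
    "ModelSpace",
    "CVPredictions",
    "make_outer_folds",
    "build_preprocessor",
    "nested_cv_fit_predict",
    "TopKSelector",
]

#: Simplicity order used for tie-breaking between model families.
FAMILY_ORDER = ("dummy", "logistic", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class ModelSpace:
    """Search space for the nested cross-validation.

    The tree and selector grids are the pipeline's standard search space;
    the logistic-regression C grid is a documented extension of it.
    ``budget`` is the number of sampled
    configurations per family per outer fold; a family whose full grid
    fits within the budget is searched exhaustively.
    """

    families: Sequence[str] = ("logistic", "random_forest", "gradient_boosting", "dummy")
    n_estimators: Sequence[int] = (100, 200, 500)
    max_depth: Sequence[int] = (5, 10, 20)
    min_samples_leaf: Sequence[int] = (2, 5, 10)
    max_features: Sequence[object] = (None, "sqrt", "log2")
    select_k: Sequence[object] = (10, "all")
    selector_scores: Sequence[str] = ("f", "mutual_info")
    logreg_C: Sequence[float] = (0.01, 0.1, 1.0, 10.0)
    budget: int = 25

    def family_grid(self, family: str) -> list[dict]:
        selector = [
            {"select_k": k, "selector_score": s}
            for k, s in itertools.product(self.select_k, self.selector_scores)
        ]
        if family == "logistic":
            model = [{"C": c} for c in self.logreg_C]
        elif family in ("random_forest", "gradient_boosting"):
            model = [
                {
                    "n_estimators": n,
                    "max_depth": d,
                    "min_samples_leaf": leaf,
                    "max_features": mf,
                }
                for n, d, leaf, mf in itertools.product(
                    self.n_estimators, self.max_depth, self.min_samples_leaf, self.max_features
                )
            ]
        elif family == "dummy":
            return [{"family": "dummy"}]
        else:
            raise ValueError(f"unknown model family: {family!r}")
        return [{"family": family, **m, **s} for m, s in itertools.product(model, selector)]

    def candidates(self, rng: np.random.Generator) -> list[dict]:
        """Configurations evaluated in one outer fold's search.

        The dummy family is a selectable candidate (its single
        configuration): when no model beats chance in the inner folds the
        dummy wins the fold, exactly as the baseline rows of a results
        table arise.
        """
        out: list[dict] = []
        for family in self.families:
            grid = self.family_grid(family)
            if len(grid) <= self.budget:
                out.extend(grid)
            else:
                idx = rng.choice(len(grid), size=self.budget, replace=False)
                out.extend(grid[i] for i in sorted(idx))
        return out


class TopKSelector(BaseEstimator, TransformerMixin):
    """Select the K best features by ANOVA F or mutual information.

    ``k`` is clamped to the number of available features ("all" keeps
    everything).  Mutual information uses a fixed random state so that
    searches are reproducible.
    """

    def __init__(self, k="all", score="f", random_state: int = 0):
        self.k = k
        self.score = score
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n_features = X.shape[1]
        if self.k == "all" or self.k >= n_features:
            self.support_ = np.arange(n_features)
            return self
        if self.score == "f":
            scores, _ = f_classif(X, y)
        elif self.score == "mutual_info":
            scores = mutual_info_classif(X, y, random_state=self.random_state)
        else:
            raise ValueError(f"unknown selector score: {self.score!r}")
        scores = np.where(np.isnan(scores), -np.inf, scores)
        order = np.argsort(-scores, kind="stable")
        self.support_ = np.sort(order[: int(self.k)])
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


def build_preprocessor(select_k="all", selector_score="f", seed: int = 0) -> Pipeline:
    """The fixed preprocessing chain, fitted on training rows only.

    Order: median imputation -> drop zero-variance features -> select K
    best -> robust scaling centered on the median and scaled by the
    5th-95th percentile range.
    """
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("variance", VarianceThreshold(threshold=0.0)),
            ("select", TopKSelector(k=select_k, score=selector_score, random_state=seed)),
            ("scale", RobustScaler(quantile_range=(5.0, 95.0))),
        ]
    )


def _make_model(config: dict, seed: int):
    family = config["family"]
    if family == "logistic":
        # L2 penalty (the library default), strength searched over C
        return LogisticRegression(C=config["C"], solver="lbfgs", max_iter=2000)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=config["n_estimators"],
            max_depth=config["max_depth"],
            min_samples_leaf=config["min_samples_leaf"],
            max_features=config["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=config["n_estimators"],
            max_depth=config["max_depth"],
            min_samples_leaf=config["min_samples_leaf"],
            max_features=config["max_features"],
            random_state=seed,
        )
    if family == "dummy":
        return DummyClassifier(strategy="prior")
    raise ValueError(f"unknown model family: {family!r}")


def _make_pipeline(config: dict, seed: int) -> Pipeline:
    pre = build_preprocessor(
        config.get("select_k", "all"), config.get("selector_score", "f"), seed
    )
    return Pipeline(list(pre.steps) + [("model", _make_model(config, seed))])


class TargetSkipped(RuntimeError):
    """The target cannot be modelled (e.g. a class is absent)."""


def make_outer_folds(
    y: np.ndarray, groups: np.ndarray, n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Stratified group K-fold assignment (one fold index per event).

    Participants are never split across the train/test boundary; folds are
    approximately balanced in positive prevalence.  Raises
    :class:`TargetSkipped` when a class is absent overall or there are
    fewer participants than folds.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TargetSkipped(f"only one class present (all labels == {classes[0]!r})")
    if len(np.unique(groups)) < n_folds:
        raise TargetSkipped(
            f"need >= {n_folds} participants, got {len(np.unique(groups))}"
        )
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(cv.split(np.zeros((len(y), 1)), y, groups)):
        fold[test_idx] = i
    return fold


@dataclass
class CVPredictions:
    """Out-of-fold predictions for one (target, feature set) run."""

    frame: pd.DataFrame  # fold, event_id, participant_id, y_true, score, score_dummy
    winners: dict[int, dict] = field(default_factory=dict)  # per-fold winning config
    seed: int = 0
    target: str = ""
    feature_set: str = ""

    def for_scores(self, column: str) -> "CVPredictions":
        """A view with ``score`` replaced by another score column."""
        f = self.frame.copy()
        f["score"] = f[column]
        return replace(self, frame=f)


def _config_sort_key(config: dict) -> tuple:
    k = config.get("select_k", "all")
    k_rank = 10**9 if k == "all" else int(k)
    return (k_rank, FAMILY_ORDER.index(config["family"]))


def _inner_score(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: dict,
    inner_folds: int,
    grouped: bool,
    seed: int,
) -> float:
    if grouped and len(np.unique(groups)) >= inner_folds:
        splits = GroupKFold(n_splits=inner_folds).split(X, y, groups)
    else:
        splits = KFold(n_splits=inner_folds, shuffle=True, random_state=seed).split(X, y)
    scores = []
    for tr, va in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            continue  # split contributes no score
        pipe = _make_pipeline(config, seed)
        try:
            pipe.fit(X[tr], y[tr])
        except ValueError:
            continue  # e.g. all features zero-variance in this split
        proba = pipe.predict_proba(X[va])[:, 1]
        scores.append(roc_auc_score(y[va], proba))
    return float(np.mean(scores)) if scores else float("nan")


def nested_cv_fit_predict(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    space: ModelSpace = ModelSpace(),
    event_ids: np.ndarray | None = None,
    n_folds: int = 10,
    inner_folds: int = 5,
    grouped_inner: bool = True,
    seed: int = 0,
    target: str = "",
    feature_set: str = "",
) -> CVPredictions:
    """Nested cross-validation with per-fold random search.

    Per outer fold the candidate configurations (see
    :meth:`ModelSpace.candidates`) are scored by mean inner-fold AUROC on
    the outer-train rows; the winner (ties broken toward fewer selected
    features, then the simpler family) is refitted on the full outer-train
    set and scored on the outer-test rows.  The dummy baseline is always
    fitted as well; its constant scores come back in ``score_dummy``.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    if event_ids is None:
        event_ids = np.arange(len(y))
    fold = make_outer_folds(y, groups, n_folds=n_folds, seed=seed)
    master = np.random.SeedSequence(seed)
    rows = []
    winners: dict[int, dict] = {}
    for f in range(n_folds):
        test = fold == f
        train = ~test
        fold_seed = int(master.spawn(1)[0].generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, f)))
        candidates = space.candidates(rng)
        scored: list[tuple[float, dict]] = []
        for config in candidates:
            s = _inner_score(
                X[train], y[train], groups[train], config, inner_folds, grouped_inner, fold_seed
            )
            if not np.isnan(s):
                scored.append((s, config))
        if not scored:
            winner = {"family": "dummy"}
        else:
            best = max(s for s, _ in scored)
            tied = [c for s, c in scored if s >= best - 1e-12]
            winner = min(tied, key=_config_sort_key)
        winners[f] = winner
        pipe = _make_pipeline(winner, fold_seed)
        pipe.fit(X[train], y[train])
        score = pipe.predict_proba(X[test])[:, 1]
        dummy = _make_pipeline({"family": "dummy"}, fold_seed)
        dummy.fit(X[train], y[train])
        score_dummy = dummy.predict_proba(X[test])[:, 1]
        for i, idx in enumerate(np.nonzero(test)[0]):
            rows.append(
                {
                    "fold": f,
                    "event_id": event_ids[idx],
                    "participant_id": groups[idx],
                    "y_true": int(y[idx]),
                    "score": float(score[i]),
                    "score_dummy": float(score_dummy[i]),
                }
            )
    return CVPredictions(
        frame=pd.DataFrame(rows), winners=winners, seed=seed, target=target, feature_set=feature_set
    )
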