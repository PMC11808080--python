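"""Resampled metrics, Wilcoxon/BH/t-test conventions, Shapley, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import exact_shapley
from somnolog.stats_eval import (
    _ap_row,
    _auroc_rows,
    bh_adjust,
    compare_feature_sets,
    paired_sleep_correlations,
    resampled_fold_metrics,
    shapley_attributions,
    subgroup_performance,
)
from somnolog.stats_eval import test_above_chance as above_chance_p


def _frame(folds):
    """Build a predictions frame from {fold: [(pid, y, score), ...]}."""
    rows = []
    for f, entries in folds.items():
        for i, (pid, y, s) in enumerate(entries):
            rows.append({"fold": f, "event_id": f"{f}-{i}", "participant_id": pid,
                         "y_true": y, "score": s})
    return pd.DataFrame(rows)


class TestResampledMetrics:
    def test_constant_scores_give_exact_half(self):
        frame = _frame({
            f: [("a", 0, 0.3), ("a", 1, 0.3), ("b", 1, 0.3), ("c", 0, 0.3)]
            for f in range(10)
        })
        fm = resampled_fold_metrics(frame, n_draws=50, seed=0)
        assert (fm["auroc"] == 0.5).all()

    def test_perfect_scores_give_one(self):
        frame = _frame({
            0: [("a", 0, 0.0), ("b", 1, 1.0), ("c", 0, 0.0), ("d", 1, 1.0)]
        })
        fm = resampled_fold_metrics(frame, n_draws=30, seed=0)
        assert fm["auroc"].iloc[0] == 1.0
        assert fm["auprc"].iloc[0] == 1.0

    def test_one_event_per_participant_degenerates_to_plain_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 12)
        y[:2] = [0, 1]
        s = rng.random(12)
        frame = _frame({0: [(f"p{i}", int(y[i]), float(s[i])) for i in range(12)]})
        fm = resampled_fold_metrics(frame, n_draws=25, seed=0)
        assert fm["auroc"].iloc[0] == pytest.approx(roc_auc_score(y, s))

    def test_infeasible_fold_is_missing(self):
        # a single participant holds all positives and all negatives: a
        # one-event-per-participant draw can never contain both classes
        frame = _frame({0: [("a", 0, 0.1), ("a", 1, 0.9)]})
        fm = resampled_fold_metrics(frame, n_draws=10, seed=0)
        assert np.isnan(fm["auroc"]).all()

    def test_fast_metrics_match_sklearn_with_ties(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 1)
            assert _auroc_rows(y[None], s[None])[0] == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )
            assert _ap_row(y, s) == pytest.approx(average_precision_score(y, s), abs=1e-12)


class TestWilcoxon:
    def test_all_at_chance_gives_p_one(self):
        assert above_chance_p([0.5] * 10) == 1.0

    def test_all_above_gives_exact_minimum(self):
        assert above_chance_p([0.9] * 10) == pytest.approx(1 / 1024)

    def test_symmetric_values_not_significant(self):
        vals = [0.4, 0.6, 0.45, 0.55, 0.3, 0.7]
        assert above_chance_p(vals) >= 0.5

    def test_matches_scipy_exact_on_distinct_values(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            v = 0.5 + rng.standard_normal(10) * 0.1
            expected = sps.wilcoxon(v - 0.5, alternative="greater", method="exact").pvalue
            assert above_chance_p(v) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration_with_ties(self):
        v = np.array([0.6, 0.6, 0.4, 0.7, 0.7])
        d = v - 0.5
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=5)
            if np.dot(signs, ranks) >= w_obs - 1e-9
        )
        assert above_chance_p(v) == pytest.approx(count / 32)

    def test_nan_folds_dropped(self):
        assert above_chance_p([0.9] * 9 + [np.nan]) == pytest.approx(1 / 512)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.2])
        assert adj == pytest.approx([0.2])

    def test_all_ones(self):
        adj, rej = bh_adjust([1.0, 1.0, 1.0])
        assert adj == pytest.approx([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            adj, rej = bh_adjust(p)
            ref_rej, ref_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert adj == pytest.approx(ref_adj, abs=1e-12)
            assert (rej == ref_rej).all()

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(4)
        p = rng.random(15)
        adj, _ = bh_adjust(p)
        perm = rng.permutation(15)
        adj_p, _ = bh_adjust(p[perm])
        assert adj_p == pytest.approx(adj[perm])
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_empty_input(self):
        adj, rej = bh_adjust([])
        assert len(adj) == 0 and len(rej) == 0


class TestPairedT:
    def test_identical_vectors_give_half(self):
        assert compare_feature_sets([0.6] * 10, [0.6] * 10) == 0.5

    def test_constant_improvement_tends_to_zero(self):
        base = np.linspace(0.5, 0.7, 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            p = compare_feature_sets(base + 0.05, base)
        assert p == 0.0

    def test_wrong_direction_large_p(self):
        rng = np.random.default_rng(0)
        base = 0.7 + rng.standard_normal(10) * 0.01
        assert compare_feature_sets(base - 0.05, base) > 0.5

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(1)
        a = 0.6 + rng.standard_normal(10) * 0.05
        b = a - 0.03 + rng.standard_normal(10) * 0.02
        expected = sps.ttest_rel(a, b, alternative="greater").pvalue
        assert compare_feature_sets(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_folds_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_feature_sets([0.5] * 10, [0.5] * 9)


class TestSubgroups:
    def test_identical_distributions_u_centred(self):
        rng = np.random.default_rng(5)
        frame_rows = {}
        for f in range(8):
            entries = []
            for i in range(12):
                y = i % 2
                entries.append((f"p{i}", y, float(rng.random() * 0.2 + y * 0.3)))
            frame_rows[f] = entries
        frame = _frame(frame_rows)
        sub = {f"p{i}": ("A" if i < 6 else "B") for i in range(12)}
        res = subgroup_performance(frame, sub, n_draws=40, seed=0)
        n1, n2 = len(res["fold_values"]["A"]), len(res["fold_values"]["B"])
        assert res["p"] > 0.01
        assert 0 <= res["U"] <= n1 * n2


class TestShapley:
    def test_additive_model_recovers_weights(self):
        rng = np.random.default_rng(0)
        w = np.array([1.0, -2.0, 0.5, 0.0])
        fn = lambda X: X @ w
        background = rng.standard_normal((60, 4))
        x = np.array([1.0, 1.0, 1.0, 1.0])
        (att,) = shapley_attributions(fn, background, x[None], n_samples=400, seed=1)
        expected = w * (x - background.mean(axis=0))
        assert np.all(np.abs(att.values - expected) <= 3 * att.se + 1e-9)

    def test_ignored_feature_attribution_near_zero(self):
        rng = np.random.default_rng(2)
        fn = lambda X: X[:, 0] ** 2
        background = rng.standard_normal((40, 3))
        (att,) = shapley_attributions(fn, background, np.array([[2.0, 5.0, -7.0]]),
                                      n_samples=300, seed=3)
        assert abs(att.values[1]) <= 3 * att.se[1] + 1e-9
        assert abs(att.values[2]) <= 3 * att.se[2] + 1e-9

    def test_matches_exact_enumeration_on_small_instance(self):
        rng = np.random.default_rng(4)
        w = rng.standard_normal(6)

        def fn(X):
            X = np.atleast_2d(X)
            return X @ w + 0.5 * X[:, 0] * X[:, 1]  # interaction term

        background = rng.standard_normal((12, 6))
        x = rng.standard_normal(6)
        exact = exact_shapley(fn, background, x)
        (att,) = shapley_attributions(fn, background, x[None], n_samples=500, seed=5)
        assert np.all(np.abs(att.values - exact) <= 3 * att.se + 1e-9)

    def test_efficiency_property(self):
        rng = np.random.default_rng(6)
        fn = lambda X: np.tanh(X).sum(axis=1)
        background = rng.standard_normal((30, 5))
        x = rng.standard_normal(5)
        (att,) = shapley_attributions(fn, background, x[None], n_samples=400, seed=7)
        assert abs(att.values.sum() + att.base - att.prediction) <= 3 * att.se.sum() + 1e-9

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError, match="n_samples"):
            shapley_attributions(lambda X: X.sum(axis=1), np.zeros((2, 2)), np.zeros((1, 2)), 0)


class TestConcordance:
    def test_zero_noise_duration_pair_nearly_perfect(self):
        """In the no-misperception limit the duration pair approaches the
        concordance ceiling (r >= 0.95)."""
        from somnolog.orchestration import prepare_cohort_tables
        from somnolog.synthetic_data import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(
            n_participants=100, seed=21, misperception_sd=0.0,
            missing_annotation_frac=0.0, wear_prob=0.97,
        )
        tables = prepare_cohort_tables(generate_cohort(cfg))
        out = paired_sleep_correlations(tables.psqi_features, tables.psqi_scored)
        r = out.set_index("pair").loc["sleep_duration", "spearman_r"]
        assert r >= 0.95

    def test_monotone_transform_leaves_spearman_unchanged(self, clean_tables):
        out1 = paired_sleep_correlations(clean_tables.psqi_features, clean_tables.psqi_scored)
        feats = clean_tables.psqi_features.copy()
        feats["median_sleep_duration"] = np.exp(feats["median_sleep_duration"] / 3.0)
        out2 = paired_sleep_correlations(feats, clean_tables.psqi_scored)
        a = out1.set_index("pair").loc["sleep_duration", "spearman_r"]
        b = out2.set_index("pair").loc["sleep_duration", "spearman_r"]
        assert a == pytest.approx(b)

    def test_adjusted_p_never_below_raw(self, clean_tables):
        out = paired_sleep_correlations(clean_tables.psqi_features, clean_tables.psqi_scored)
        v = out.dropna(subset=["p_raw"])
        assert (v["p_adjusted"] >= v["p_raw"] - 1e-15).all()
        assert (v["spearman_r"].abs() <= 1).all()


class TestNeurocog:
    def test_planted_disturbance_link_recovered(self):
        """A disturbance -> processing-speed link in the generator should
        surface as a flagged negative disturbances/RCS correlation."""
        from somnolog.orchestration import prepare_cohort_tables, run_neurocog
        from somnolog.synthetic_data import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(
            n_participants=200, seed=31, neurocog_link=0.8,
            missing_annotation_frac=0.0, wear_prob=0.97,
        )
        tables = prepare_cohort_tables(generate_cohort(cfg))
        out = run_neurocog(tables)
        row = out[(out["sleep"] == "comp_disturbances") & (out["neurocog"] == "rcs_dsc")]
        assert row["spearman_r"].iloc[0] < 0
        assert bool(row["significant"].iloc[0])

    def test_constant_column_reported_missing(self, clean_tables):
        from somnolog.stats_eval import neurocog_correlations, neurocog_metric_table

        neuro = neurocog_metric_table(clean_tables.cohort.neurocog)
        sleep = clean_tables.psqi_features.copy()
        sleep["flat"] = 1.0
        out = neurocog_correlations(sleep, neuro, ["flat"])
        assert out["spearman_r"].isna().all()
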