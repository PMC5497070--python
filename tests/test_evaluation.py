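"""Confusion metrics, ROC/DeLong, calibration, cut-points, jackknife."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from crowdrasch.consensus import RaschWeightedConsensus, vote_matrix
from crowdrasch.data import ABNORMAL, NORMAL
from crowdrasch.evaluation import (
    JackknifeConfig,
    auroc,
    compare_auroc,
    confusion,
    fit_logistic_calibration,
    jackknife_auroc,
    select_cutpoint,
)
from crowdrasch.simulate import SimConfig, simulate_crowd

from _oracles import auroc_pair_count, sweep_cutoffs


def _labels(gold01):
    return pd.Series(np.where(np.asarray(gold01) == 1, ABNORMAL, NORMAL))


class TestConfusion:
    def test_perfect_predictions(self):
        gold = pd.Series([ABNORMAL, NORMAL, ABNORMAL])
        c = confusion(gold, gold)
        assert (c.percent_correct, c.sensitivity, c.specificity) == (100.0, 100.0, 100.0)

    def test_all_abnormal_degenerate_classifier(self):
        gold = pd.Series([ABNORMAL, NORMAL, NORMAL, ABNORMAL])
        pred = pd.Series([ABNORMAL] * 4)
        c = confusion(pred, gold)
        assert c.sensitivity == 100.0
        assert c.specificity == 0.0

    def test_hand_built_counts(self):
        # tp=453 fn=48 tn=453 fp=146 -> sens 90.4%, spec 75.6%
        gold, pred = [], []
        for (g, p), k in [
            ((ABNORMAL, ABNORMAL), 453),
            ((ABNORMAL, NORMAL), 48),
            ((NORMAL, NORMAL), 453),
            ((NORMAL, ABNORMAL), 146),
        ]:
            gold += [g] * k
            pred += [p] * k
        c = confusion(pd.Series(pred), pd.Series(gold))
        assert (c.tp, c.fn, c.tn, c.fp) == (453, 48, 453, 146)
        assert c.sensitivity == pytest.approx(100 * 453 / 501, abs=1e-9)
        assert round(c.sensitivity, 1) == 90.4
        assert round(c.specificity, 1) == 75.6
        assert c.n == c.tp + c.fp + c.tn + c.fn

    def test_single_class_gold_gives_nan_rate(self):
        gold = pd.Series([NORMAL, NORMAL])
        pred = pd.Series([NORMAL, ABNORMAL])
        c = confusion(pred, gold)
        assert np.isnan(c.sensitivity)
        assert c.specificity == 50.0

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError):
            confusion({"a": NORMAL}, {"b": NORMAL})


class TestAuroc:
    def test_perfect_ranking(self):
        scores = pd.Series([3.0, 2.0, 1.0, 0.0])
        gold = _labels([1, 1, 0, 0])
        gold.index = scores.index
        assert auroc(scores, gold).auroc == 1.0

    def test_constant_scores_give_half(self):
        scores = pd.Series([1.0] * 6)
        gold = _labels([1, 1, 1, 0, 0, 0])
        assert auroc(scores, gold).auroc == 0.5

    def test_matches_pair_count_oracle_with_ties(self, rng):
        for n in (6, 15, 30, 50):
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            gold01 = rng.integers(0, 2, n)
            if gold01.sum() in (0, n):
                gold01[0] = 1 - gold01[0]
            s = pd.Series(scores)
            res = auroc(s, _labels(gold01))
            assert res.auroc == pytest.approx(auroc_pair_count(scores, gold01), abs=1e-12)
            assert res.ci_low <= res.auroc <= res.ci_high

    def test_roc_points_monotone(self, rng):
        scores = pd.Series(rng.normal(size=60))
        gold01 = rng.integers(0, 2, 60)
        gold01[:2] = [0, 1]
        res = auroc(scores, _labels(gold01))
        assert (np.diff(res.points[:, 0]) >= 0).all()
        assert (np.diff(res.points[:, 1]) >= 0).all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(pd.Series([1.0, 2.0]), _labels([1, 1]))

    def test_delong_ci_coverage(self):
        """The 95% DeLong interval covers the true AUROC at the nominal rate
        (binormal scores, n=300 per class, 500 replicates)."""
        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 500
        gold = _labels([1] * 300 + [0] * 300)
        for _ in range(reps):
            scores = pd.Series(
                np.concatenate([rng.normal(mu, 1, 300), rng.normal(0, 1, 300)])
            )
            res = auroc(scores, gold)
            covered += res.ci_low <= true_auc <= res.ci_high
        assert 0.92 <= covered / reps <= 0.98


class TestCompareAuroc:
    def test_self_comparison_is_null(self, rng):
        scores = pd.Series(rng.normal(size=40))
        gold01 = rng.integers(0, 2, 40)
        gold01[:2] = [0, 1]
        res = compare_auroc(scores, scores, _labels(gold01))
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_symmetric_in_arguments(self, rng):
        a = pd.Series(rng.normal(size=80))
        b = pd.Series(rng.normal(size=80))
        gold01 = rng.integers(0, 2, 80)
        gold01[:2] = [0, 1]
        gold = _labels(gold01)
        r1 = compare_auroc(a, b, gold)
        r2 = compare_auroc(b, a, gold)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_informative_vs_random_rejects(self):
        rng = np.random.default_rng(5)
        gold01 = rng.integers(0, 2, 200)
        gold01[:2] = [0, 1]
        informative = pd.Series(gold01 + rng.normal(0, 0.3, 200))
        noise = pd.Series(rng.normal(size=200))
        res = compare_auroc(informative, noise, _labels(gold01))
        assert res.p_value < 0.001

    def test_degenerate_variance_not_applicable(self):
        # constant scores for both: equal AUROCs -> null; mark applicable
        gold = _labels([1, 1, 0, 0])
        a = pd.Series([1.0, 1.0, 1.0, 1.0])
        res = compare_auroc(a, a, gold)
        assert res.applicable and res.p_value == 1.0


class TestLogisticCalibration:
    def test_uninformative_scores_recover_prevalence(self):
        rng = np.random.default_rng(8)
        n = 4000
        gold01 = (rng.random(n) < 0.3).astype(int)
        scores = pd.Series(rng.normal(size=n))
        res = fit_logistic_calibration(scores, _labels(gold01))
        assert not res.separated
        assert res.slope == pytest.approx(0.0, abs=0.1)
        prev = gold01.mean()
        assert res.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=0.15)

    def test_true_log_odds_scores_have_unit_slope(self):
        rng = np.random.default_rng(9)
        n = 4000
        scores = rng.normal(0, 1.5, n)
        gold01 = (rng.random(n) < 1 / (1 + np.exp(-scores))).astype(int)
        res = fit_logistic_calibration(pd.Series(scores), _labels(gold01))
        assert res.slope == pytest.approx(1.0, abs=0.1)
        assert res.intercept == pytest.approx(0.0, abs=0.1)

    def test_probabilities_preserve_roc(self, rng):
        n = 200
        gold01 = rng.integers(0, 2, n)
        gold01[:2] = [0, 1]
        scores = pd.Series(gold01 * 1.2 + rng.normal(0, 1, n))
        gold = _labels(gold01)
        res = fit_logistic_calibration(scores, gold)
        assert res.slope > 0
        assert auroc(res.probabilities, gold).auroc == pytest.approx(
            auroc(scores, gold).auroc, abs=1e-12
        )

    def test_complete_separation_flagged(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        gold = _labels([0, 0, 0, 1, 1, 1])
        res = fit_logistic_calibration(scores, gold)
        assert res.separated
        # the raw-score ROC remains perfectly valid
        assert auroc(scores, gold).auroc == 1.0


class TestSelectCutpoint:
    def test_separable_scores_any_criterion(self):
        scores = pd.Series([5.0, 4.0, 1.0, 0.0])
        gold = _labels([1, 1, 0, 0])
        for crit, target in [
            ("max_correct", None),
            ("min_sensitivity", 100.0),
            ("min_specificity", 100.0),
        ]:
            rep = select_cutpoint(scores, gold, crit, target)
            assert rep.summary.percent_correct == 100.0
            assert rep.auroc_at_cutpoint == 1.0

    def test_vacuous_sensitivity_target(self, rng):
        scores = pd.Series(rng.normal(size=30))
        gold01 = rng.integers(0, 2, 30)
        gold01[:2] = [0, 1]
        rep = select_cutpoint(scores, _labels(gold01), "min_sensitivity", 0.0)
        assert rep.summary.specificity == 100.0  # extreme cutoff, all-normal calls

    def test_matches_exhaustive_sweep(self, rng):
        """All three criteria agree with the brute-force cutoff sweep."""
        for trial in range(5):
            n = 10 + 4 * trial
            scores = np.round(rng.normal(size=n), 1)
            gold01 = rng.integers(0, 2, n)
            gold01[:2] = [0, 1]
            s = pd.Series(scores)
            gold = _labels(gold01)
            rows = sweep_cutoffs(scores, gold01)

            rep = select_cutpoint(s, gold, "max_correct")
            assert rep.summary.percent_correct == pytest.approx(
                max(r[3] for r in rows)
            )

            target = 70.0
            feasible = [r for r in rows if r[1] >= target]
            if feasible:
                rep = select_cutpoint(s, gold, "min_sensitivity", target)
                assert rep.summary.sensitivity >= target
                assert rep.summary.specificity == pytest.approx(
                    max(r[2] for r in feasible)
                )
            feasible_sp = [r for r in rows if r[2] >= target]
            if feasible_sp:
                rep = select_cutpoint(s, gold, "min_specificity", target)
                assert rep.summary.specificity >= target
                assert rep.summary.sensitivity == pytest.approx(
                    max(r[1] for r in feasible_sp)
                )

    def test_never_worse_than_trivial_rules(self, rng):
        for _ in range(5):
            n = 40
            scores = pd.Series(rng.normal(size=n))
            gold01 = rng.integers(0, 2, n)
            gold01[:2] = [0, 1]
            rep = select_cutpoint(scores, _labels(gold01), "max_correct")
            prevalence = 100.0 * gold01.mean()
            assert rep.summary.percent_correct >= max(prevalence, 100 - prevalence)

    def test_unattainable_target_names_best(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0])
        gold = _labels([1, 0, 1, 0])
        # specificity can only be 0 or 100; sensitivity likewise -> 101% impossible
        with pytest.raises(ValueError, match="best achievable"):
            select_cutpoint(scores, gold, "min_sensitivity", 101.0)

    def test_dichotomized_auroc_is_mean_of_rates(self, rng):
        scores = pd.Series(rng.normal(size=50))
        gold01 = rng.integers(0, 2, 50)
        gold01[:2] = [0, 1]
        rep = select_cutpoint(scores, _labels(gold01), "max_correct")
        expected = (rep.summary.sensitivity + rep.summary.specificity) / 200.0
        assert rep.auroc_at_cutpoint == pytest.approx(expected)
        # equals the AUROC of the binary predictions themselves
        pred01 = (scores >= rep.chosen_cutoff).astype(float)
        assert auroc(pred01, _labels(gold01)).auroc == pytest.approx(expected)


class TestJackknife:
    def test_uniform_weights_equal_naive_exactly(self):
        bundle = simulate_crowd(
            SimConfig(n_items=30, n_workers=12, grades_per_item=6, seed=3)
        )
        res = jackknife_auroc(
            bundle.records, bundle.truth, JackknifeConfig(weight_mode="uniform")
        )
        gold = bundle.truth.set_index("item_id")["gold"]
        X = vote_matrix(bundle.records)
        naive = auroc(pd.Series(X.to_numpy().sum(axis=1), index=X.index), gold.loc[X.index])
        assert res.roc.auroc == naive.auroc
        assert res.n_replicates == 30
        assert res.n_nonconverged == 0

    def test_replicate_count_equals_item_count(self):
        bundle = simulate_crowd(
            SimConfig(n_items=25, n_workers=10, grades_per_item=5, seed=4)
        )
        res = jackknife_auroc(bundle.records, bundle.truth, JackknifeConfig())
        assert res.n_replicates == 25
        assert len(res.scores) == 25

    def test_close_to_naive_when_weights_are_stable(self):
        """With many grades per worker the leave-one-item-out weights barely
        move and the jackknife AUROC tracks the full-data AUROC."""
        bundle = simulate_crowd(
            SimConfig(n_items=300, n_workers=80, grades_per_item=20,
                      ability_sd=1.2, seed=5)
        )
        res = jackknife_auroc(bundle.records, bundle.truth, JackknifeConfig())
        gold = bundle.truth.set_index("item_id")["gold"]
        X = vote_matrix(bundle.records)
        model = RaschWeightedConsensus(missing_weight="neutral").fit(
            X, gold.loc[X.index].to_numpy()
        )
        naive = auroc(
            pd.Series(model.decision_function(X), index=X.index), gold.loc[X.index]
        )
        assert abs(res.roc.auroc - naive.auroc) < 0.02

    def test_too_few_items_rejected(self):
        records = pd.DataFrame(
            {
                "worker_id": ["w1", "w2", "w1", "w2"],
                "item_id": ["a", "a", "b", "b"],
                "classification": [ABNORMAL, NORMAL, NORMAL, NORMAL],
            }
        )
        truth = pd.DataFrame({"item_id": ["a", "b"], "gold": [ABNORMAL, NORMAL]})
        with pytest.raises(ValueError):
            jackknife_auroc(records, truth, JackknifeConfig())
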