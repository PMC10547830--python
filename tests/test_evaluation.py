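"""Voting rule, balanced accuracy, grid execution and scheme statistics."""

import numpy as np
import pandas as pd
import pytest

import eegleak as el
from eegleak.evaluate import (EvaluationReport, VotingRule, bonferroni,
                              compare_schemes, vote_subject)


def oracle_vote(n_patient_votes, n_total, true_label, threshold=0.6):
    """Independent restatement of the rule: a class wins at a vote
    fraction >= threshold, otherwise abstain (counted incorrect)."""
    fp = n_patient_votes / n_total
    if fp >= threshold:
        predicted = el.PATIENT
    elif 1 - fp >= threshold:
        predicted = el.CONTROL
    else:
        predicted = None
    return predicted, predicted == true_label


class TestVoting:
    def test_exhaustive_enumeration_up_to_eight_votes(self):
        rule = VotingRule(0.6)
        for n in range(1, 9):
            for k in range(n + 1):
                preds = [el.PATIENT] * k + [el.CONTROL] * (n - k)
                for truth in (el.PATIENT, el.CONTROL):
                    expected_label, expected_correct = oracle_vote(k, n, truth)
                    d = vote_subject(preds, truth, rule)
                    assert d.predicted_label == expected_label, (n, k, truth)
                    assert d.correct == expected_correct, (n, k, truth)

    def test_three_of_five_reaches_the_threshold(self):
        """3/5 = 60% patient votes classifies the subject as patient."""
        d = vote_subject([el.PATIENT] * 3 + [el.CONTROL] * 2, el.PATIENT)
        assert d.predicted_label == el.PATIENT and d.correct

    def test_unanimous_votes_are_correct(self):
        d = vote_subject([el.PATIENT] * 6, el.PATIENT)
        assert d.correct and not d.abstained

    def test_tied_votes_abstain_and_count_incorrect(self):
        d = vote_subject([el.PATIENT] * 3 + [el.CONTROL] * 3, el.PATIENT)
        assert d.abstained and not d.correct

    def test_empty_votes_rejected(self):
        with pytest.raises(el.ConfigurationError):
            vote_subject([], el.PATIENT)

    def test_threshold_outside_half_one_rejected(self):
        with pytest.raises(el.ConfigurationError):
            VotingRule(0.4)

    def test_vote_monotonicity(self):
        """Flipping one wrong trial vote to correct never turns a correct
        subject decision incorrect."""
        rule = VotingRule(0.6)
        for n in range(1, 9):
            for k in range(n):
                before = vote_subject([el.PATIENT] * k + [el.CONTROL] * (n - k),
                                      el.PATIENT, rule)
                after = vote_subject([el.PATIENT] * (k + 1) + [el.CONTROL] * (n - k - 1),
                                     el.PATIENT, rule)
                assert not (before.correct and not after.correct)


class TestBalancedAccuracy:
    def test_all_correct_is_hundred(self):
        truth = [el.PATIENT] * 3 + [el.CONTROL] * 2
        assert el.balanced_accuracy(truth, truth) == 100.0

    def test_sensitivity_specificity_average(self):
        truth = np.array([el.PATIENT] * 10 + [el.CONTROL] * 10)
        pred = truth.copy()
        pred[:2] = el.CONTROL   # sensitivity 0.8
        pred[10:14] = el.PATIENT  # specificity 0.6
        assert el.balanced_accuracy(truth, pred) == pytest.approx(70.0)

    def test_chance_level_on_imbalanced_truth(self, rng):
        """Monte-Carlo: random predictions on 77/58 truth average 50%."""
        truth = np.array([1] * 77 + [0] * 58)
        correct = rng.random((10_000, 135)) < 0.5
        sens = correct[:, :77].mean(axis=1)
        spec = correct[:, 77:].mean(axis=1)
        mean_acc = 100 * (sens + spec).mean() / 2
        assert mean_acc == pytest.approx(50.0, abs=1.0)
        # and the implementation agrees with the oracle on one draw
        pred = np.where(rng.random(135) < 0.5, el.PATIENT, el.CONTROL)
        t = np.where(truth == 1, el.PATIENT, el.CONTROL)
        expected = 100 * ((pred[:77] == el.PATIENT).mean()
                          + (pred[77:] == el.CONTROL).mean()) / 2
        assert el.balanced_accuracy(t, pred) == pytest.approx(expected)

    def test_one_class_absent_rejected(self):
        with pytest.raises(el.ConfigurationError):
            el.balanced_accuracy([el.PATIENT] * 5, [el.PATIENT] * 5)

    def test_label_swap_invariance(self, rng):
        truth = np.where(rng.random(40) < 0.5, el.PATIENT, el.CONTROL)
        truth[:2] = [el.PATIENT, el.CONTROL]  # both classes present
        pred = np.where(rng.random(40) < 0.5, el.PATIENT, el.CONTROL)
        swap = {el.PATIENT: el.CONTROL, el.CONTROL: el.PATIENT}
        swapped_t = np.array([swap[x] for x in truth])
        swapped_p = np.array([swap[x] for x in pred])
        assert el.balanced_accuracy(truth, pred) == \
            pytest.approx(el.balanced_accuracy(swapped_t, swapped_p))


def _toy_report(columns: dict) -> EvaluationReport:
    rows = []
    for scheme_name, accs in columns.items():
        for r, a in enumerate(accs):
            rows.append({"model": "m", "scheme": scheme_name, "window_s": 10.0,
                         "repeat": r, "accuracy": a, "abstain_rate": 0.0})
    return EvaluationReport(results=pd.DataFrame(rows))


class TestSchemeComparison:
    def test_identical_columns_show_no_difference(self):
        accs = list(np.linspace(60, 70, 10))
        report = _toy_report({s: accs for s in ("sCV", "osCV", "tCV", "otCV")})
        stats = compare_schemes(report)
        assert (stats["friedman_stat"] == 0.0).all()
        assert (stats["friedman_p"] == 1.0).all()
        assert (stats["p_adj"] == 1.0).all()

    def test_friedman_statistic_matches_hand_ranking(self, rng):
        """4 schemes x 10 repetitions without ties: chi-square from rank
        sums, Q = 12/(nk(k+1)) * sum R_j^2 - 3n(k+1)."""
        cols = {name: list(rng.permutation(20)[:10] + off)
                for off, name in zip((0.0, 0.3, 0.6, 0.9), ("sCV", "osCV", "tCV", "otCV"))}
        names = sorted(cols)
        data = np.array([cols[n] for n in names]).T  # rows = repeats
        ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1
        n, k = data.shape
        R = ranks.sum(axis=0)
        q_hand = 12.0 / (n * k * (k + 1)) * (R ** 2).sum() - 3 * n * (k + 1)
        stats = compare_schemes(_toy_report(cols))
        assert stats["friedman_stat"].iloc[0] == pytest.approx(q_hand, rel=1e-9)

    def test_bonferroni_adjustment(self):
        rng_l = np.random.default_rng(0)
        cols = {s: list(rng_l.normal(60 + i * 5, 1, 10))
                for i, s in enumerate(("sCV", "osCV", "tCV", "otCV"))}
        stats = compare_schemes(_toy_report(cols))
        n_pairs = 6
        for _, row in stats.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * n_pairs))
        assert bonferroni(0.3, 6) == 1.0

    def test_unequal_repetition_counts_rejected(self):
        report = _toy_report({"sCV": [60] * 10, "tCV": [70] * 8})
        with pytest.raises(el.ConfigurationError):
            compare_schemes(report)

    def test_signed_rank_variant_available(self):
        rng_l = np.random.default_rng(1)
        cols = {"sCV": list(rng_l.normal(60, 2, 10)), "tCV": list(rng_l.normal(75, 2, 10))}
        stats = compare_schemes(_toy_report(cols), wilcoxon="signed_rank")
        assert (stats["p_raw"] < 0.05).all()
        with pytest.raises(el.ConfigurationError):
            compare_schemes(_toy_report(cols), wilcoxon="mann_whitney")


class TestRunExperiment:
    def test_grid_schema_contract(self, small_cohort):
        """Every requested cell appears with accuracies in [0, 100]."""
        _, recs = small_cohort
        schemes = [el.scheme(s) for s in ("sCV", "osCV", "tCV", "otCV")]
        report = el.run_experiment(recs, schemes, [10.0, 30.0],
                                   [el.ModelConfig(family="spectral_baseline")],
                                   k=4, repeats=2, seed=5)
        df = report.results
        assert not report.meta["errors"]
        assert len(df) == 4 * 2 * 2  # schemes x windows x repeats
        assert df["accuracy"].between(0, 100).all()
        summary = report.summary()
        assert len(summary) == 8
        assert (summary["std"] >= 0).all()
        gaps = report.leakage_gap()
        assert set(gaps["pair"]) == {"tCV-sCV", "otCV-osCV"}
        matrix = report.table_matrix()
        assert matrix.shape == (4, 2)

    def test_report_round_trip_files(self, tmp_path, small_cohort):
        _, recs = small_cohort
        report = el.run_experiment(recs, [el.scheme("sCV")], [10.0],
                                   [el.ModelConfig(family="spectral_baseline")],
                                   k=4, repeats=2, seed=5)
        compare_schemes(report)
        csv = report.to_csv(tmp_path / "r.csv")
        js = report.to_json(tmp_path / "r.json")
        assert pd.read_csv(csv).shape[0] == len(report.results)
        import json
        payload = json.loads(js.read_text())
        assert payload["meta"]["seed"] == 5
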