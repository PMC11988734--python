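"""Detection metrics, AUROC estimator, cost profiling, suite, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afview import (
    ModelSpec,
    SyntheticConfig,
    auroc,
    build_classifier,
    confusion_metrics,
    inference_time_ratio,
    rank_models,
    run_robustness_suite,
    sample_balanced_intervals,
    split_cohort,
    synth_cohort,
)


class TestConfusionMetrics:
    def test_rate_arithmetic(self):
        y = np.array([1] * 100 + [0] * 100)
        p = np.array([0.9] * 90 + [0.1] * 10 + [0.1] * 95 + [0.9] * 5)
        res = confusion_metrics(y, p)
        assert (res.tp, res.fn, res.tn, res.fp) == (90, 10, 95, 5)
        assert res.tpr == pytest.approx(90.0)
        assert res.tnr == pytest.approx(95.0)
        assert res.acc == pytest.approx(92.5)
        assert res.n == 200

    def test_all_correct(self):
        res = confusion_metrics([1, 0, 1], [0.8, 0.2, 0.9])
        assert res.tpr == res.tnr == res.acc == 100.0

    def test_half_probability_is_af_positive(self):
        res = confusion_metrics([1], [0.5])
        assert res.tp == 1 and res.fn == 0

    def test_absent_class_rate_undefined_not_zero(self):
        res = confusion_metrics([1, 1], [0.9, 0.2])
        assert np.isnan(res.tnr)
        assert res.flags["tnr_undefined"]
        assert not res.flags["tpr_undefined"]

    def test_accuracy_between_rates_on_balanced_sets(self, rng):
        y = np.repeat([0, 1], 50)
        p = rng.random(100)
        res = confusion_metrics(y, p)
        assert min(res.tpr, res.tnr) <= res.acc <= max(res.tpr, res.tnr)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1.5, 0.2])


def auroc_bruteforce(y, p):
    """Independent O(n^2) pair-counting oracle (ties count one half)."""
    y, p = np.asarray(y), np.asarray(p)
    pos, neg = p[y == 1], p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_constant_scores_chance_level(self):
        assert auroc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 1], [0.2, 0.4])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 10**6))
    def test_matches_bruteforce_pair_counting(self, n1, n0, seed):
        rng = np.random.default_rng(seed)
        y = np.array([1] * n1 + [0] * n0)
        p = rng.choice(np.linspace(0, 1, 7), size=n1 + n0)  # many ties
        assert auroc(y, p) == pytest.approx(auroc_bruteforce(y, p), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = rng.random(200)
        assert auroc(y, p) == pytest.approx(auroc(y, 1 / (1 + np.exp(-7 * p))), abs=1e-12)


class TestInferenceTime:
    def test_fastest_model_ratio_is_one(self):
        models = {
            "a": build_classifier(ModelSpec(input_size=16, seed=0)),
            "b": build_classifier(ModelSpec(input_size=32, seed=0)),
        }
        costs = inference_time_ratio(models, probe_batch=2, repeats=3)
        assert min(c.inference_time_ratio for c in costs.values()) == 1.0
        assert all(c.inference_time_ratio >= 1.0 for c in costs.values())

    def test_single_model_ratio_one(self):
        model = build_classifier(ModelSpec(input_size=16, seed=0))
        costs = inference_time_ratio({"only": model}, probe_batch=2, repeats=1)
        assert costs["only"].inference_time_ratio == 1.0
        assert costs["only"].trainable_params["retrain"] == 65


def fabricate_report(acc1, drop2, drop3, auroc10, auroc30, acc5):
    return {
        "test1": {"Acc": acc1, "AUROC": auroc30},
        "test2": {"drop": drop2},
        "test3": {"drop": drop3, "per_lead_Acc": {}},
        "test4": {10.0: {"AUROC": auroc10}, 30.0: {"AUROC": auroc30}},
        "test5": {"Acc": acc5},
    }


class TestRanking:
    def test_best_everywhere_wins_with_five_top_ranks(self):
        reports = {
            "good": fabricate_report(97.0, 1.0, 0.5, 0.95, 0.99, 98.0),
            "poor": fabricate_report(93.0, 3.0, 2.0, 0.70, 0.98, 94.0),
        }
        out = rank_models(reports)
        assert out["winners"] == ["good"]
        assert out["table"]["good"]["top_ranks"] == 5

    def test_worst_rank_anywhere_disqualifies(self):
        reports = {
            "sprinter": fabricate_report(99.0, 0.5, 0.2, 0.50, 0.99, 99.0),  # fails at 10 s
            "steady": fabricate_report(96.0, 1.0, 0.8, 0.93, 0.97, 97.0),
            "weak": fabricate_report(90.0, 4.0, 3.0, 0.80, 0.95, 91.0),
        }
        out = rank_models(reports)
        assert "sprinter" not in out["winners"]
        assert out["winners"] == ["steady"]

    def test_identical_reports_tie(self):
        r = fabricate_report(95.0, 1.0, 1.0, 0.9, 0.95, 96.0)
        out = rank_models({"a": dict(r), "b": dict(r)})
        assert out["winners"] == ["a", "b"]

    def test_needs_two_reports(self):
        with pytest.raises(ValueError, match="two"):
            rank_models({"a": fabricate_report(95, 1, 1, 0.9, 0.95, 96)})


@pytest.fixture(scope="module")
def tiny_setup():
    recs = synth_cohort(4, SyntheticConfig(duration_s=300.0), seed=13, af_fraction=1.0)
    samples = []
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for r in recs:
            for lead in r.leads:
                samples += sample_balanced_intervals(r, lead, 2, 30.0, seed=2)
    ids = [r.record_id for r in recs]
    split = split_cohort(samples, ids[:2], ids[2:], seed=0)
    model = build_classifier(ModelSpec(seed=0))
    return recs, split, model


class TestRobustnessSuite:
    def test_report_structure_and_consistency(self, tiny_setup):
        recs, split, model = tiny_setup
        test_ids = {s.record_id for s in split.test}
        full = [r for r in recs if r.record_id in test_ids][:1]
        report = run_robustness_suite({"m": model}, recs, split, full_records=full)
        entry = report["m"]
        # duration 30 s re-evaluation must agree with the main test metric
        assert entry["test4"][30.0]["AUROC"] == pytest.approx(entry["test1"]["AUROC"])
        assert set(entry["test3"]["per_lead_Acc"]) == {"I", "II"}
        assert entry["test5"]["n_segments"] + entry["test5"]["n_unscorable"] == \
            len(full) * 2 * 10  # 300 s -> 10 segments per lead
        assert entry["cost"].inference_time_ratio == 1.0

    def test_identical_validation_and_test_give_zero_drop(self, tiny_setup):
        recs, split, model = tiny_setup
        from afview.dataset import DatasetSplit

        degenerate = DatasetSplit(
            train=split.train, validation=split.validation, test=split.validation,
        )
        report = run_robustness_suite({"m": model}, recs, degenerate)
        assert report["m"]["test2"]["drop"] == pytest.approx(0.0)
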