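"""Performance metrics, sweep bookkeeping, plateau detection, logarithmic
fit and cross-participant aggregation."""

import math

import numpy as np
import pytest

import semgpipe as sp
from semgpipe.classify import ActionCounts, ConfusionMatrix
from semgpipe.evaluate import SWEEP_METRICS, enumerate_subsets


class TestActionMetrics:
    def test_worked_example(self):
        """6 correct of 50 trials in a 300-sample matrix: sensitivity 12%,
        precision 1, action accuracy 256/300, F1 from the definition."""
        m = sp.action_metrics(ActionCounts("WE", TP=6, TN=250, FP=0, FN=44))
        assert m.sensitivity == pytest.approx(0.12, abs=1e-12)
        assert m.precision == pytest.approx(1.0, abs=1e-12)
        assert m.action_accuracy == pytest.approx(256 / 300, abs=1e-12)
        assert m.f1 == pytest.approx(2 * 1.0 * 0.12 / 1.12, abs=1e-12)

    def test_symmetric_counts(self):
        m = sp.action_metrics(ActionCounts("A", 25, 25, 25, 25))
        assert (m.precision, m.sensitivity, m.action_accuracy, m.f1) == \
            (0.5, 0.5, 0.5, 0.5)

    def test_zero_denominator_convention(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="semgpipe.evaluate"):
            m = sp.action_metrics(ActionCounts("A", TP=0, TN=90, FP=0, FN=10))
        assert m.precision == 0.0
        assert m.f1 == 0.0
        assert "precision undefined" in caplog.text

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ActionCounts("A", TP=-1, TN=5, FP=0, FN=0)

    def test_metrics_match_per_sample_recount(self):
        """Metric identities hold against a brute-force recount of
        TP/TN/FP/FN from raw prediction lists."""
        rng = np.random.default_rng(21)
        labels = list("ABCDEF")
        for _ in range(30):
            true = rng.choice(labels, size=120)
            pred = rng.choice(labels, size=120)
            counts = np.zeros((6, 6), dtype=int)
            for t, p in zip(true, pred):
                counts[labels.index(t), labels.index(p)] += 1
            cm = ConfusionMatrix(counts=counts, action_order=tuple(labels))
            for a in labels:
                tp = int(np.sum((true == a) & (pred == a)))
                fn = int(np.sum((true == a) & (pred != a)))
                fp = int(np.sum((true != a) & (pred == a)))
                tn = 120 - tp - fn - fp
                got = sp.confusion_to_counts(cm, a)
                assert (got.TP, got.TN, got.FP, got.FN) == (tp, tn, fp, fn)
            assert sp.overall_accuracy(cm) == pytest.approx(
                np.mean(true == pred))


class TestOverallAccuracy:
    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(np.diag([50] * 6), tuple("ABCDEF"))
        assert sp.overall_accuracy(cm) == 1.0

    def test_arithmetic(self):
        counts = np.full((6, 6), 1)
        np.fill_diagonal(counts, 45)
        cm = ConfusionMatrix(counts, tuple("ABCDEF"))
        assert sp.overall_accuracy(cm) == pytest.approx(270 / 300)

    def test_tp_weighted_identity(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 40, (6, 6))
        cm = ConfusionMatrix(counts, tuple("ABCDEF"))
        per = [sp.confusion_to_counts(cm, a) for a in cm.action_order]
        assert sp.overall_accuracy(cm) == pytest.approx(
            sum(c.TP for c in per) / sum(c.TP + c.FN for c in per))


class TestSubsetEnumeration:
    def test_combinatorial_completeness(self):
        """The full sweep enumerates C(12,k) subsets at every size and
        4095 in total."""
        subsets = enumerate_subsets(range(1, 13))
        for k, combos in subsets.items():
            assert len(combos) == math.comb(12, k)
            assert all(len(c) == k for c in combos)
            assert len(set(combos)) == len(combos)
        assert sum(len(c) for c in subsets.values()) == 4095

    def test_boundary_sizes(self):
        assert len(enumerate_subsets([1])[1]) == 12
        assert len(enumerate_subsets([12])[12]) == 1

    def test_subsampling_is_seeded_and_capped(self):
        a = enumerate_subsets(range(1, 13), subsets_per_k=10, seed=5)
        b = enumerate_subsets(range(1, 13), subsets_per_k=10, seed=5)
        assert a == b
        assert len(a[1]) == 10  # capped below C(12,1)=12
        assert len(a[12]) == 1  # sizes with fewer combinations keep all
        c = enumerate_subsets(range(1, 13), subsets_per_k=10, seed=6)
        assert c != a

    def test_out_of_range_size_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets([0])
        with pytest.raises(ValueError):
            enumerate_subsets([13])


@pytest.fixture(scope="module")
def small_sweep(participant_table):
    specs = [sp.ClassifierSpec(a) for a in ("lda", "svm")]
    return sp.feature_sweep(participant_table, specs, k_range=[1, 2],
                            seed=9, subsets_per_k=4)


class TestFeatureSweep:

    def test_structure(self, small_sweep):
        assert [r.algorithm for r in small_sweep] == ["lda", "svm"]
        for r in small_sweep:
            assert set(r.per_k) == {1, 2}
            for k in (1, 2):
                entry = r.per_k[k]
                assert set(entry) == set(SWEEP_METRICS)
                assert entry["overall_accuracy"]["n_subsets"] == 4
                assert 0 <= entry["overall_accuracy"]["mean"] <= 1

    def test_records_tidy(self, small_sweep):
        rec = small_sweep[0].records
        assert len(rec) == 8
        assert set(rec["k"]) == {1, 2}

    def test_order_independence(self, participant_table):
        """Per-subset results do not depend on which other subsets run:
        a single-subset sweep reproduces the full-run value."""
        spec = sp.ClassifierSpec("lda")
        full = sp.feature_sweep(participant_table, [spec], k_range=[1],
                                seed=9, subsets_per_k=None)
        one = full[0].records.iloc[3]
        again = sp.feature_sweep(participant_table, [spec], k_range=[1],
                                 seed=9, subsets_per_k=None)[0].records.iloc[3]
        assert one["overall_accuracy"] == again["overall_accuracy"]


class TestPlateau:
    def test_rising_then_flat(self):
        rep = sp.plateau_onset([10, 20, 20.5, 20.6])
        assert rep.onset_k == 3
        assert rep.value_at_onset == 20.5
        assert rep.rel_changes[0] == (2, pytest.approx(1.0))

    def test_constant_sequence(self):
        assert sp.plateau_onset([5.0, 5.0, 5.0]).onset_k == 2

    def test_doubling_never_plateaus(self):
        assert sp.plateau_onset([1, 2, 4, 8, 16]).onset_k is None

    def test_scale_invariance(self):
        seq = [3.0, 5.5, 5.6, 5.65, 9.0]
        for c in (0.01, 1.0, 250.0):
            assert sp.plateau_onset([c * v for v in seq]).onset_k == \
                sp.plateau_onset(seq).onset_k

    def test_mapping_input_with_explicit_k(self):
        rep = sp.plateau_onset({3: 10.0, 4: 20.0, 5: 20.2})
        assert rep.onset_k == 5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sp.plateau_onset([1.0])
        with pytest.raises(ValueError):
            sp.plateau_onset([1.0, 0.0, 2.0])


class TestLogFit:
    def test_noiseless_recovery(self):
        ks = np.arange(1, 13)
        acc = 0.5 + 0.1 * np.log(ks)
        fit = sp.fit_log_curve(ks, acc)
        assert fit["a"] == pytest.approx(0.5, abs=1e-9)
        assert fit["b"] == pytest.approx(0.1, abs=1e-9)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_data(self):
        fit = sp.fit_log_curve([1, 2, 3, 4], [0.7] * 4)
        assert fit["b"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_sampling_theory(self):
        """Estimated slope lies within 3 standard errors of truth."""
        rng = np.random.default_rng(14)
        ks = np.arange(1, 13)
        x = np.log(ks)
        acc = 0.5 + 0.1 * x + rng.normal(0, 0.01, size=len(ks))
        from scipy import stats
        res = stats.linregress(x, acc)
        fit = sp.fit_log_curve(ks, acc)
        assert fit["b"] == pytest.approx(res.slope)
        assert abs(fit["b"] - 0.1) < 3 * res.stderr

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sp.fit_log_curve([1, 2], [0.1, 0.2])


def _fake_sweep_result(pid, algo, acc_by_k):
    per_k = {k: {m: {"mean": v if m == "overall_accuracy" else 0.5,
                     "sd": 0.0, "n_subsets": 1.0}
                 for m in SWEEP_METRICS}
             for k, v in acc_by_k.items()}
    return sp.SweepResult(algorithm=algo, participant_id=pid, per_k=per_k)


class TestAggregateParticipants:
    def test_single_participant_zero_spread(self):
        res = [_fake_sweep_result("P1", "lda", {1: 0.4, 2: 0.6})]
        agg = sp.aggregate_participants(res)
        entry = agg["algorithms"]["lda"]
        assert entry["n_participants"] == 1
        assert entry["per_k"][1]["overall_accuracy"]["sd"] == 0.0
        assert entry["per_k"][1]["overall_accuracy"]["range"] == 0.0
        assert entry["max_overall_accuracy"] == 0.6

    def test_identical_participants_zero_range(self):
        res = [_fake_sweep_result(p, "svm", {1: 0.4, 2: 0.6})
               for p in ("P1", "P2")]
        agg = sp.aggregate_participants(res)
        assert agg["algorithms"]["svm"]["range_mean"] == 0.0

    def test_schema_complete_for_many_participants(self):
        ks = dict.fromkeys(range(1, 13), 0.5)
        res = [_fake_sweep_result(f"P{p}", a, {k: 0.5 + 0.01 * p for k in ks})
               for p in range(9) for a in ("knn", "lda", "svm")]
        agg = sp.aggregate_participants(res)
        assert set(agg["algorithms"]) == {"knn", "lda", "svm"}
        for entry in agg["algorithms"].values():
            assert entry["n_participants"] == 9
            assert set(entry["per_k"]) == set(range(1, 13))
            assert entry["range_mean"] == pytest.approx(0.08)

    def test_heterogeneous_k_ranges_rejected(self):
        res = [_fake_sweep_result("P1", "lda", {1: 0.5, 2: 0.5}),
               _fake_sweep_result("P2", "lda", {1: 0.5, 2: 0.5, 3: 0.5})]
        with pytest.raises(ValueError):
            sp.aggregate_participants(res)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.aggregate_participants([])
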