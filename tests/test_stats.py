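import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radtex.stats import (auc, bootstrap_auc_ci, delong_test, evaluate,
                          mcnemar_test, roc_result, wald_ci, youden_point)


def auc_pair_counting(scores, labels):
    """Exhaustive pair-counting oracle for the Mann-Whitney AUC."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_ordering(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    def test_matches_pair_counting_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        assert auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_interval(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 100)
        scores = labels + rng.uniform(-0.4, 0.4, 200)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=1)
        assert 0.9 <= lo <= hi == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 30)
        scores = rng.random(60) + labels * 0.5
        assert bootstrap_auc_ci(scores, labels, seed=7) == \
            bootstrap_auc_ci(scores, labels, seed=7)


class TestYouden:
    def test_separable_case(self):
        t, sens, spec = youden_point([0.2, 0.3, 0.7, 0.9], [0, 0, 1, 1])
        assert 0.3 < t <= 0.7 and sens == 1.0 and spec == 1.0

    def test_degenerate_all_equal(self):
        t, sens, spec = youden_point([0.5] * 4, [0, 1, 0, 1])
        assert sens + spec - 1 == 0.0

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        t, sens, spec = youden_point(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        best_j = max((pos >= c).mean() + (neg < c).mean() - 1
                     for c in np.unique(scores))
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestWald:
    def test_reproduces_reported_interval(self):
        lo, hi = wald_ci(64 / 77, 77)
        assert (round(lo, 2), round(hi, 2)) == (0.75, 0.91)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_boundary_zero_width(self, p):
        assert wald_ci(p, 50) == (p, p)

    def test_half_at_n100(self):
        lo, hi = wald_ci(0.5, 100)
        assert lo == pytest.approx(0.402, abs=1e-3)
        assert hi == pytest.approx(0.598, abs=1e-3)

    def test_width_decreases_with_n(self):
        widths = [np.diff(wald_ci(0.3, n))[0] for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)


class TestDeLong:
    def test_identical_scores(self):
        labels = [0, 0, 1, 1, 0, 1]
        scores = [0.1, 0.5, 0.3, 0.9, 0.2, 0.7]
        delta, p = delong_test(scores, scores, labels)
        assert delta == 0.0 and p == 1.0

    def test_frozen_pROC_oracle(self):
        """Fixed dataset checked once against R pROC roc.test (DeLong)."""
        rng = np.random.default_rng(42)
        y = np.repeat([0, 1], 20)
        a = y * 1.0 + rng.standard_normal(40)
        b = y * 0.5 + rng.standard_normal(40)
        delta, p = delong_test(a, b, y)
        assert delta == pytest.approx(0.2150000000, abs=1e-9)
        assert p == pytest.approx(0.0821015210, abs=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 25)
        a = y + rng.standard_normal(50)
        b = y + rng.standard_normal(50)
        d1, p1 = delong_test(a, b, y)
        d2, p2 = delong_test(np.exp(a), np.exp(b), y)
        assert d1 == pytest.approx(d2) and p1 == pytest.approx(p2)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])

    def test_variance_agrees_with_bootstrap(self):
        """DeLong's variance of delta-AUC vs a lesion-level bootstrap."""
        rng = np.random.default_rng(4)
        n = 200
        y = np.repeat([0, 1], n // 2)
        latent = y * 1.2 + rng.standard_normal(n)
        a = latent + 0.8 * rng.standard_normal(n)
        b = latent + 0.8 * rng.standard_normal(n)
        delta, p = delong_test(a, b, y)
        from scipy.stats import norm
        var_delong = (delta / norm.isf(p / 2)) ** 2 if p < 1 else np.inf
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(auc(a[idx], y[idx]) - auc(b[idx], y[idx]))
        var_boot = np.var(boots)
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestMcNemar:
    def test_exact_binomial_example(self):
        # b=5, c=15 discordant -> 2 * sum_{k<=5} C(20,k) / 2^20
        a = np.array([1] * 5 + [0] * 15 + [1] * 30, bool)
        b = np.array([0] * 5 + [1] * 15 + [1] * 30, bool)
        from scipy.stats import binom
        expected = 2 * binom.cdf(5, 20, 0.5)
        assert mcnemar_test(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0414, abs=2e-4)

    def test_symmetric_discordance_near_one(self):
        a = np.array([1] * 6 + [0] * 6 + [1] * 10, bool)
        b = np.array([0] * 6 + [1] * 6 + [1] * 10, bool)
        assert mcnemar_test(a, b) >= 0.99

    def test_no_discordance_is_one(self):
        v = np.array([1, 0, 1, 1, 0], bool)
        assert mcnemar_test(v, v) == 1.0

    def test_chi_square_approaches_exact(self):
        """At b+c=200 the corrected chi-square and exact p agree within 10%."""
        from scipy.stats import binom, chi2
        b_, c_ = 85, 115
        p_exact = min(1.0, 2 * binom.cdf(min(b_, c_), b_ + c_, 0.5))
        stat = (abs(b_ - c_) - 1) ** 2 / (b_ + c_)
        p_chi = chi2.sf(stat, 1)
        assert abs(p_chi - p_exact) / p_exact < 0.10
        a = np.array([1] * b_ + [0] * c_, bool)
        b = np.array([0] * b_ + [1] * c_, bool)
        assert mcnemar_test(a, b) == pytest.approx(p_chi, rel=1e-9)


class TestEvaluate:
    @staticmethod
    def _records(n, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        return pd.DataFrame({
            "lesion_id": [f"L{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "label": labels,
            "pirads": rng.choice([3, 4, 5], n),
            "zone": rng.choice(["PZ", "TZ"], n),
            "focality": rng.choice(["solitary", "multifocal"], n),
            "is_index": True,
            "psa": rng.uniform(1, 20, n),
            "split": "test",
        })

    def test_groups_partition_by_pirads(self):
        records = self._records(60)
        rng = np.random.default_rng(1)
        preds = {"m": rng.random(60),
                 "pirads_cla": (records["pirads"] >= 4).to_numpy(float)}
        report = evaluate(preds, records, n_boot=50)
        n_by_pirads = sum(report.groups[f"pirads_{s}"].n for s in (3, 4, 5))
        assert n_by_pirads == report.groups["all"].n == 60

    def test_single_class_group_not_evaluable(self):
        res = roc_result(np.array([0.2, 0.8, 0.5]), np.array([1, 1, 1]), n_boot=10)
        assert not res.evaluable and res.auc is None
        assert res.specificity.value is None

    def test_ppv_npv_against_hand_confusion(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 0, 1, 1, 0, 0, 0])
        res = roc_result(scores, labels, n_boot=20, threshold=0.5)
        # thr 0.5: TP=3 FP=1 FN=1 TN=3
        assert res.ppv.value == pytest.approx(3 / 4)
        assert res.npv.value == pytest.approx(3 / 4)
        assert res.sensitivity.value == pytest.approx(3 / 4)
        assert res.specificity.value == pytest.approx(3 / 4)

    def test_roc_curve_frame_endpoints(self):
        from radtex.stats import roc_curve_frame
        frame = roc_curve_frame([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert frame.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (frame[["fpr", "tpr"]].diff().fillna(0) >= 0).all().all()

    def test_report_serializes_and_tabulates(self):
        import json
        records = self._records(40, seed=2)
        rng = np.random.default_rng(2)
        preds = {"m": rng.random(40) + records["label"] * 0.5,
                 "pirads_cla": (records["pirads"] >= 4).to_numpy(float)}
        report = evaluate(preds, records, n_boot=30)
        payload = json.dumps(report.to_dict(), sort_keys=True)
        assert "delta_auc" in payload
        frame = report.to_frame()
        assert {"group", "model", "auc"} <= set(frame.columns)
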