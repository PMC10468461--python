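"""Similarity metrics vs loop oracles, t-test machinery vs an independent
t-CDF computation, AUC sanity, and the classifier fold protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import betainc

from ecgsynth.validation import (
    ClassifierSpec,
    TTestResult,
    compare_real_vs_synthetic,
    cosine_similarity,
    cross_domain_test,
    fit_single_classifier,
    rmse,
    similarity_report,
    train_classifier,
)


def loop_rmse(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return (total / len(a)) ** 0.5


def loop_cosine(a, b):
    dot = na = nb = 0.0
    for x, y in zip(a, b):
        dot += x * y
        na += x * x
        nb += y * y
    return dot / ((na**0.5) * (nb**0.5))


class TestMetrics:
    def test_matches_loop_oracles_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            assert abs(rmse(a, b) - loop_rmse(a, b)) < 1e-12
            assert abs(cosine_similarity(a, b) - loop_cosine(a, b)) < 1e-12

    def test_closed_forms(self):
        a = np.array([1.0, 2.0])
        assert rmse(a, a) == 0.0
        assert rmse(np.array([1.0, 2.0]), np.array([1.0, 4.0])) == pytest.approx(
            np.sqrt(2.0)
        )
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_similarity(a, -a) == pytest.approx(-1.0)

    @given(
        arrays(np.float64, st.integers(2, 50),
               elements=st.floats(-1e3, 1e3, allow_nan=False)),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_rmse_nonnegative_and_symmetric(self, a, seed):
        b = np.random.default_rng(seed).normal(size=a.shape)
        assert rmse(a, b) >= 0.0
        assert rmse(a, b) == pytest.approx(rmse(b, a))

    def test_zero_vector_cosine_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(5), np.ones(5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(np.zeros(5), np.zeros(6))


class TestSimilarityReport:
    def test_identity_gives_zero_rmse_unit_cosine(self, normalized_cohort):
        table = similarity_report(normalized_cohort, normalized_cohort)
        assert (table.rmse_norm.to_numpy() == 0).all()
        np.testing.assert_allclose(table.cosine.to_numpy(), 1.0)

    def test_grid_shape_12_by_diagnoses(self, normalized_cohort):
        table = similarity_report(normalized_cohort, normalized_cohort)
        assert table.rmse_norm.shape == (12, 6)
        assert set(table.rmse_norm.columns) == {
            r.diagnosis_label for r in normalized_cohort
        }

    def test_grand_mean_equals_bruteforce_cell_average(self, normalized_cohort):
        rng = np.random.default_rng(5)
        perturbed = []
        for r in normalized_cohort:
            p = r.copy()
            p.leads = {k: v + rng.normal(0, 0.01, v.shape) for k, v in r.leads.items()}
            perturbed.append(p)
        table = similarity_report(perturbed, normalized_cohort)
        raw = []
        weights = []
        for col in table.rmse_norm.columns:
            for lead in table.rmse_norm.index:
                raw.append(table.rmse_norm.loc[lead, col])
                weights.append(table.n_records.loc[lead, col])
        expected = np.average(raw, weights=weights)
        assert table.grand_mean("rmse_norm") == pytest.approx(expected, rel=1e-12)

    def test_group_means_cover_lead_groups(self, normalized_cohort):
        table = similarity_report(normalized_cohort, normalized_cohort)
        groups = table.group_means("cosine")
        assert set(groups) == {"standard", "extremity", "precordial"}

    def test_unmatched_records_rejected(self, normalized_cohort):
        with pytest.raises(ValueError, match="matched"):
            similarity_report(normalized_cohort[:2], normalized_cohort[:3])


def t_cdf_oracle(t, df):
    """Student-t CDF via the regularized incomplete beta function."""
    x = df / (df + t * t)
    p_tail = 0.5 * betainc(df / 2.0, 0.5, x)
    return 1.0 - p_tail if t >= 0 else p_tail


def two_sided_p_oracle(a, b):
    a, b = np.asarray(a), np.asarray(b)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, 2.0 * (1.0 - t_cdf_oracle(abs(t), df))


def frame(values):
    return pd.DataFrame(
        {m: values for m in ("accuracy", "precision", "recall", "f1")}
    )


class TestTTests:
    def test_identical_nonconstant_vectors(self):
        v = [0.9, 0.92, 0.88, 0.91, 0.9]
        results = compare_real_vs_synthetic(frame(v), frame(v))
        for r in results:
            assert r.t == pytest.approx(0.0, abs=1e-12)
            assert r.p == pytest.approx(1.0)
            assert not r.significant

    def test_separated_samples_significant(self):
        a = frame([0.9] * 5)
        b = frame([0.1, 0.1, 0.1, 0.1, 0.2])
        results = compare_real_vs_synthetic(a, b)
        for r in results:
            assert r.p < 0.01 and r.significant

    def test_p_values_match_t_cdf_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a = rng.normal(0.8, 0.05, 5)
            b = rng.normal(0.78, 0.05, 5)
            res = compare_real_vs_synthetic(frame(a), frame(b))[0]
            t_o, p_o = two_sided_p_oracle(a, b)
            assert res.t == pytest.approx(t_o, rel=1e-9)
            assert res.p == pytest.approx(p_o, abs=1e-6)

    def test_degenerate_zero_variance_flagged(self):
        same = compare_real_vs_synthetic(frame([0.5] * 5), frame([0.5] * 5))[0]
        assert same.degenerate and same.p == 1.0
        diff = compare_real_vs_synthetic(frame([0.5] * 5), frame([0.6] * 5))[0]
        assert diff.degenerate and diff.significant


class SeparableDataset:
    """Records whose class is encoded in beat spacing (fast stand-in)."""

    @staticmethod
    def build(n_per_class=30, frames=200, seed=0):
        from datetime import datetime

        from ecgsynth.leads import LEAD_NAMES
        from ecgsynth.records import make_record

        rng = np.random.default_rng(seed)
        records, labels = [], []
        for i in range(2 * n_per_class):
            label = i % 2
            period = 40 if label else 25
            base = np.zeros(frames)
            phase = rng.integers(0, period)
            base[phase::period] = 1.0
            leads = {
                name: base * (j + 1) / 12 + rng.normal(0, 0.01, frames)
                for j, name in enumerate(LEAD_NAMES)
            }
            rec = make_record(
                f"r{i}", f"s{i}", datetime(2020, 1, 1), 500.0,
                {k: np.clip(v, 0, 1) for k, v in leads.items()},
                diagnosis_label="slow" if label else "fast",
                normalized=True,
            )
            records.append(rec)
            labels.append(label)
        return records, np.array(labels)


SMALL_SPEC = ClassifierSpec(
    frames=200, conv_channels=(4, 4, 8, 8, 8, 8), epochs=8, batch_size=16,
    learning_rate=3e-3, folds=5, seed=0,
)


class TestClassifier:
    @pytest.fixture(scope="class")
    def separable(self):
        return SeparableDataset.build()

    @pytest.fixture(scope="class")
    def folds(self, separable):
        records, labels = separable
        return train_classifier(records, labels, SMALL_SPEC)

    def test_five_fold_metric_vectors(self, folds):
        _, metrics = folds
        assert len(metrics) == 5
        assert set(metrics.columns) >= {"accuracy", "precision", "recall", "f1", "auc"}
        assert ((metrics[["accuracy", "precision", "recall", "f1"]] >= 0).all().all())
        assert ((metrics[["accuracy", "precision", "recall", "f1"]] <= 1).all().all())

    def test_separable_classes_learned(self, folds):
        _, metrics = folds
        assert metrics["accuracy"].mean() >= 0.9

    def test_shuffled_labels_at_chance(self, separable):
        records, labels = separable
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(labels)
        _, metrics = train_classifier(records, shuffled, SMALL_SPEC)
        assert 0.5 - 0.15 <= metrics["accuracy"].mean() <= 0.5 + 0.15

    def test_single_class_rejected(self, separable):
        records, labels = separable
        with pytest.raises(ValueError, match="binary"):
            train_classifier(records, np.zeros_like(labels), SMALL_SPEC)

    def test_cross_domain_and_leakage_guard(self, separable):
        records, labels = separable
        model = fit_single_classifier(records[:40], labels[:40], SMALL_SPEC, seed=3)
        held_out = records[40:]
        metrics = cross_domain_test(model, held_out, labels[40:])
        assert metrics["accuracy"] >= 0.8
        with pytest.raises(ValueError, match="leakage"):
            cross_domain_test(model, records[:4], labels[:4])

    def test_perfect_scores_give_unit_metrics(self):
        from ecgsynth.validation import _binary_metrics

        y = np.array([0, 1, 0, 1])
        m = _binary_metrics(y, y, y.astype(float))
        assert m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["auc"] == 1.0

    def test_random_scorer_auc_near_half(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        aucs = [
            roc_auc_score(rng.integers(0, 2, 200), rng.random(200)) for _ in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05
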