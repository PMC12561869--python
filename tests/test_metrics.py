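"""Metric suite versus independent oracles (sklearn and brute force)."""

import numpy as np
import pytest

from sleepstager.metrics import (ConfusionMatrix, compute_metrics, confusion,
                                 hypnogram_series, one_vs_rest,
                                 plot_position_to_class)


def random_confusions(n, seed=0, scale=200):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        c = rng.integers(0, scale, size=(5, 5))
        if c.sum() == 0:
            c[0, 0] = 1
        yield ConfusionMatrix(c)


def brute_force_metrics(counts):
    """Independent evaluation straight from the definitions."""
    total = counts.sum()
    acc = counts.trace() / total
    pre, sen, spe, f1 = [], [], [], []
    for k in range(5):
        tp = counts[k, k]
        fp = counts[:, k].sum() - tp
        fn = counts[k, :].sum() - tp
        tn = total - tp - fp - fn
        p = tp / (tp + fp) if tp + fp else 0.0
        s = tp / (tp + fn) if tp + fn else 0.0
        pre.append(p)
        sen.append(s)
        spe.append(tn / (tn + fp) if tn + fp else 0.0)
        f1.append(2 * p * s / (p + s) if p + s else 0.0)
    pe = sum(counts[k, :].sum() * counts[:, k].sum()
             for k in range(5)) / total ** 2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    return dict(accuracy=acc, f1_macro=np.mean(f1), kappa=kappa,
                sensitivity=np.mean(sen), specificity=np.mean(spe),
                precision=np.mean(pre))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 2, 2])
        c = confusion(y, y)
        assert np.array_equal(np.diag(np.diag(c.counts)), c.counts)

    def test_empty_input_gives_zero_matrix(self):
        assert confusion([], []).total == 0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 5, 1000)
        p = rng.integers(0, 5, 1000)
        c = confusion(t, p)
        for i in range(5):
            for j in range(5):
                assert c.counts[i, j] == int(((t == i) & (p == j)).sum())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0])


class TestOneVsRest:
    def test_partition_identity(self):
        for conf in random_confusions(20, seed=3):
            for k in range(5):
                tp, fp, tn, fn = one_vs_rest(conf, k)
                assert tp + fp + tn + fn == conf.total

    def test_diagonal_matrix_has_no_errors(self):
        conf = ConfusionMatrix(np.diag([5, 4, 3, 2, 1]))
        for k in range(5):
            tp, fp, tn, fn = one_vs_rest(conf, k)
            assert fp == 0 and fn == 0

    def test_matches_binarized_counting(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 5, 500)
        p = rng.integers(0, 5, 500)
        conf = confusion(t, p)
        for k in range(5):
            tp, fp, tn, fn = one_vs_rest(conf, k)
            assert tp == int(((t == k) & (p == k)).sum())
            assert fp == int(((t != k) & (p == k)).sum())
            assert fn == int(((t == k) & (p != k)).sum())
            assert tn == int(((t != k) & (p != k)).sum())


class TestComputeMetrics:
    def test_agrees_with_brute_force_on_random_matrices(self):
        for conf in random_confusions(200, seed=42):
            got = compute_metrics(conf)
            ref = brute_force_metrics(conf.counts.astype(float))
            for name, val in ref.items():
                assert abs(getattr(got, name) - val) < 1e-10, name

    def test_agrees_with_sklearn_on_label_streams(self):
        from sklearn.metrics import (accuracy_score, cohen_kappa_score,
                                     f1_score, precision_score, recall_score)

        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.integers(0, 5, 400)
            p = np.where(rng.random(400) < 0.6, t, rng.integers(0, 5, 400))
            rep = compute_metrics(confusion(t, p))
            assert np.isclose(rep.accuracy, accuracy_score(t, p), atol=1e-12)
            assert np.isclose(rep.kappa, cohen_kappa_score(t, p), atol=1e-12)
            assert np.isclose(rep.f1_macro,
                              f1_score(t, p, average="macro"), atol=1e-12)
            assert np.isclose(rep.precision,
                              precision_score(t, p, average="macro"),
                              atol=1e-12)
            assert np.isclose(rep.sensitivity,
                              recall_score(t, p, average="macro"),
                              atol=1e-12)

    def test_worked_binary_example(self):
        # two-class matrix embedded in the 5x5 frame:
        # P0 = 0.85, Pe = (60*55 + 40*45)/100^2 = 0.51
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0], counts[0, 1] = 50, 10
        counts[1, 0], counts[1, 1] = 5, 35
        rep = compute_metrics(ConfusionMatrix(counts))
        assert abs(rep.accuracy - 0.85) < 1e-12
        assert abs(rep.kappa - (0.85 - 0.51) / (1 - 0.51)) < 1e-12

    def test_perfect_and_degenerate_cases(self):
        rep = compute_metrics(ConfusionMatrix(np.diag([10, 5, 30, 8, 12])))
        assert rep.accuracy == 1.0 and rep.kappa == 1.0 and rep.f1_macro == 1.0
        # constant predictor: observed accuracy equals chance, kappa 0
        counts = np.zeros((5, 5), dtype=int)
        counts[:, 2] = [10, 5, 60, 10, 15]
        rep = compute_metrics(ConfusionMatrix(counts))
        assert abs(rep.kappa) < 1e-12

    def test_scale_invariance(self):
        for conf in random_confusions(10, seed=5):
            a = compute_metrics(conf)
            b = compute_metrics(ConfusionMatrix(conf.counts * 7))
            for f in ("accuracy", "f1_macro", "kappa", "sensitivity",
                      "specificity", "precision"):
                assert np.isclose(getattr(a, f), getattr(b, f), atol=1e-12)

    def test_accuracy_is_frequency_weighted_mean_sensitivity(self):
        for conf in random_confusions(10, seed=6):
            rep = compute_metrics(conf)
            freq = conf.counts.sum(axis=1) / conf.total
            sen = rep.per_class["SEN"].to_numpy()
            assert np.isclose(rep.accuracy, (freq * sen).sum(), atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestMetricProperties:
    """Structural invariants over arbitrary confusion matrices."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts_matrices = st.lists(
        st.integers(min_value=0, max_value=500), min_size=25,
        max_size=25).map(lambda v: np.array(v).reshape(5, 5)).filter(
            lambda c: c.sum() > 0)

    @given(counts=counts_matrices)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_all_fields_in_range(self, counts):
        rep = compute_metrics(ConfusionMatrix(counts))
        for f in ("accuracy", "f1_macro", "sensitivity", "specificity",
                  "precision"):
            assert 0.0 <= getattr(rep, f) <= 1.0
        assert -1.0 <= rep.kappa <= 1.0

    @given(counts=counts_matrices)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_one_vs_rest_partition_and_trace(self, counts):
        conf = ConfusionMatrix(counts)
        tps = 0
        for k in range(5):
            tp, fp, tn, fn = one_vs_rest(conf, k)
            assert tp + fp + tn + fn == conf.total
            tps += tp
        assert tps == counts.trace()


class TestHypnogramSeries:
    def test_identical_inputs_identical_traces(self):
        y = np.array([0, 2, 2, 3, 4, 0])
        df = hypnogram_series(y, y)
        assert (df["truth"] == df["predicted"]).all()
        assert len(df) == len(y)

    def test_plot_order_round_trips(self):
        y = np.array([0, 1, 2, 3, 4])
        df = hypnogram_series(y)
        back = [plot_position_to_class(v) for v in df["truth"]]
        assert back == y.tolist()

    def test_conventional_ordering_w_on_top(self):
        df = hypnogram_series(np.array([0, 3]))
        assert df["truth"].iloc[0] > df["truth"].iloc[1]
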