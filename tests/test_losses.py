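"""Batched partial-likelihood, oracle and two-task losses against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from minicox import (
    Batch,
    ConstantBaseline,
    SurvivalDataset,
    binary_cross_entropy,
    full_batched_loss,
    full_negative_log_likelihood,
    mini_batched_loss,
    oracle_loss,
    partition_batches,
    true_loss,
    two_task_loss,
)
from minicox.losses import (
    EVENT_FREE_BATCHES,
    binary_cross_entropy_with_grad,
    full_batched_loss_with_grad,
    mini_batched_loss_with_grad,
    oracle_loss_with_grad,
    two_task_loss_with_grad,
)
from minicox.simdata import SimulationSpec

from conftest import random_dataset


def brute_force_partial_likelihood_loss(times, events, scores):
    """Term-by-term negative log of the partial-likelihood product.

    Independent oracle: explicit risk sets by definition, no shared code
    with the implementation.
    """
    times, events, scores = map(np.asarray, (times, events, scores))
    total = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        denom = sum(np.exp(scores[j]) for j in range(len(times)) if times[j] >= times[i])
        total += np.log(np.exp(scores[i]) / denom)
    return -total / len(times)


class TestFullBatchedLoss:
    @pytest.mark.parametrize(
        "times, events, scores, expected",
        [
            ([1.0, 2.0], [1, 1], [0.0, 0.0], np.log(2) / 2),
            ([1.0, 2.0], [1, 1], [1.0, 0.0], -(1 - np.log(np.e + 1)) / 2),
            ([1.0, 2.0], [0, 1], [5.0, -3.0], 0.0),
        ],
    )
    def test_hand_values(self, times, events, scores, expected):
        ds = SurvivalDataset(times, events)
        assert full_batched_loss(ds, scores) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_small_datasets(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            ds = random_dataset(rng, n, tie_prob=0.4)
            f = rng.normal(0, 1.5, n)
            assert full_batched_loss(ds, f) == pytest.approx(
                brute_force_partial_likelihood_loss(ds.times, ds.events, f), abs=1e-10
            )

    def test_shift_invariance(self, rng):
        """Partial likelihood ignores a constant shift; full likelihood does not."""
        ds = random_dataset(rng, 20)
        f = rng.normal(0, 1, ds.n)
        assert full_batched_loss(ds, f + 2.3) == pytest.approx(
            full_batched_loss(ds, f), abs=1e-9
        )
        assert oracle_loss(ds, f + 2.3) != pytest.approx(oracle_loss(ds, f), abs=1e-3)

    def test_event_free_dataset_returns_zero_and_counts(self):
        ds = SurvivalDataset([1.0, 2.0], [0, 0])
        EVENT_FREE_BATCHES.reset()
        assert full_batched_loss(ds, [0.3, -0.1]) == 0.0
        assert EVENT_FREE_BATCHES.count == 1


class TestMiniBatchedLoss:
    def test_full_batch_equals_full_batched_loss(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            ds = random_dataset(rng, n, tie_prob=0.2)
            f = rng.normal(0, 1, n)
            batch = Batch.of(np.arange(n))
            assert mini_batched_loss(ds, f, batch) == full_batched_loss(ds, f)

    def test_two_member_batch_reduces_to_two_sample_case(self):
        ds = SurvivalDataset([9.0, 1.0, 2.0, 7.0], [0, 1, 1, 0])
        f = np.array([4.0, 0.0, 0.0, -2.0])
        assert mini_batched_loss(ds, f, Batch.of([1, 2])) == pytest.approx(
            np.log(2) / 2
        )

    def test_all_censored_batch_is_zero(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 0, 0])
        EVENT_FREE_BATCHES.reset()
        assert mini_batched_loss(ds, np.zeros(3), Batch.of([1, 2])) == 0.0
        assert EVENT_FREE_BATCHES.count == 1

    def test_batch_of_one_rejected(self, two_sample_events):
        with pytest.raises(ValueError):
            mini_batched_loss(two_sample_events, [0.0, 0.0], Batch.of([0]))


class TestOracleAndTrueLoss:
    def test_hand_values(self):
        assert oracle_loss(SurvivalDataset([1, 2], [1, 1]), [0.0, 0.0]) == 1.5
        assert oracle_loss(
            SurvivalDataset([1, 2], [1, 0]), [np.log(2), 0.0]
        ) == pytest.approx(1.6534264097)

    def test_matches_full_likelihood_with_unit_baseline(self, rng):
        ds = random_dataset(rng, 15)
        f = rng.normal(0, 1, ds.n)
        assert oracle_loss(ds, f) == pytest.approx(
            full_negative_log_likelihood(ds, f, ConstantBaseline(1.0)), abs=1e-12
        )

    def test_single_sample_minimiser_is_log_inverse_time(self):
        """For one uncensored sample, δf − e^f T* is maximised at f = −log T*."""
        t = 3.7
        ds = SurvivalDataset([t], [1])
        res = minimize_scalar(lambda f: oracle_loss(ds, [f]), bounds=(-5, 5),
                              method="bounded")
        assert res.x == pytest.approx(-np.log(t), abs=1e-5)

    def test_true_loss_equals_oracle_at_true_scores(self, rng):
        spec = SimulationSpec(class_log_hazards=(0.0, 3.0))
        n = 30
        classes = rng.integers(0, 2, n)
        ds = random_dataset(rng, n)
        phis = np.asarray(spec.class_log_hazards)[classes]
        assert true_loss(ds, spec, classes) == pytest.approx(oracle_loss(ds, phis))
        with pytest.raises(ValueError):
            true_loss(ds, spec, np.full(n, 5))


class TestBCEAndTwoTask:
    def test_hand_values(self):
        assert binary_cross_entropy([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))
        assert binary_cross_entropy([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-10)
        value, _ = binary_cross_entropy_with_grad(np.array([0.0]), np.array([1]))
        assert value == pytest.approx(np.log(2))

    def test_two_task_sum_of_components(self, rng):
        ds = random_dataset(rng, 12, with_labels=True)
        f = rng.normal(0, 1, ds.n)
        batch = Batch.of(rng.choice(ds.n, 6, replace=False))
        expected = mini_batched_loss(ds, f, batch) + binary_cross_entropy(
            expit(f[batch.member_indices]), ds.labels[batch.member_indices]
        )
        assert two_task_loss(ds, f, ds.labels, batch) == pytest.approx(expected)

    def test_two_sample_hand_value(self):
        ds = SurvivalDataset([1.0, 2.0], [1, 1], labels=[1, 0])
        value = two_task_loss(ds, [0.0, 0.0], ds.labels, Batch.of([0, 1]))
        assert value == pytest.approx(np.log(2) / 2 + np.log(2))

    def test_missing_labels_rejected(self, two_sample_events):
        with pytest.raises(ValueError):
            two_task_loss(two_sample_events, [0.0, 0.0], None, Batch.of([0, 1]))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        n = 10
        ds = random_dataset(rng, n, with_labels=True, tie_prob=0.3)
        batch = Batch.of(rng.choice(n, 6, replace=False))
        f0 = rng.normal(0, 1, n)
        cases = [
            lambda f: full_batched_loss_with_grad(ds, f),
            lambda f: mini_batched_loss_with_grad(ds, f, batch),
            lambda f: oracle_loss_with_grad(ds, f, batch),
            lambda f: two_task_loss_with_grad(ds, f, ds.labels, batch),
        ]
        eps = 1e-6
        for fn in cases:
            _, grad = fn(f0)
            for k in range(n):
                step = np.zeros(n)
                step[k] = eps
                numeric = (fn(f0 + step)[0] - fn(f0 - step)[0]) / (2 * eps)
                if abs(numeric) > 1e-9:
                    assert abs(grad[k] - numeric) / max(abs(numeric), 1e-9) < 1e-5
                else:
                    assert abs(grad[k]) < 1e-7


class TestPartitioning:
    def test_partitions_cover_each_index_once(self, rng):
        batches = partition_batches(103, 10, rng)
        all_idx = np.concatenate([b.member_indices for b in batches])
        assert sorted(all_idx.tolist()) == list(range(103))
        assert all(b.size >= 2 for b in batches)

    def test_trailing_singleton_merged(self, rng):
        batches = partition_batches(9, 4, rng)
        assert sorted(b.size for b in batches) == [4, 5]


class TestLinearCoxRecovery:
    def test_minimising_full_batched_loss_recovers_classical_fit(self):
        """A linear scorer f = βx trained on the partial-likelihood loss
        agrees with a classical Cox fit within 3 standard errors."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(np.exp(-1.0 * x))
        ds = SurvivalDataset(times + 1e-9, np.ones(n, dtype=int))

        def objective(beta):
            value, grad = full_batched_loss_with_grad(ds, beta[0] * x)
            return value, np.array([grad @ x])

        fit = minimize(objective, x0=[0.0], jac=True, method="L-BFGS-B")
        beta_ours = fit.x[0]

        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"x": x, "T": ds.times, "E": ds.events}),
            duration_col="T", event_col="E",
        )
        beta_ref = cph.params_["x"]
        se_ref = cph.standard_errors_["x"]
        assert abs(beta_ours - beta_ref) < 3 * se_ref
        assert abs(beta_ours - 1.0) < 3 * se_ref
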