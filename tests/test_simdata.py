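"""Generators: exponential hazards, censoring rules, image structure, ledgers."""

import numpy as np
import pytest

from minicox import (
    SurvivalDataset,
    apply_median_censoring,
    concordance_index,
    make_nodule_images,
    make_two_class_images,
    nodule_survival,
    simulate_survival_times,
)
from minicox.simdata import (
    ImageSample,
    Nodule,
    NoduleParams,
    SimulationSpec,
    ledger_frame,
    load_images,
    save_images,
    stack_pixels,
)


SPEC_SMALL = SimulationSpec(n_train=300, n_test=100, seed=11)


class TestSurvivalTimes:
    def test_unit_rate_mean(self):
        spec = SimulationSpec(class_log_hazards=(0.0,), seed=5)
        t = simulate_survival_times(spec, np.zeros(10000, dtype=int))
        assert abs(t.mean() - 1.0) < 0.03  # 3 sd of the mean

    def test_log_hazard_three_mean(self):
        spec = SimulationSpec(class_log_hazards=(0.0, 3.0), seed=6)
        t = simulate_survival_times(spec, np.ones(10000, dtype=int))
        expected = np.exp(-3.0)
        assert abs(t.mean() - expected) < 3 * expected / 100

    def test_seed_determinism_and_unknown_class(self):
        spec = SimulationSpec(seed=9)
        cls = np.zeros(50, dtype=int)
        assert np.array_equal(
            simulate_survival_times(spec, cls), simulate_survival_times(spec, cls)
        )
        with pytest.raises(ValueError):
            simulate_survival_times(spec, np.full(5, 7))


class TestMedianCensoring:
    def test_single_class_censors_quarter_above_median(self):
        rng = np.random.default_rng(0)
        ds = SurvivalDataset(rng.exponential(1, 100) + 1e-6, np.ones(100, dtype=int))
        out = apply_median_censoring(ds, np.zeros(100, dtype=int), seed=1)
        censored = out.events == 0
        assert censored.sum() == 25
        assert (out.times[censored] > np.median(ds.times)).all()
        assert np.array_equal(out.times, ds.times)  # times never modified

    def test_event_count_accounting(self):
        rng = np.random.default_rng(2)
        n = 201
        classes = rng.integers(0, 2, n)
        ds = SurvivalDataset(rng.exponential(1, n) + 1e-6, np.ones(n, dtype=int))
        out = apply_median_censoring(ds, classes, seed=3)
        med = np.median(ds.times)
        expected_censored = sum(
            int((ds.times[classes == c] > med).sum()) // 2 for c in (0, 1)
        )
        assert (out.events == 0).sum() == expected_censored

    def test_per_class_median_option(self):
        rng = np.random.default_rng(4)
        n = 400
        classes = rng.integers(0, 2, n)
        rates = np.where(classes == 0, 1.0, 20.0)
        ds = SurvivalDataset(rng.exponential(1 / rates) + 1e-9, np.ones(n, dtype=int))
        out = apply_median_censoring(ds, classes, seed=5, median="per_class")
        for c in (0, 1):
            m = classes == c
            med = np.median(ds.times[m])
            censored = m & (out.events == 0)
            assert censored.sum() == int((ds.times[m] > med).sum()) // 2
            assert (ds.times[censored] > med).all()

    def test_requires_all_events(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 0, 1])
        with pytest.raises(ValueError):
            apply_median_censoring(ds, np.zeros(3, dtype=int), seed=0)


class TestTwoClassImages:
    def test_linearly_separable_and_balanced(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        samples = make_two_class_images(SimulationSpec(n_train=800, n_test=200, seed=3))
        X = stack_pixels(samples).reshape(len(samples), -1)
        y = np.array([s.class_id for s in samples])
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.3, random_state=0)
        acc = LogisticRegression(max_iter=2000).fit(Xtr, ytr).score(Xte, yte)
        assert acc >= 0.99
        # class balance within binomial noise (3 sd)
        assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(len(y))
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_seeded_reproducibility(self):
        a = make_two_class_images(SPEC_SMALL)
        b = make_two_class_images(SPEC_SMALL)
        assert np.array_equal(stack_pixels(a), stack_pixels(b))
        assert [s.class_id for s in a] == [s.class_id for s in b]


@pytest.fixture(scope="module")
def generated():
    spec = SimulationSpec(censoring_scheme="nodule_cifar", n_train=500,
                          n_test=100, seed=21)
    return make_nodule_images(spec), spec


class TestNoduleImages:

    def test_cancer_images_have_exactly_two_patches(self, generated):
        (samples, ds), _ = generated
        for s in samples:
            patches = [n for n in s.nodule_ledger if n.kind == "patch"]
            assert len(patches) == (2 if s.class_id == 1 else 0)

    def test_group_structure(self, generated):
        (samples, ds), _ = generated
        labels = ds.labels
        # cancer prevalence ~ 1/2 within binomial noise (3 sd)
        assert abs(labels.mean() - 0.5) < 3 * 0.5 / np.sqrt(ds.n)
        # all non-cancer samples censored
        assert (ds.events[labels == 0] == 0).all()
        # roughly half of cancer cases censored
        cancer_events = ds.events[labels == 1]
        assert abs(cancer_events.mean() - 0.5) < 3 * 0.5 / np.sqrt(len(cancer_events))

    def test_nodule_size_ordering_across_groups(self, generated):
        (samples, ds), _ = generated
        max_size = np.array([s.max_nodule_size() for s in samples])
        labels, events = ds.labels, ds.events
        params = NoduleParams()
        event_mean = max_size[(labels == 1) & (events == 1)].mean()
        cens_cancer_mean = max_size[(labels == 1) & (events == 0)].mean()
        noncancer_mean = max_size[labels == 0].mean()
        assert event_mean > cens_cancer_mean > noncancer_mean
        cens_sizes = max_size[(labels == 1) & (events == 0)]
        assert cens_sizes.max() < params.event_patch_size[1]

    def test_pixel_range_and_determinism(self, generated):
        (samples, ds), spec = generated
        X = stack_pixels(samples)
        assert X.min() >= 0.0 and X.max() <= 1.0
        again, ds2 = make_nodule_images(spec)
        assert np.array_equal(stack_pixels(again), X)
        assert np.array_equal(ds2.times, ds.times)


class TestNoduleSurvival:
    def test_closed_form_mean_and_size_ordering(self):
        rng = np.random.default_rng(0)
        for size, scale in [(4.0, 0.25), (8.0, 0.25), (12.0, 0.25)]:
            ledger = [Nodule((0, 0), size, "patch")]
            draws = [nodule_survival(ledger, scale, rng=rng) for _ in range(5000)]
            expected = np.exp(-scale * size)
            assert abs(np.mean(draws) - expected) < 5 * expected / np.sqrt(5000)

    def test_zero_scale_is_unit_exponential(self):
        rng = np.random.default_rng(1)
        ledger = [Nodule((0, 0), 100.0, "patch")]
        draws = [nodule_survival(ledger, 0.0, rng=rng) for _ in range(4000)]
        assert abs(np.mean(draws) - 1.0) < 0.05

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError):
            nodule_survival([], 0.25, seed=0)


class TestTheoreticalCIndex:
    def test_class_constant_scores_match_closed_form(self):
        """For two classes with log hazards φ0, φ1 and class-constant scores,
        the expected half-tie C-index on uncensored data is
        q·e^Δ/(1+e^Δ) + (1−q)/2 with Δ = φ1−φ0 and q the between-class pair
        fraction."""
        spec = SimulationSpec(class_log_hazards=(0.0, 3.0), seed=13,
                              n_train=2000, n_test=2000)
        rng = np.random.default_rng(13)
        n = 2000
        classes = rng.integers(0, 2, n)
        times = simulate_survival_times(spec, classes, rng=rng)
        ds = SurvivalDataset(times, np.ones(n, dtype=int))
        scores = np.asarray(spec.class_log_hazards)[classes]
        empirical = concordance_index(ds, scores)
        n0, n1 = (classes == 0).sum(), (classes == 1).sum()
        q = n0 * n1 / (n * (n - 1) / 2)
        delta = 3.0
        theory = q * np.exp(delta) / (1 + np.exp(delta)) + (1 - q) / 2
        assert empirical == pytest.approx(theory, abs=0.01)


class TestLedgersAndContainers:
    def test_ledger_round_trip(self, tmp_path):
        spec = SimulationSpec(censoring_scheme="nodule_cifar", n_train=40,
                              n_test=10, seed=5)
        samples, ds = make_nodule_images(spec)
        frame = ledger_frame(samples, ds, hazard_scale=NoduleParams().hazard_scale)
        path = tmp_path / "ledger.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        loaded = pd.read_csv(path)
        assert loaded["sample_id"].tolist() == frame["sample_id"].tolist()
        for col in ("phi", "time", "max_nodule_size"):
            assert np.allclose(loaded[col], frame[col])
        assert np.array_equal(loaded["event"], ds.events)

    def test_hdf5_round_trip(self, tmp_path):
        samples = make_two_class_images(SimulationSpec(n_train=6, n_test=2, seed=1))
        path = tmp_path / "images.h5"
        save_images(path, samples)
        pixels, ids = load_images(path)
        assert np.allclose(pixels, stack_pixels(samples))
        assert ids == [s.sample_id for s in samples]
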