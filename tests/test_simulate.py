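"""The synthetic-sample generator and fit scoring."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from sigrefit import (
    PriorSpec,
    mse_weights,
    run_benchmark,
    simulate_sample,
    support_metrics,
    synthetic_catalog,
)
from sigrefit.fitting import FitSettings
from sigrefit.simulate import (
    MAX_NOISE_CONTEXTS,
    MIN_ACTIVE_WEIGHT,
    NOISE_SCALE_REFERENCE,
)


def test_noise_scale_is_relative_to_mean_mixture_mass():
    assert NOISE_SCALE_REFERENCE == pytest.approx(1 / 96)


def test_thousand_draws_respect_sparsity_and_weight_floor(catalog30):
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        s = simulate_sample(catalog30, 0.1, 50, rng)
        active = s.true_weights[s.true_weights > 0]
        assert 2 <= active.size <= 8
        assert active.min() >= MIN_ACTIVE_WEIGHT
        assert active.sum() == pytest.approx(1.0)
        assert 1 <= s.n_noise_contexts <= MAX_NOISE_CONTEXTS
        assert s.spectrum.total == 50


def test_zero_noise_leaves_the_mixture_untouched(catalog30):
    s = simulate_sample(catalog30, 0.0, 100, 7)
    assert np.array_equal(s.noisy_distribution, s.noiseless_mixture)


def test_noise_touches_at_most_the_selected_contexts(catalog30):
    """Up to renormalization, only the drawn noise contexts are perturbed."""
    s = simulate_sample(catalog30, 0.5, 100, 3)
    # unperturbed coordinates keep a common ratio 1/Z to the clean mixture
    ratio = s.noisy_distribution / s.noiseless_mixture
    baseline = np.median(ratio)
    assert np.sum(~np.isclose(ratio, baseline, rtol=1e-9)) <= s.n_noise_contexts


def test_fixed_true_weights_are_passed_through(catalog30):
    w = np.zeros(30)
    w[[1, 2]] = [0.5, 0.5]
    s = simulate_sample(catalog30, 0.0, 100, 5, true_weights=w)
    assert np.array_equal(s.true_weights, w)


class TestSupportMetrics:
    def test_perfect_recovery(self):
        t = np.array([0.5, 0.5, 0.0])
        m = support_metrics(t, t)
        assert (m.precision, m.recall, m.accuracy) == (1.0, 1.0, 1.0)

    def test_contingency_arithmetic(self):
        true = np.zeros(30)
        true[[1, 2]] = 0.5
        pred = np.zeros(30)
        pred[[2, 3]] = 0.5
        m = support_metrics(true, pred)
        assert m.precision == 0.5
        assert m.recall == 0.5
        assert m.accuracy == pytest.approx(28 / 30)
        assert m.true_positive + m.false_positive + m.false_negative + m.true_negative == 30

    def test_empty_prediction_convention(self):
        m = support_metrics(np.array([0.5, 0.5]), np.zeros(2))
        assert m.precision == 1.0
        assert m.recall == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            support_metrics(np.ones(3), np.ones(4))


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    st.integers(0, 2**31 - 1),
)
@hyp_settings(max_examples=50, deadline=None)
def test_mse_matches_direct_summation(vals, seed):
    t = np.array(vals)
    f = np.random.default_rng(seed).uniform(0, 1, size=t.size)
    expected = sum((a - b) ** 2 for a, b in zip(t, f)) / t.size
    assert mse_weights(t, f) == pytest.approx(expected)


@pytest.fixture(scope="module")
def tiny_benchmark(catalog30):
    return run_benchmark(
        catalog30,
        noise_levels=(0.1,),
        mutation_counts=(100,),
        replicates=2,
        settings=FitSettings(cv_repeats=5),
        seed=77,
    )


def test_benchmark_is_deterministic(catalog30, tiny_benchmark):
    again = run_benchmark(
        catalog30,
        noise_levels=(0.1,),
        mutation_counts=(100,),
        replicates=2,
        settings=FitSettings(cv_repeats=5),
        seed=77,
    )
    assert tiny_benchmark.equals(again)


def test_benchmark_table_layout(tiny_benchmark):
    t = tiny_benchmark
    assert set(t.columns) == {
        "noise_level", "n_mutations", "prior_arm", "metric", "mean", "sd", "replicates",
    }
    assert set(t.prior_arm) == {"no_prior", "prior"}
    assert set(t.metric) == {"mse", "precision", "recall", "accuracy"}
    assert (t.replicates == 2).all()
    assert t["mean"].between(0, 1).all()


def test_empty_prior_spec_reduces_to_no_prior_arm(catalog30):
    t = run_benchmark(
        catalog30,
        noise_levels=(0.0,),
        mutation_counts=(60,),
        replicates=2,
        prior_spec=PriorSpec(strength=0.1, fraction_true=0.0),
        settings=FitSettings(cv_repeats=3),
        seed=5,
    )
    wide = t.pivot_table(index="metric", columns="prior_arm", values="mean")
    assert np.allclose(wide["prior"], wide["no_prior"])


def test_catalog_generator_is_deterministic_and_stochastic_columns():
    a = synthetic_catalog(seed=1)
    b = synthetic_catalog(seed=1)
    assert np.array_equal(a.probabilities, b.probabilities)
    assert not np.array_equal(a.probabilities, synthetic_catalog(seed=2).probabilities)
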