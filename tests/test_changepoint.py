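"""Product-partition change-point model: calibration, determinism, peaks."""

import numpy as np
import pytest
from scipy import integrate

from dawnchorus import (
    ChangePointResult,
    bcp_fit,
    detect_transition,
    exact_change_probabilities,
)


def quad_change_probabilities(x, p0=0.2, w0=0.2):
    """Independent tiny-n oracle: partition weights by adaptive quadrature.

    Evaluates the model's partition marginals with scipy.integrate.quad for
    both the p- and w-integrals (no shared quadrature grid, no shared code
    path with the sampler or the enumerator).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    probs = np.zeros(n)
    weights = []
    partitions = []
    for code in range(2 ** (n - 1)):
        bounds = [0] + [i for i in range(1, n) if code >> (i - 1) & 1] + [n]
        k = len(bounds) - 2
        W = sum(
            np.sum((x[a:b] - x[a:b].mean()) ** 2)
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        B = sum(
            (b - a) * x[a:b].mean() ** 2 for a, b in zip(bounds[:-1], bounds[1:])
        )
        p_int, _ = integrate.quad(lambda p: p**k * (1 - p) ** (n - 1 - k), 0, p0)
        w_int, _ = integrate.quad(
            lambda w: w ** (k / 2.0) * (W + w * B) ** (-(n - 1) / 2.0), 0, w0
        )
        weights.append(p_int * w_int)
        partitions.append(bounds[1:-1])
    weights = np.asarray(weights) / np.sum(weights)
    for wgt, bounds in zip(weights, partitions):
        for i in bounds:
            probs[i] += wgt
    return probs


def test_enumeration_agrees_with_adaptive_quadrature():
    for x in ([0.0, 0.1, 2.0], [1.0, 1.1, 0.9, 3.0, 3.2], [0.5, 2.0, 0.4, 1.9]):
        got = exact_change_probabilities(x)
        want = quad_change_probabilities(x)
        np.testing.assert_allclose(got, want, atol=5e-3)


def test_mcmc_tracks_exact_enumeration_on_small_series():
    rng = np.random.default_rng(42)
    series = [
        np.concatenate([rng.normal(0, 0.5, 5), rng.normal(3, 0.5, 5)]),
        rng.normal(1.0, 0.3, 8),
        np.linspace(0, 2, 9) + rng.normal(0, 0.2, 9),
    ]
    for x in series:
        exact = exact_change_probabilities(x)
        fit = bcp_fit(x, iterations=10000, burn_in=5000, seed=7)
        assert np.max(np.abs(fit.posterior_prob - exact)) <= 0.03


def test_constant_series_shows_no_high_probability_change():
    fit = bcp_fit(np.full(30, 3.14), seed=0)
    assert fit.posterior_prob.max() < 0.5


def test_well_separated_step_is_located_with_high_probability():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(5, 0.01, 10)])
    fit = bcp_fit(x, seed=2)
    assert int(np.argmax(fit.posterior_prob)) == 10
    assert fit.posterior_prob[10] > 0.9
    # posterior mean stays within the observed range
    assert fit.posterior_mean.min() >= x.min() - 1e-9
    assert fit.posterior_mean.max() <= x.max() + 1e-9


def test_location_equivariance():
    rng = np.random.default_rng(3)
    x = rng.normal(2.0, 1.0, 25)
    x[12:] += 4.0
    a = bcp_fit(x, seed=5)
    b = bcp_fit(x + 123.4, seed=5)
    np.testing.assert_allclose(a.posterior_prob, b.posterior_prob, atol=0.02)


def test_seed_determinism():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 20)
    a = bcp_fit(x, seed=9)
    b = bcp_fit(x, seed=9)
    np.testing.assert_array_equal(a.posterior_prob, b.posterior_prob)
    np.testing.assert_array_equal(a.posterior_mean, b.posterior_mean)


def test_input_validation():
    with pytest.raises(ValueError, match="too short"):
        bcp_fit([1.0, 2.0])
    with pytest.raises(ValueError, match="NaN"):
        bcp_fit([1.0, np.nan, 2.0, 3.0])
    with pytest.raises(ValueError, match="exceed"):
        bcp_fit(np.ones(5), iterations=100, burn_in=100)
    with pytest.raises(ValueError, match="enumeration"):
        exact_change_probabilities(np.ones(20))


def _result(probs, dates=None):
    probs = np.asarray(probs, dtype=float)
    return ChangePointResult(
        dates=tuple(dates or range(probs.size)),
        posterior_mean=probs * 0,
        posterior_prob=probs,
        iterations=10,
        burn_in=5,
        seed=0,
        p0=0.2,
        w0=0.2,
    )


def test_transition_at_first_peak_with_fold_change():
    res = _result([0.1, 0.2, 0.6, 0.4])
    tr = detect_transition(res, [1.0, 1.0, 2.2, 2.0])
    assert tr.index == 2
    assert tr.prob == pytest.approx(0.6)
    assert tr.fold_change == pytest.approx(2.2)
    assert tr.baseline_days == 2


def test_no_transition_when_below_threshold():
    res = _result([0.1, 0.5, 0.3, 0.2])
    assert detect_transition(res, [1.0, 1.0, 1.0, 1.0]) is None


def test_plateau_resolves_to_earliest_index():
    res = _result([0.1, 0.8, 0.8, 0.2, 0.9, 0.1])
    tr = detect_transition(res, [1.0, 2.0, 2.0, 1.0, 3.0, 1.0])
    assert tr.index == 1


def test_baseline_window_limits_the_mean():
    res = _result([0.0, 0.0, 0.0, 0.9, 0.0])
    tr = detect_transition(res, [10.0, 1.0, 1.0, 4.0, 1.0], baseline=2)
    assert tr.fold_change == pytest.approx(4.0)
    assert tr.baseline_days == 2
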