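"""DoG bias curve: evaluation, half-amplitude, predictors, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdfaces import (
    DoGParams,
    PredictorVariant,
    alpha_to_amplitude,
    amplitude_to_alpha,
    build_predictor,
    derive_trials,
    dog_value,
    filter_trials,
    fit_dog,
    half_amplitude,
    signed_distance,
)

from conftest import make_trials


def grid_extremum(params, domain_half=70.0):
    """Independent oracle: dense grid + local quadratic refinement."""
    x = np.linspace(-domain_half, domain_half, 200_001)
    v = dog_value(x, params)
    k = int(np.argmax(np.abs(v)))
    from scipy.optimize import minimize_scalar
    lo = max(-domain_half, x[k] - 0.01)
    hi = min(domain_half, x[k] + 0.01)
    res = minimize_scalar(
        lambda t: -abs(dog_value(float(t), params)),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    edge = max(abs(dog_value(-domain_half, params)), abs(dog_value(domain_half, params)))
    return max(-res.fun, edge)


def test_dog_zero_at_center():
    p = DoGParams(mu=5.0, sigma=12.0, alpha=100.0)
    assert dog_value(5.0, p) == 0.0


def test_dog_requires_positive_sigma():
    with pytest.raises(ValueError):
        DoGParams(mu=0.0, sigma=0.0, alpha=1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    sigma=st.floats(1.0, 70.0),
    alpha=st.floats(-1e4, 1e4),
    x=st.floats(-70.0, 70.0),
)
def test_dog_odd_symmetry_at_zero_center(sigma, alpha, x):
    p = DoGParams(mu=0.0, sigma=sigma, alpha=alpha)
    assert dog_value(-x, p) == pytest.approx(-dog_value(x, p), abs=1e-12)


@pytest.mark.parametrize("sigma", [3.0, 10.0, 20.0, 45.0, 70.0])
@pytest.mark.parametrize("alpha", [-800.0, -5.0, 13.0, 250.0])
def test_half_amplitude_matches_grid_oracle(sigma, alpha):
    p = DoGParams(mu=0.0, sigma=sigma, alpha=alpha)
    h = half_amplitude(p)
    assert math.copysign(1, h) == math.copysign(1, alpha)
    assert abs(h) == pytest.approx(grid_extremum(p), rel=1e-9)


@pytest.mark.parametrize("mu", [-15.0, 4.0, 20.0])
def test_half_amplitude_offcenter_matches_oracle(mu):
    p = DoGParams(mu=mu, sigma=25.0, alpha=40.0)
    assert abs(half_amplitude(p)) == pytest.approx(grid_extremum(p), rel=1e-9)


def test_half_amplitude_boundary_case():
    # both lobes outside the domain: extremum sits on the boundary
    p = DoGParams(mu=0.0, sigma=120.0, alpha=500.0)
    assert abs(half_amplitude(p, 70.0)) == pytest.approx(grid_extremum(p), rel=1e-9)


def test_half_amplitude_trivia():
    assert half_amplitude(DoGParams(0.0, 20.0, 0.0)) == 0.0
    p1 = half_amplitude(DoGParams(0.0, 20.0, 10.0))
    p2 = half_amplitude(DoGParams(0.0, 20.0, 20.0))
    assert p2 == pytest.approx(2 * p1)


def test_amplitude_alpha_round_trip():
    assert alpha_to_amplitude(amplitude_to_alpha(6.0)) == pytest.approx(6.0)
    p = DoGParams(0.0, 33.0, amplitude_to_alpha(-4.2))
    assert half_amplitude(p) == pytest.approx(-4.2)


# --- predictors ---------------------------------------------------------


def _derived(rows, wheel, experiment=1):
    return derive_trials(make_trials(rows, experiment), wheel, experiment)


def test_within_trial_predictor_counts(derived_exp1, wheel):
    kept, _ = filter_trials(derived_exp1)
    x, y = build_predictor(derived_exp1, "within_trial", wheel)
    assert len(x) == len(kept)
    np.testing.assert_array_equal(np.sort(y), np.sort(kept["error"].to_numpy()))


def test_prev_variant_drops_first_trial(wheel):
    d = _derived([{"face1": 5, "face2": 50, "response": 52},
                  {"face1": 90, "face2": 10, "response": 12}], wheel)
    x, y = build_predictor(d, PredictorVariant.prev_response, wheel)
    assert len(x) == 1
    assert x[0] == signed_distance(10, 52, wheel)
    assert y[0] == 2


def test_prev_variants_hand_computed_table(wheel):
    d = _derived(
        [{"face1": 0, "face2": 30, "response": 33},
         {"face1": 100, "face2": 70, "response": 68},
         {"face1": 140, "face2": 20, "response": 25}],
        wheel,
    )
    for variant, col, prev_vals in [
        ("prev_face2", "face2", [30, 70]),
        ("prev_face1", "face1", [0, 100]),
        ("prev_response", "response", [33, 68]),
    ]:
        x, y = build_predictor(d, variant, wheel)
        expected_x = [signed_distance(70, prev_vals[0], wheel),
                      signed_distance(20, prev_vals[1], wheel)]
        np.testing.assert_array_equal(x, expected_x)
        np.testing.assert_array_equal(y, [-2, 5])


def test_excluded_trials_break_pairs(wheel):
    rows = [{"face2": 10, "response": 12},
            {"face2": 20, "response": 22, "rt_s": 20.0},  # excluded
            {"face2": 30, "response": 29}]
    d = _derived(rows, wheel)
    x, y = build_predictor(d, "prev_face2", wheel)
    # trial 2 excluded: pair (1->2) loses its current trial, pair (2->3)
    # its predecessor; nothing remains
    assert len(x) == 0
    xw, _ = build_predictor(d, "within_trial", wheel)
    assert len(xw) == 2


def test_unknown_variant_rejected(derived_exp1, wheel):
    with pytest.raises(ValueError):
        build_predictor(derived_exp1, "next_trial", wheel)


# --- fitting ------------------------------------------------------------


def test_noiseless_recovery():
    true = DoGParams(mu=0.0, sigma=20.0, alpha=500.0)
    x = np.arange(-70, 71).astype(float)
    y = dog_value(x, true)
    f = fit_dog(x, y)
    assert f.converged
    assert f.params.sigma == pytest.approx(20.0, rel=1e-6)
    assert f.params.alpha == pytest.approx(500.0, rel=1e-6)
    assert abs(f.params.mu) < 1e-4
    assert f.rss == pytest.approx(0.0, abs=1e-8)
    assert f.half_amplitude == pytest.approx(alpha_to_amplitude(500.0), rel=1e-6)


def test_zero_response_gives_zero_half_amplitude():
    x = np.arange(-70, 71).astype(float)
    f = fit_dog(x, np.zeros_like(x))
    assert f.half_amplitude == pytest.approx(0.0, abs=1e-9)


def test_fit_is_deterministic():
    rng = np.random.default_rng(3)
    x = rng.integers(-70, 71, 400)
    y = rng.normal(0, 10, 400)
    f1, f2 = fit_dog(x, y), fit_dog(x, y)
    assert f1.params == f2.params and f1.rss == f2.rss


def test_reflection_equivariance():
    """Mirroring the wheel (x -> -x, y -> -y) preserves attraction, so the
    half-amplitude is invariant with mu flipped; negating the errors alone
    turns attraction into repulsion."""
    rng = np.random.default_rng(8)
    true = DoGParams(mu=3.0, sigma=18.0, alpha=amplitude_to_alpha(5.0))
    x = rng.integers(-70, 71, 900)
    y = dog_value(x.astype(float), true) + rng.normal(0, 12, 900)
    f, fr = fit_dog(x, y), fit_dog(-x, -y)
    assert fr.half_amplitude == pytest.approx(f.half_amplitude, rel=1e-6)
    assert fr.params.mu == pytest.approx(-f.params.mu, abs=1e-4)
    assert fr.rss == pytest.approx(f.rss, rel=1e-9)
    fn = fit_dog(x, -y)
    assert fn.half_amplitude == pytest.approx(-f.half_amplitude, rel=1e-6)


def test_fix_mu_matches_closed_form():
    true = DoGParams(mu=0.0, sigma=25.0, alpha=300.0)
    x = np.arange(-70, 71).astype(float)
    f = fit_dog(x, dog_value(x, true), fix_mu=0.0)
    assert f.params.mu == 0.0
    assert f.half_amplitude == pytest.approx(alpha_to_amplitude(300.0), rel=1e-6)


def test_null_fits_centered_at_zero():
    """Across seeds, fitted half-amplitudes on pure-noise data average ~0."""
    rng = np.random.default_rng(12)
    halves = []
    for _ in range(40):
        x = rng.integers(-70, 71, 600)
        y = rng.normal(0, 14, 600)
        halves.append(fit_dog(x, y).half_amplitude)
    h = np.asarray(halves)
    assert abs(h.mean()) < 2.5 * h.std(ddof=1) / math.sqrt(h.size)


def test_noisy_recovery_close_to_truth():
    true_amp = 6.0
    true = DoGParams(0.0, 20.0, amplitude_to_alpha(true_amp))
    rng = np.random.default_rng(5)
    x = rng.integers(-70, 71, 1800)
    y = dog_value(x.astype(float), true) + rng.normal(0, 10, 1800)
    f = fit_dog(x, y)
    assert f.half_amplitude == pytest.approx(true_amp, abs=1.5)


def test_fit_input_contracts():
    x = np.arange(-70, 71).astype(float)
    with pytest.raises(ValueError):
        fit_dog(x[:5], np.zeros(5))
    with pytest.raises(ValueError):
        fit_dog(np.full(50, 3.0), np.zeros(50))
    with pytest.raises(ValueError):
        fit_dog(x, np.zeros(7))
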