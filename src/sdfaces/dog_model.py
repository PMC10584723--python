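"""Derivative-of-Gaussian (DoG) bias model for serial dependence.

The bias curve relating the inducer-target difference x (morph steps) to the
adjustment error y (morph steps) is

    y = alpha * (x - mu) * N(x; mu, sigma)

where N is the normal density with mean mu and standard deviation sigma.
Up to a rescaling of alpha this is the first derivative of a Gaussian; the
sign convention is chosen so that positive alpha bends the curve toward the
inducer (attraction) and negative alpha away from it (repulsion).

The curve's extremum magnitude — the "half-amplitude", the height of the
peak above zero — is the standard scalar summary of serial-dependence
strength. For this parameterisation the interior extrema sit at x = mu +/-
sigma with magnitude |alpha| * exp(-1/2) / sqrt(2*pi), independent of sigma
(sigma controls only the width).

Fitting minimises the residual sum of squares under box constraints. The
model is linear in alpha, so alpha is profiled out in closed form and the
numerical search runs over (mu, sigma) only, multi-started from a
deterministic grid. Observations are aggregated by unique x value first,
which makes each objective evaluation O(#unique x) instead of O(n) — on the
wheel x is an integer in [-70, 70], so bootstrap refits on thousands of
trials cost the same as on a hundred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize

from .morphspace import MorphWheel, signed_distance

__all__ = [
    "DoGParams",
    "DoGFit",
    "PredictorVariant",
    "dog_value",
    "half_amplitude",
    "amplitude_to_alpha",
    "alpha_to_amplitude",
    "build_predictor",
    "fit_dog",
]

# peak height of (x-mu)*N(x; mu, sigma) at x = mu +/- sigma, any sigma
_PEAK = math.exp(-0.5) / math.sqrt(2.0 * math.pi)

# sigma floor 10: curves narrower than ~10 morph steps on a 141-step wheel
# have no perceptual interpretation and act as single-bin noise detectors,
# inflating the half-amplitude of null data severalfold (measured in the
# estimator-stability study; see docs/methods.md)
DEFAULT_BOUNDS = {"mu": (-20.0, 20.0), "sigma": (10.0, 70.0), "alpha": (-1e6, 1e6)}


@dataclass(frozen=True)
class DoGParams:
    """DoG curve parameters: centre ``mu``, width ``sigma`` (morph steps,
    > 0) and height multiplier ``alpha`` (sign = attraction/repulsion)."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class DoGFit:
    """Result of a constrained least-squares DoG fit."""

    params: DoGParams
    half_amplitude: float
    rss: float
    n_points: int
    converged: bool
    n_starts_used: int


class PredictorVariant(str, Enum):
    """Which stimulus difference drives the bias curve.

    ``within_trial`` pairs the current trial's inducer-target difference with
    its adjustment error. The ``prev_*`` variants test carry-over from the
    preceding trial (its second face, first face, or response) and therefore
    drop the first trial of every session.
    """

    within_trial = "within_trial"
    prev_face2 = "prev_face2"
    prev_face1 = "prev_face1"
    prev_response = "prev_response"


def dog_value(x, params: DoGParams):
    """Evaluate the DoG bias curve at ``x`` (scalar or array, morph steps)."""
    xa = np.asarray(x, dtype=float)
    z = (xa - params.mu) / params.sigma
    val = params.alpha * (xa - params.mu) * np.exp(-0.5 * z * z) / (
        params.sigma * math.sqrt(2.0 * math.pi)
    )
    return float(val) if np.isscalar(x) else val


def amplitude_to_alpha(amplitude: float) -> float:
    """Alpha giving a curve whose signed half-amplitude is ``amplitude``."""
    return amplitude / _PEAK


def alpha_to_amplitude(alpha: float) -> float:
    """Signed half-amplitude of the curve with height multiplier ``alpha``."""
    return alpha * _PEAK


def half_amplitude(params: DoGParams, domain_half: float = 70.0) -> float:
    """Signed extremum of the DoG curve over ``[-domain_half, +domain_half]``.

    Positive = attraction, negative = repulsion; the sign equals
    sign(alpha). The interior extrema of the curve sit exactly at
    mu +/- sigma; if either falls inside the domain the extremum magnitude is
    |alpha| * exp(-1/2)/sqrt(2*pi), otherwise the maximum is attained on the
    domain boundary and is evaluated there.
    """
    if domain_half <= 0:
        raise ValueError("domain_half must be > 0")
    if params.alpha == 0:
        return 0.0
    lo, hi = -domain_half, domain_half
    if (lo <= params.mu - params.sigma <= hi) or (lo <= params.mu + params.sigma <= hi):
        mag = abs(params.alpha) * _PEAK
    else:
        mag = float(np.max(np.abs(dog_value(np.array([lo, hi]), params))))
    return math.copysign(mag, params.alpha)


def build_predictor(trials, variant, wheel: MorphWheel, *, return_frame: bool = False):
    """Construct (x, y) pairs for one predictor variant.

    Parameters
    ----------
    trials
        Derived-trial table (one session-ordered DataFrame with at least
        ``participant, session, trial, target, inducer, response, error,
        delta, excluded`` columns), as produced by
        :func:`sdfaces.preprocessing.derive_trials`.
    variant
        A :class:`PredictorVariant` (or its string value).
    wheel
        The morph wheel, used for circular distances.

    Returns
    -------
    (x, y)
        Integer numpy arrays of equal length. ``y`` is always the current
        trial's adjustment error. For ``within_trial`` x is the current
        inducer-target difference and every kept trial contributes one pair.
        For the ``prev_*`` variants x is the signed distance from the current
        target to the previous trial's Face 2 / Face 1 / response; the first
        trial of each session has no predecessor and is dropped, as is any
        pair whose current or previous trial was excluded.

        With ``return_frame=True`` the contributing (current-trial) rows are
        returned as a third element, aligned with x and y — used to slice
        pairs by the current trial's design cell.
    """
    variant = PredictorVariant(variant)
    df = trials.sort_values(["participant", "session", "trial"], kind="stable")

    if variant is PredictorVariant.within_trial:
        kept = df[~df["excluded"]]
        x = kept["delta"].to_numpy(dtype=int)
        y = kept["error"].to_numpy(dtype=int)
        return (x, y, kept) if return_frame else (x, y)

    source_col = {
        PredictorVariant.prev_face2: "face2",
        PredictorVariant.prev_face1: "face1",
        PredictorVariant.prev_response: "response",
    }[variant]
    grouped = df.groupby(["participant", "session"], sort=False)
    prev_source = grouped[source_col].shift(1)
    prev_excluded = grouped["excluded"].shift(1)
    ok = (~df["excluded"]) & (prev_excluded == False)  # noqa: E712 — NaN (first trial) must drop
    cur = df[ok]
    x = signed_distance(
        cur["target"].to_numpy(dtype=int),
        prev_source[ok].to_numpy(dtype=int),
        wheel,
    )
    x = np.asarray(x, dtype=int)
    y = cur["error"].to_numpy(dtype=int)
    return (x, y, cur) if return_frame else (x, y)


_SQRT2PI = math.sqrt(2.0 * math.pi)


def _rss_grid(mu, sigma, ux, counts, ysum, yss):
    """Profiled RSS on a flat array of (mu, sigma) candidates, vectorised.

    The model is linear in alpha, so for each (mu, sigma) the optimal alpha
    and the resulting RSS have closed forms in the x-aggregated sufficient
    statistics (counts, per-x y sums, total y sum of squares).
    """
    u = ux[None, :] - mu[:, None]
    s = sigma[:, None]
    g = u * np.exp(-0.5 * (u / s) ** 2) / (s * _SQRT2PI)
    gy = g @ ysum
    gg = (g * g) @ counts
    safe = gg > 0
    alpha = np.where(safe, gy / np.where(safe, gg, 1.0), 0.0)
    rss = yss - np.where(safe, gy * gy / np.where(safe, gg, 1.0), 0.0)
    return np.maximum(rss, 0.0), alpha


def _rss_and_grad(theta, ux, counts, ysum, yss, fix_mu):
    """Profiled RSS and its analytic gradient in (mu, sigma)."""
    mu, sigma = (fix_mu, theta[0]) if fix_mu is not None else (theta[0], theta[1])
    u = ux - mu
    e = np.exp(-0.5 * (u / sigma) ** 2)
    g = u * e / (sigma * _SQRT2PI)
    gy = float(g @ ysum)
    gg = float((g * g) @ counts)
    if gg <= 0:
        return yss, np.zeros_like(np.atleast_1d(theta))
    rss = max(yss - gy * gy / gg, 0.0)
    w = u * u / (sigma * sigma) - 1.0
    dg_dmu = e * w / (sigma * _SQRT2PI)
    dg_dsig = g * w / sigma
    grads = []
    for dg in ([dg_dsig] if fix_mu is not None else [dg_dmu, dg_dsig]):
        dgy = float(dg @ ysum)
        dgg = 2.0 * float((g * dg) @ counts)
        grads.append(-(2.0 * gy * dgy * gg - gy * gy * dgg) / (gg * gg))
    return rss, np.asarray(grads)


def fit_dog(
    x,
    y,
    bounds: dict | None = None,
    n_starts: int = 3,
    seed: int = 0,
    *,
    fix_mu: float | None = None,
    min_n: int = 10,
    domain_half: float = 70.0,
    x0: DoGParams | None = None,
) -> DoGFit:
    """Constrained least-squares DoG fit.

    The search runs in two phases. First a deterministic zooming grid
    search over (mu, sigma) — alpha profiled out in closed form at every
    candidate — locates the global basin; the DoG least-squares surface is
    multimodal in (mu, sigma), which the global stage-1 grid handles.
    Then, if ``n_starts`` > 0, that many of the best well-separated grid
    candidates are polished with L-BFGS-B using the analytic gradient.
    ``n_starts=0`` skips the polish (grid resolution ~0.2 steps; used for
    bootstrap refits where only the half-amplitude distribution matters).

    Parameters
    ----------
    x, y
        Predictor differences and adjustment errors, morph steps.
    bounds
        Box constraints, a dict with keys ``mu``, ``sigma``, ``alpha``;
        missing keys fall back to ``DEFAULT_BOUNDS``.
    n_starts
        Number of grid candidates polished with the local optimiser.
    seed
        Accepted for interface symmetry; the search is fully deterministic,
        so the fit is a pure function of (x, y, bounds, n_starts, fix_mu).
    fix_mu
        Pin the curve centre (e.g. 0 for the symmetry-constrained fit) and
        optimise sigma only.
    min_n
        Minimum number of pairs; below this a ValueError is raised and the
        condition should be reported non-estimable.
    x0
        Optional warm start appended to the polish candidates (bootstrap
        refits pass the full-data solution).

    Returns
    -------
    DoGFit
        Best-RSS solution; RSS ties go to the smaller sigma.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs to fit, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate predictor: all x values identical")

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    mu_b, sig_b, alpha_b = b["mu"], b["sigma"], b["alpha"]

    # aggregate by unique x: exact same RSS, O(#unique x) per evaluation
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    ysum = np.bincount(inv, weights=y)
    yss = float(np.dot(y, y))

    # --- phase 1: zooming grid search (sigma ascending so that RSS ties
    # resolve to the smaller sigma via argmin-first) ---
    if fix_mu is not None:
        mu_c, mu_h = fix_mu, 0.0
        n_mu = 1
    else:
        mu_c, mu_h = 0.5 * (mu_b[0] + mu_b[1]), 0.5 * (mu_b[1] - mu_b[0])
        n_mu = 9
    sig_grid = np.geomspace(sig_b[0], sig_b[1], 12)
    mu_grid = np.linspace(mu_c - mu_h, mu_c + mu_h, n_mu)
    best_mu, best_sig = mu_grid[0], sig_grid[0]
    for stage in range(4):
        MU, SIG = np.meshgrid(mu_grid, sig_grid, indexing="ij")
        rss, _ = _rss_grid(MU.ravel(), SIG.ravel(), ux, counts, ysum, yss)
        k = int(np.argmin(rss))
        best_mu, best_sig = float(MU.ravel()[k]), float(SIG.ravel()[k])
        if stage == 0:
            top = np.argsort(rss, kind="stable")[: max(n_starts, 1)]
            candidates = list(zip(MU.ravel()[top], SIG.ravel()[top]))
        # zoom in around the incumbent
        mu_step = (mu_grid[1] - mu_grid[0]) if mu_grid.size > 1 else 0.0
        sig_lo = max(best_sig / (sig_grid[1] / sig_grid[0]), sig_b[0])
        sig_hi = min(best_sig * (sig_grid[1] / sig_grid[0]), sig_b[1])
        mu_grid = np.clip(np.linspace(best_mu - mu_step, best_mu + mu_step, max(n_mu // 2 + 1, 1)), *mu_b) \
            if n_mu > 1 else mu_grid
        sig_grid = np.geomspace(sig_lo, sig_hi, 7)

    # --- phase 2: local polish with analytic gradient ---
    incumbent = (best_mu, best_sig)
    n_polish = max(n_starts, 0)
    converged = True
    if n_polish > 0:
        starts = [incumbent] + candidates
        if x0 is not None:
            starts.append((float(np.clip(x0.mu, *mu_b)), float(np.clip(x0.sigma, *sig_b))))
        best_fun, best_theta, any_ok = np.inf, incumbent, False
        seen = set()
        for mu0, sig0 in starts[: n_polish + 2]:
            key = (round(mu0, 3), round(sig0, 3))
            if key in seen:
                continue
            seen.add(key)
            theta0 = [sig0] if fix_mu is not None else [mu0, sig0]
            res = optimize.minimize(
                _rss_and_grad, np.asarray(theta0),
                args=(ux, counts, ysum, yss, fix_mu),
                jac=True, method="L-BFGS-B",
                bounds=[sig_b] if fix_mu is not None else [mu_b, sig_b],
            )
            if not res.success:
                continue
            any_ok = True
            sig_here = float(res.x[-1])
            if res.fun < best_fun - 1e-12 or (
                abs(res.fun - best_fun) <= 1e-12 and sig_here < best_theta[1]
            ):
                best_fun = float(res.fun)
                best_theta = (
                    (fix_mu, sig_here) if fix_mu is not None else (float(res.x[0]), sig_here)
                )
        if any_ok and best_fun <= _rss_grid(
            np.array([incumbent[0]]), np.array([incumbent[1]]), ux, counts, ysum, yss
        )[0][0] + 1e-12:
            incumbent = best_theta
        converged = any_ok

    mu, sigma = incumbent
    rss_arr, alpha_arr = _rss_grid(
        np.array([mu]), np.array([sigma]), ux, counts, ysum, yss
    )
    alpha = float(np.clip(alpha_arr[0], *alpha_b))
    params = DoGParams(mu=float(mu), sigma=float(sigma), alpha=alpha)
    return DoGFit(
        params=params,
        half_amplitude=half_amplitude(params, domain_half) if converged else float("nan"),
        rss=float(rss_arr[0]),
        n_points=int(x.size),
        converged=converged,
        n_starts_used=n_polish,
    )
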