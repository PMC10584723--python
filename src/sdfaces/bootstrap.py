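"""Resampling-based confidence intervals and significance flags.

Uncertainty on half-amplitudes and categorical indices is quantified by
resampling trials with replacement (10,000 iterations by default),
recomputing the statistic on each resample, and reading the 95% interval
off the resulting distribution. Percentile intervals are the default for
curve-fit statistics; the bias-corrected and accelerated (BCa) variant is
available and is the default for the categorical index. A statistic is
declared significant when its interval excludes zero.

The resampling unit is the trial, matching analyses that pool trials across
participants; a participant-level (cluster) bootstrap is available via
``resample_unit="participant"`` with a group label per trial. Resample
statistics that fail (return NaN — e.g. a non-converged curve fit) are
counted and excluded from the quantiles; more than 20% failures aborts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = ["BootstrapResult", "bootstrap_statistic"]


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with a bootstrap confidence interval."""

    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    method: str
    significant: bool
    seed: int
    n_failed_fits: int
    distribution: np.ndarray | None = None

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _take(data, idx):
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    if isinstance(data, tuple):
        return tuple(np.asarray(a)[idx] for a in data)
    return np.asarray(data)[idx]


def _n_units(data) -> int:
    if isinstance(data, tuple):
        lengths = {len(a) for a in data}
        if len(lengths) != 1:
            raise ValueError("all arrays in data must have equal length")
        return lengths.pop()
    return len(data)


def _bca_interval(stats: np.ndarray, theta_hat: float, jack: np.ndarray, level: float):
    """BCa interval from the bootstrap distribution and jackknife values."""
    n_b = stats.size
    below = np.sum(stats < theta_hat) + 0.5 * np.sum(stats == theta_hat)
    p0 = below / n_b
    if p0 <= 0.0 or p0 >= 1.0:
        return None  # bias correction degenerate; caller falls back to percentile
    z0 = ndtri(p0)
    d = jack.mean() - jack
    denom = np.sum(d * d) ** 1.5
    a = np.sum(d**3) / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for q in ((1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0):
        z = ndtri(q)
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(stats, float(ndtr(adj)))))
    return out[0], out[1]


def bootstrap_statistic(
    data,
    statistic_fn,
    n_boot: int = 10_000,
    method: str = "percentile",
    seed: int = 0,
    *,
    level: float = 0.95,
    resample_unit: str = "trial",
    groups=None,
    max_fail_frac: float = 0.2,
    keep_distribution: bool = False,
) -> BootstrapResult:
    """Bootstrap a scalar statistic of a trial set.

    Parameters
    ----------
    data
        A DataFrame of trials or a tuple of equal-length arrays (e.g.
        ``(x, y)`` pairs); rows are resampled together.
    statistic_fn
        Maps a resampled ``data``-like object to a scalar; NaN marks a
        failed evaluation.
    n_boot
        Number of resamples (>= 100).
    method
        ``"percentile"`` or ``"bca"``. BCa adds a leave-one-unit-out
        jackknife pass for the acceleration constant, so it suits cheap
        statistics; it falls back to percentile when the bias correction is
        degenerate (e.g. a constant bootstrap distribution).
    seed
        Seeds an independent generator; same seed, same interval.
    resample_unit
        ``"trial"`` (rows) or ``"participant"`` (clusters given by
        ``groups``, a label per row).
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if method not in ("percentile", "bca"):
        raise ValueError(f"unknown CI method {method!r}")
    n = _n_units(data)
    if n == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)

    if resample_unit == "participant":
        if groups is None:
            raise ValueError("participant-level bootstrap requires groups")
        labels = np.asarray(groups)
        if labels.shape[0] != n:
            raise ValueError("groups must label every row")
        uniq = np.unique(labels)
        members = [np.flatnonzero(labels == u) for u in uniq]
        n_u = len(uniq)

        def draw():
            picks = rng.integers(0, n_u, n_u)
            return np.concatenate([members[p] for p in picks])

        jack_sets = [np.flatnonzero(labels != u) for u in uniq]
    elif resample_unit == "trial":
        def draw():
            return rng.integers(0, n, n)

        jack_sets = None  # built lazily below
    else:
        raise ValueError(f"unknown resample_unit {resample_unit!r}")

    theta_hat = float(statistic_fn(data))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = statistic_fn(_take(data, draw()))

    failed = int(np.sum(np.isnan(stats)))
    if failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"statistic failed on {failed}/{n_boot} resamples "
            f"(> {max_fail_frac:.0%}); data too unstable to bootstrap"
        )
    valid = stats[~np.isnan(stats)]

    alpha = (1.0 - level) / 2.0
    ci = None
    used = method
    if method == "bca":
        if jack_sets is None:
            all_idx = np.arange(n)
            jack_sets = [np.delete(all_idx, i) for i in range(n)]
        jack = np.array([statistic_fn(_take(data, s)) for s in jack_sets])
        jack = jack[~np.isnan(jack)]
        ci = _bca_interval(valid, theta_hat, jack, level) if jack.size >= 2 else None
        if ci is None:
            used = "percentile"
    if ci is None:
        ci = (float(np.quantile(valid, alpha)), float(np.quantile(valid, 1.0 - alpha)))

    lo, hi = ci
    return BootstrapResult(
        point_estimate=theta_hat,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        method=used,
        significant=bool(lo > 0.0 or hi < 0.0),
        seed=seed,
        n_failed_fits=failed,
        distribution=valid if keep_distribution else None,
    )
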