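"""Categorical classification-error index of serial dependence.

The morph wheel is partitioned into three prototype categories. A response
that lands outside the target's category is a classification error. For a
purely parametric-model-free read-out of attraction toward the inducer,
errors are partitioned by the inducer's category and, within each
partition, the proportion of errors landing in the inducer's own category
is computed. Averaging the three proportions and subtracting the 33.33%
chance baseline gives an index that is zero under independence, positive
when responses are pulled toward the inducer's category, and negative when
pushed away.

The per-partition (conditional) denominator is used because it is the
reading under which the 33.33% baseline is exact when target, inducer and
response are independent and uniform on the wheel; a grand-total
denominator is available for sensitivity analysis. Classification accuracy
(response category = target category) is reported alongside, with a
bootstrap SD as its dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_statistic
from .morphspace import MorphWheel, category_of

__all__ = [
    "CHANCE_BASELINE_PCT",
    "CategoricalIndexResult",
    "categorical_index",
    "classification_accuracy",
]

CHANCE_BASELINE_PCT = 33.33  # the subtracted chance level, as conventionally printed


@dataclass(frozen=True)
class CategoricalIndexResult:
    """Baseline-subtracted classification-error index for one condition."""

    per_category_ratio: tuple[float, float, float]
    mean_ratio_pct: float
    index_pct: float
    ci_low: float
    ci_high: float
    significant: bool
    n_trials: int
    n_errors: int
    accuracy_pct: float
    accuracy_sd: float
    estimable: bool
    n_defined_categories: int


def _categories(trials: pd.DataFrame, wheel: MorphWheel):
    ct = category_of(trials["target"].to_numpy(dtype=int), wheel)
    ci = category_of(trials["inducer"].to_numpy(dtype=int), wheel)
    cr = category_of(trials["response"].to_numpy(dtype=int), wheel)
    return ct, ci, cr


def _mean_ratio_pct(cat_t, cat_i, cat_r, denominator: str) -> float:
    """Mean (over inducer categories) error ratio, in percent; NaN if no
    category has errors."""
    err = cat_r != cat_t
    total_err = int(err.sum())
    ratios = np.full(3, np.nan)
    for k, c in enumerate((1, 2, 3)):
        part = err & (cat_i == c)
        hits = int(np.sum(part & (cat_r == c)))
        if denominator == "partition":
            denom = int(part.sum())
        elif denominator == "grand":
            denom = total_err
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        if denom > 0:
            ratios[k] = hits / denom
    if np.all(np.isnan(ratios)):
        return float("nan")
    return float(np.nanmean(ratios) * 100.0)


def categorical_index(
    trials: pd.DataFrame,
    wheel: MorphWheel,
    *,
    n_boot: int = 10_000,
    method: str = "bca",
    seed: int = 0,
    denominator: str = "partition",
    include_shared_category: bool = True,
    compute_ci: bool = True,
    accuracy_n_boot: int = 1_000,
) -> CategoricalIndexResult:
    """Compute the classification-error index for one set of trials.

    Parameters
    ----------
    trials
        Filtered derived trials (columns ``target``, ``inducer``,
        ``response``).
    denominator
        ``"partition"`` (default; chance = 33.33%) or ``"grand"``.
    include_shared_category
        Keep trials whose inducer and target share a category (default; the
        chance baseline holds with them included). Set False to drop them.
    compute_ci
        Bootstrap a CI for the index (trial-level resampling).
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    cat_t, cat_i, cat_r = _categories(trials, wheel)
    if not include_shared_category:
        keep = cat_t != cat_i
        cat_t, cat_i, cat_r = cat_t[keep], cat_i[keep], cat_r[keep]
        if cat_t.size == 0:
            raise ValueError("no trials left after dropping shared-category trials")

    err = cat_r != cat_t
    n = int(cat_t.size)
    n_errors = int(err.sum())
    accuracy_pct = 100.0 * (n - n_errors) / n

    ratios = np.full(3, np.nan)
    for k, c in enumerate((1, 2, 3)):
        part = err & (cat_i == c)
        hits = int(np.sum(part & (cat_r == c)))
        denom = int(part.sum()) if denominator == "partition" else n_errors
        if denom > 0:
            ratios[k] = hits / denom
    n_defined = int(np.sum(~np.isnan(ratios)))
    estimable = n_defined > 0
    mean_ratio_pct = float(np.nanmean(ratios) * 100.0) if estimable else float("nan")
    index_pct = mean_ratio_pct - CHANCE_BASELINE_PCT if estimable else float("nan")

    ci_low = ci_high = float("nan")
    significant = False
    if compute_ci and estimable:
        data = (cat_t, cat_i, cat_r)

        def stat(d):
            m = _mean_ratio_pct(*d, denominator)
            return m - CHANCE_BASELINE_PCT

        res = bootstrap_statistic(data, stat, n_boot=n_boot, method=method, seed=seed)
        ci_low, ci_high, significant = res.ci_low, res.ci_high, res.significant

    # dispersion of accuracy across bootstrap resamples
    rng = np.random.default_rng(seed + 1)
    acc_means = rng.binomial(n, (n - n_errors) / n, size=accuracy_n_boot) / n
    accuracy_sd = float(100.0 * acc_means.std(ddof=1))

    return CategoricalIndexResult(
        per_category_ratio=tuple(float(r) for r in ratios),
        mean_ratio_pct=mean_ratio_pct,
        index_pct=index_pct,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        n_trials=n,
        n_errors=n_errors,
        accuracy_pct=accuracy_pct,
        accuracy_sd=accuracy_sd,
        estimable=estimable,
        n_defined_categories=n_defined,
    )


def classification_accuracy(
    trials: pd.DataFrame,
    wheel: MorphWheel,
    *,
    n_boot: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percent of trials whose response falls in the target's category,
    with a bootstrap-resample SD as dispersion."""
    if len(trials) == 0:
        raise ValueError("empty trial set")
    cat_t, _, cat_r = _categories(trials, wheel)
    n = cat_t.size
    p = float(np.mean(cat_r == cat_t))
    rng = np.random.default_rng(seed)
    resampled = rng.binomial(n, p, size=n_boot) / n
    return 100.0 * p, float(100.0 * resampled.std(ddof=1))
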