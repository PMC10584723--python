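"""End-to-end analysis: derive -> filter -> group -> fit -> bootstrap -> index.

`run_analysis` reproduces the full report structure of a two-face
continuous-report study: per design cell it fits the within-trial DoG bias
curve with a bootstrap CI on its half-amplitude, repeats the fit for the
three across-trial predictor variants (previous trial's Face 2, Face 1, and
response), and computes the categorical classification-error index with its
own CI and the classification accuracy. Cells with too few trials are
reported non-estimable rather than failing the run.

Everything is deterministic given the config seed: per-(cell, variant)
bootstrap seeds are spawned from one `numpy` SeedSequence so that adding or
reordering cells never perturbs another cell's resamples.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_statistic
from .dog_model import PredictorVariant, build_predictor, fit_dog
from .morphspace import MorphWheel, build_wheel
from .nonparametric import categorical_index
from .preprocessing import (
    condition_keys,
    derive_trials,
    filter_trials,
    group_by_condition,
    read_trials,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "moving_average"]

log = logging.getLogger("sdfaces")

_VARIANTS = [
    PredictorVariant.within_trial,
    PredictorVariant.prev_face2,
    PredictorVariant.prev_face1,
    PredictorVariant.prev_response,
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis run (defaults follow the published procedure)."""

    n_boot: int = 10_000
    dog_ci_method: str = "percentile"
    index_ci_method: str = "bca"
    seed: int = 0
    n_starts: int = 3           # polish starts for the point fit
    boot_n_starts: int = 0      # 0 = grid-only bootstrap refits (fast)
    min_fit_n: int = 10
    fix_mu: float | None = None
    bounds: dict | None = None
    binned_means: bool = False  # fit per-x mean errors instead of raw trials
    bonferroni: bool = False    # widen CIs to level 1 - 0.05/n_cells
    resample_unit: str = "trial"
    variants: tuple = tuple(v.value for v in _VARIANTS)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load analysis settings from a YAML or JSON file."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All per-condition results of one run."""

    experiment: int
    removal_fraction: float
    dog_within: pd.DataFrame
    across_trial: pd.DataFrame
    categorical: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dog_within.to_csv(out / "dog_fits.csv", index=False)
        self.across_trial.to_csv(out / "across_trial.csv", index=False)
        self.categorical.to_csv(out / "categorical.csv", index=False)
        with open(out / "run.json", "w") as fh:
            json.dump(self.meta | {"removal_fraction": self.removal_fraction}, fh, indent=2)


def _spawn_seed(root: np.random.SeedSequence, *key: int) -> int:
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


def _seed_table(config_seed: int, n_cells: int, n_variants: int):
    """Stable per-(cell, variant[, index]) bootstrap seeds."""
    root = np.random.SeedSequence(config_seed)
    children = root.spawn(n_cells * (n_variants + 1))
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _fit_with_ci(x, y, cfg: AnalysisConfig, seed: int, level: float, groups=None):
    """Point DoG fit plus bootstrap CI on its half-amplitude."""
    point = fit_dog(
        x, y,
        bounds=cfg.bounds, n_starts=cfg.n_starts,
        fix_mu=cfg.fix_mu, min_n=cfg.min_fit_n,
    )

    def stat(d):
        xb, yb = d
        try:
            f = fit_dog(
                xb, yb,
                bounds=cfg.bounds, n_starts=cfg.boot_n_starts,
                fix_mu=cfg.fix_mu, min_n=cfg.min_fit_n,
                x0=point.params if point.converged else None,
            )
        except ValueError:
            return float("nan")
        return f.half_amplitude if f.converged else float("nan")

    boot = bootstrap_statistic(
        (np.asarray(x), np.asarray(y)),
        stat,
        n_boot=cfg.n_boot,
        method=cfg.dog_ci_method,
        seed=seed,
        level=level,
        resample_unit=cfg.resample_unit,
        groups=groups,
    )
    return point, boot


def _nonestimable_row(key, variant, n) -> dict:
    return {
        "condition": str(key), "variant": variant, "n": n,
        "mu": np.nan, "sigma": np.nan, "alpha": np.nan,
        "half_amplitude": np.nan, "rss": np.nan, "converged": False,
        "ci_low": np.nan, "ci_high": np.nan, "significant": False,
        "n_failed_fits": 0, "estimable": False,
    }


def _binned(x, y):
    ux, inv = np.unique(x, return_inverse=True)
    ymean = np.bincount(inv, weights=np.asarray(y, dtype=float)) / np.bincount(inv)
    return ux, ymean


def run_analysis(
    trials,
    experiment: int,
    config: AnalysisConfig | None = None,
    wheel: MorphWheel | None = None,
    out_dir=None,
) -> AnalysisReport:
    """Run the complete serial-dependence analysis on a trial table.

    Parameters
    ----------
    trials
        Raw trial table (DataFrame) or path to a trial CSV.
    experiment
        1 (single-target, ISI x delay design) or 2 (postcued target).
    config
        :class:`AnalysisConfig`; defaults follow the published procedure
        (n_boot=10,000 — pass a smaller value for quick runs).
    out_dir
        If given, write `dog_fits.csv`, `across_trial.csv`,
        `categorical.csv` and `run.json` there.
    """
    cfg = config or AnalysisConfig()
    wheel = wheel or build_wheel()
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)

    t0 = time.time()
    derived = derive_trials(trials, wheel, experiment)
    kept, removal_fraction = filter_trials(derived)
    for _, row in derived[derived["excluded"]].iterrows():
        log.info(
            "excluded %s/%s trial %s (%s)",
            row["participant"], row["session"], row["trial"], row["exclude_reason"],
        )

    keys = condition_keys(experiment)
    level = 1.0 - (0.05 / len(keys) if cfg.bonferroni else 0.05)
    key_cols = ("isi_s", "delay_s") if experiment == 1 else ("postcue", "delay_s")

    root = np.random.SeedSequence(cfg.seed)
    seeds = {}
    children = root.spawn(len(keys) * (len(_VARIANTS) + 1))
    it = iter(children)
    for k in keys:
        for v in _VARIANTS:
            seeds[(k, v.value)] = int(next(it).generate_state(1)[0] % (2**31))
        seeds[(k, "categorical")] = int(next(it).generate_state(1)[0] % (2**31))

    # predictor pairs over full sessions (across-trial variants may cross
    # condition boundaries), then sliced per condition of the current trial
    dog_rows, across_rows, cat_rows = [], [], []
    variant_frames = {}
    for v in _VARIANTS:
        if v.value not in cfg.variants:
            continue
        x, y, frame = build_predictor(derived, v, wheel, return_frame=True)
        variant_frames[v] = (x, y, frame)

    groups_kept = group_by_condition(kept, experiment)
    for key in keys:
        cond_mask_cache = None
        for v in _VARIANTS:
            if v not in variant_frames:
                continue
            x_all, y_all, frame = variant_frames[v]
            sel = (frame[key_cols[0]].to_numpy() == key[0]) & (
                frame[key_cols[1]].to_numpy() == key[1]
            )
            x, y = x_all[sel], y_all[sel]
            target_rows = dog_rows if v is PredictorVariant.within_trial else across_rows
            if x.size < cfg.min_fit_n or np.all(x == x[:1]):
                log.warning("condition %s / %s non-estimable (n=%d)", key, v.value, x.size)
                target_rows.append(_nonestimable_row(key, v.value, int(x.size)))
                continue
            grp = None
            if cfg.resample_unit == "participant":
                grp = frame["participant"].to_numpy()[sel]
            point, boot = _fit_with_ci(x, y, cfg, seeds[(key, v.value)], level, groups=grp)
            if cfg.binned_means:
                xb, yb = _binned(x, y)
                point = fit_dog(xb, yb, bounds=cfg.bounds, n_starts=cfg.n_starts,
                                fix_mu=cfg.fix_mu, min_n=min(cfg.min_fit_n, xb.size))
            target_rows.append({
                "condition": str(key), "variant": v.value, "n": int(x.size),
                "mu": point.params.mu, "sigma": point.params.sigma,
                "alpha": point.params.alpha,
                "half_amplitude": point.half_amplitude, "rss": point.rss,
                "converged": point.converged,
                "ci_low": boot.ci_low, "ci_high": boot.ci_high,
                "significant": boot.significant,
                "n_failed_fits": boot.n_failed_fits, "estimable": True,
            })

        sub = groups_kept[key]
        if len(sub) == 0:
            log.warning("condition %s empty; categorical index non-estimable", key)
            cat_rows.append({
                "condition": str(key), "n": 0, "n_errors": 0,
                "ratio_cat1": np.nan, "ratio_cat2": np.nan, "ratio_cat3": np.nan,
                "index_pct": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "significant": False, "accuracy_pct": np.nan, "accuracy_sd": np.nan,
                "estimable": False,
            })
        else:
            res = categorical_index(
                sub, wheel,
                n_boot=cfg.n_boot, method=cfg.index_ci_method,
                seed=seeds[(key, "categorical")],
            )
            cat_rows.append({
                "condition": str(key), "n": res.n_trials, "n_errors": res.n_errors,
                "ratio_cat1": res.per_category_ratio[0],
                "ratio_cat2": res.per_category_ratio[1],
                "ratio_cat3": res.per_category_ratio[2],
                "index_pct": res.index_pct,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "significant": res.significant,
                "accuracy_pct": res.accuracy_pct, "accuracy_sd": res.accuracy_sd,
                "estimable": res.estimable,
            })

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    report = AnalysisReport(
        experiment=experiment,
        removal_fraction=removal_fraction,
        dog_within=pd.DataFrame(dog_rows),
        across_trial=pd.DataFrame(across_rows),
        categorical=pd.DataFrame(cat_rows),
        meta={
            "experiment": experiment,
            "seed": cfg.seed,
            "n_boot": cfg.n_boot,
            "config_hash": cfg_hash,
            "n_trials": int(len(trials)),
            "n_kept": int(len(kept)),
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def moving_average(x, y, window: int = 15):
    """Centred moving average of y over x-windows of ``window`` morph steps.

    Diagnostic smoother plotted against the DoG fit. Returns
    ``(grid, smoothed)`` where grid is the sorted unique x values; windows
    are truncated at the domain edges.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    half = window // 2
    grid = np.unique(x)
    smoothed = np.empty_like(grid, dtype=float)
    for i, g in enumerate(grid):
        m = np.abs(x - g) <= half
        smoothed[i] = y[m].mean()
    return grid, smoothed
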