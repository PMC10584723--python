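"""Trial-table ingestion, error derivation, exclusion and grouping.

Trial tables are pandas DataFrames with the CSV schema

    participant,session,trial,isi_s,delay_s,face1,face2,postcue,response,rt_s

(`postcue` empty for the single-target experiment 1). Derivation resolves
which face is the reproduction target and which the inducer, computes the
signed circular adjustment error (target -> response) and inducer-target
difference (target -> inducer), and flags lapse trials: responses slower
than 15 s or errors beyond +/-60 morph steps are treated as attentional
lapses and excluded from analysis. Both thresholds are strict — a trial at
exactly 15.0 s or exactly +/-60 steps is kept.

Experiment 1 always probes Face 2 (target = Face 2, inducer = Face 1);
experiment 2 resolves the roles from the postcue (postcue 1 -> reproduce
Face 1, Face 2 becomes the inducer). Analyses pool trials across
participants, and group them into the design cells: ISI x response delay
(20 cells) for experiment 1, postcue x delay (6 cells) for experiment 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .morphspace import MorphWheel, signed_distance

__all__ = [
    "EXP1_ISI_LEVELS",
    "EXP1_DELAY_LEVELS",
    "EXP2_DELAY_LEVELS",
    "EXP2_POSTCUE_LEVELS",
    "RT_LIMIT_S",
    "ERROR_LIMIT_STEPS",
    "TRIAL_COLUMNS",
    "condition_keys",
    "read_trials",
    "write_trials",
    "derive_trials",
    "filter_trials",
    "group_by_condition",
]

EXP1_ISI_LEVELS = (1, 3, 6, 10)
EXP1_DELAY_LEVELS = (0, 1, 3, 6, 10)
EXP2_DELAY_LEVELS = (1, 3, 6)
EXP2_POSTCUE_LEVELS = (1, 2)

RT_LIMIT_S = 15.0       # strict: rt > 15 s excluded
ERROR_LIMIT_STEPS = 60  # strict: |error| > 60 steps excluded

TRIAL_COLUMNS = [
    "participant", "session", "trial", "isi_s", "delay_s",
    "face1", "face2", "postcue", "response", "rt_s",
]

DERIVED_COLUMNS = TRIAL_COLUMNS + [
    "target", "inducer", "error", "delta", "excluded", "exclude_reason",
]


def condition_keys(experiment: int) -> list[tuple]:
    """All design-cell keys for an experiment, in canonical order.

    Experiment 1: ``(isi_s, delay_s)`` over 4 ISIs x 5 delays = 20 cells.
    Experiment 2: ``(postcue, delay_s)`` over 2 postcues x 3 delays = 6 cells.
    """
    if experiment == 1:
        return [(i, d) for i in EXP1_ISI_LEVELS for d in EXP1_DELAY_LEVELS]
    if experiment == 2:
        return [(p, d) for p in EXP2_POSTCUE_LEVELS for d in EXP2_DELAY_LEVELS]
    raise ValueError(f"experiment must be 1 or 2, got {experiment}")


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV, ignoring (and warning about) unknown columns."""
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in DERIVED_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown trial columns: {unknown}")
        df = df.drop(columns=unknown)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a (raw or derived) trial table to CSV."""
    cols = [c for c in DERIVED_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def _validate(records: pd.DataFrame, wheel: MorphWheel, experiment: int) -> None:
    n = wheel.n_positions
    for col in ("face1", "face2", "response"):
        vals = records[col].to_numpy()
        if np.any((vals < 0) | (vals >= n)):
            raise ValueError(f"column {col!r} has wheel indices outside [0, {n})")
    if np.any(records["rt_s"].to_numpy() <= 0):
        raise ValueError("rt_s must be positive")

    if experiment == 1:
        if "postcue" in records and records["postcue"].notna().any():
            raise ValueError("experiment 1 trials must not carry a postcue")
        isi_ok = records["isi_s"].isin(EXP1_ISI_LEVELS)
        delay_ok = records["delay_s"].isin(EXP1_DELAY_LEVELS)
    else:
        if "postcue" not in records or records["postcue"].isna().any():
            raise ValueError("experiment 2 trials require a postcue on every trial")
        if not records["postcue"].isin(EXP2_POSTCUE_LEVELS).all():
            raise ValueError("postcue must be 1 or 2")
        isi_ok = pd.Series(True, index=records.index)
        delay_ok = records["delay_s"].isin(EXP2_DELAY_LEVELS)
    if not isi_ok.all():
        raise ValueError("isi_s outside the experiment's level set")
    if not delay_ok.all():
        raise ValueError("delay_s outside the experiment's level set")

    for (_, _), sess in records.groupby(["participant", "session"], sort=False):
        t = sess["trial"].to_numpy()
        if np.any(np.diff(np.sort(t)) < 1) or np.any(t < 1):
            raise ValueError("trial indices must be >= 1 and unique within a session")


def derive_trials(records: pd.DataFrame, wheel: MorphWheel, experiment: int) -> pd.DataFrame:
    """Resolve target/inducer roles and derive errors and exclusion flags.

    Adds columns: ``target``, ``inducer`` (wheel indices), ``error`` (signed
    steps target -> response), ``delta`` (signed steps target -> inducer),
    ``excluded`` (bool) and ``exclude_reason`` (``""``, ``"rt"``, ``"error"``
    or ``"rt+error"``). Rows are sorted by participant, session, trial.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    if len(records) == 0:
        raise ValueError("empty trial table")
    _validate(records, wheel, experiment)

    df = records.sort_values(["participant", "session", "trial"], kind="stable").copy()
    face1 = df["face1"].to_numpy(dtype=int)
    face2 = df["face2"].to_numpy(dtype=int)
    if experiment == 1:
        target, inducer = face2, face1
    else:
        cue1 = df["postcue"].to_numpy(dtype=int) == 1
        target = np.where(cue1, face1, face2)
        inducer = np.where(cue1, face2, face1)

    response = df["response"].to_numpy(dtype=int)
    error = signed_distance(target, response, wheel)
    delta = signed_distance(target, inducer, wheel)

    rt_bad = df["rt_s"].to_numpy() > RT_LIMIT_S
    err_bad = np.abs(error) > ERROR_LIMIT_STEPS
    reason = np.where(
        rt_bad & err_bad, "rt+error",
        np.where(rt_bad, "rt", np.where(err_bad, "error", "")),
    )

    df["target"] = target
    df["inducer"] = inducer
    df["error"] = error
    df["delta"] = delta
    df["excluded"] = rt_bad | err_bad
    df["exclude_reason"] = reason
    return df


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop excluded trials; return (kept, removal_fraction).

    A trial failing both criteria counts once toward the fraction.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    kept = trials[~trials["excluded"]]
    return kept, float(1.0 - len(kept) / len(trials))


def _key_columns(experiment: int) -> tuple[str, str]:
    return ("isi_s", "delay_s") if experiment == 1 else ("postcue", "delay_s")


def group_by_condition(trials: pd.DataFrame, experiment: int) -> dict[tuple, pd.DataFrame]:
    """Split trials into the experiment's design cells.

    Every cell of the design appears in the result, empty cells included
    (they are reported non-estimable downstream rather than dropped).
    """
    c1, c2 = _key_columns(experiment)
    groups = {k: trials.iloc[0:0] for k in condition_keys(experiment)}
    for key, sub in trials.groupby([c1, c2], sort=False):
        key = (int(key[0]), int(key[1]))
        if key not in groups:
            raise ValueError(f"condition {key} outside the experiment {experiment} design")
        groups[key] = sub
    return groups
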