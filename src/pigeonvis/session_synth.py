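"""Synthetic recording sessions for the visual response-inhibition task.

The behavioural task presents 20 grayscale stimuli — 5 stimulus groupings
(human faces, scrambled human faces, pigeon faces, scrambled pigeon faces,
sine gratings) with 4 exemplars each — 8 times apiece in random order, for
160 completed trials per session.  Each trial runs through a 6 s inter-trial
interval (ITI, source of the baseline window), a response-inhibition pause
of random 2–4 s duration, and a stimulus period of random 1.5–3 s.

Simulated units are homogeneous Poisson spike generators whose rate in each
period is the unit's baseline rate scaled by a period gain.  A unit can be
excitatory (stimulus gain > 1), inhibitory (< 1) or non-responsive (= 1),
may carry extra pause-period modulation, and may be tuned to one stimulus
grouping at a chosen selectivity index (SI): planting inverts the SI
definition used in the single-unit analysis, so that the planted contrast
(preferred - other)/(preferred + other) equals the requested value in
expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "NeuronProfile",
    "TRIAL_COLUMNS",
    "plant_selectivity",
    "generate_session",
    "session_to_csv",
    "session_from_csv",
]

ResponseClass = Literal["excitatory", "inhibitory", "nonresponsive"]

#: Column schema of the per-neuron trial table.
TRIAL_COLUMNS = [
    "neuron_id",
    "trial_index",
    "image_id",
    "grouping",
    "pause_dur_s",
    "stim_dur_s",
    "rate_baseline_hz",
    "rate_pause_hz",
    "rate_stim_hz",
]


class ValidationError(ValueError):
    """Raised for malformed task configurations or neuron profiles."""


@dataclass(frozen=True)
class TaskConfig:
    """Structure of one experimental session.

    Defaults reproduce the study task: 5 groupings x 4 exemplars x 8
    presentations = 160 trials, pause drawn uniformly from [2, 4] s,
    stimulus from [1.5, 3] s, 6 s ITI, and 500 ms rate windows for the
    baseline and post-onset analysis.
    """

    n_groupings: int = 5
    n_exemplars: int = 4
    n_reps: int = 8
    iti_s: float = 6.0
    ready_pecks: int = 2
    pause_range_s: tuple[float, float] = (2.0, 4.0)
    stim_range_s: tuple[float, float] = (1.5, 3.0)
    analysis_window_s: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groupings, self.n_exemplars, self.n_reps) < 1:
            raise ValidationError("grouping/exemplar/repetition counts must be >= 1")
        for name in ("pause_range_s", "stim_range_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < low <= high")
        if self.iti_s <= 0 or self.analysis_window_s <= 0:
            raise ValidationError("durations must be strictly positive")
        if self.analysis_window_s > self.stim_range_s[0]:
            raise ValidationError(
                "analysis window cannot exceed the shortest stimulus duration"
            )

    @property
    def n_trials(self) -> int:
        return self.n_groupings * self.n_exemplars * self.n_reps

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        d = json.loads(text)
        for key in ("pause_range_s", "stim_range_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class NeuronProfile:
    """Generative description of one simulated unit.

    ``stim_gain`` multiplies the baseline rate during the stimulus window
    for non-preferred groupings; ``pause_gain`` does the same for the pause
    period.  When ``preferred_grouping`` is set, the preferred grouping's
    stimulus rate is solved from ``target_si`` (see :func:`plant_selectivity`).
    """

    neuron_id: str
    response_class: ResponseClass = "nonresponsive"
    baseline_rate_hz: float = 10.0
    stim_gain: float = 1.0
    preferred_grouping: int | None = None
    target_si: float = 0.0
    pause_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValidationError("baseline_rate_hz must be > 0")
        if self.pause_gain < 0 or self.stim_gain < 0:
            raise ValidationError("gains must be non-negative")
        if self.response_class == "excitatory" and not self.stim_gain > 1:
            raise ValidationError("excitatory profiles require stim_gain > 1")
        if self.response_class == "inhibitory" and not self.stim_gain < 1:
            raise ValidationError("inhibitory profiles require stim_gain < 1")
        if self.response_class == "nonresponsive" and self.stim_gain != 1:
            raise ValidationError("nonresponsive profiles require stim_gain = 1")
        if not (0.0 <= self.target_si < 1.0):
            raise ValidationError("target_si must lie in [0, 1)")


def plant_selectivity(profile: NeuronProfile) -> np.ndarray | tuple[float, float]:
    """Solve the preferred-grouping stimulus rate from the target SI.

    For an excitatory unit the SI contrast is
    ``(r_pref - r_other) / (r_pref + r_other)``, with
    ``r_other = baseline_rate_hz * stim_gain``; inverting gives
    ``r_pref = r_other * (1 + s) / (1 - s)``.  For an inhibitory unit the
    roles swap (the preferred grouping suppresses the rate further), giving
    ``r_pref = r_other * (1 - s) / (1 + s)``.

    Returns ``(r_pref, r_other)`` in spikes/s.
    """
    if profile.preferred_grouping is None:
        raise ValidationError("plant_selectivity requires preferred_grouping")
    s = profile.target_si
    if not (0.0 <= s < 1.0):
        raise ValidationError("target_si >= 1 is unreachable with positive rates")
    r_other = profile.baseline_rate_hz * profile.stim_gain
    if profile.response_class == "inhibitory":
        r_pref = r_other * (1.0 - s) / (1.0 + s)
    else:
        r_pref = r_other * (1.0 + s) / (1.0 - s)
    return r_pref, r_other


def _stimulus_rates(profile: NeuronProfile, n_groupings: int) -> np.ndarray:
    """Expected stimulus-window rate (spikes/s) for each grouping."""
    r_other = profile.baseline_rate_hz * profile.stim_gain
    rates = np.full(n_groupings, r_other, dtype=float)
    if profile.preferred_grouping is not None and profile.target_si > 0:
        if not (0 <= profile.preferred_grouping < n_groupings):
            raise ValidationError("preferred_grouping out of range")
        r_pref, _ = plant_selectivity(profile)
        rates[profile.preferred_grouping] = r_pref
    return rates


def _poisson_rate(
    rng: np.random.Generator, rate_hz: np.ndarray, window_s: np.ndarray | float
) -> np.ndarray:
    """Draw Poisson counts over a window and convert back to spikes/s."""
    lam = np.asarray(rate_hz, dtype=float) * np.asarray(window_s, dtype=float)
    return rng.poisson(lam) / np.asarray(window_s, dtype=float)


def generate_session(
    task: TaskConfig, neurons: Sequence[NeuronProfile]
) -> pd.DataFrame:
    """Simulate one session for every unit in ``neurons``.

    All units share the session's trial structure (stimulus order and period
    durations); spike counts are drawn independently per unit and period
    from a homogeneous Poisson law.  Rates are counts over the period window
    divided by the window length: the full pause duration for the pause
    rate, and the configured analysis window (default 0.5 s) for the
    baseline (taken inside the ITI) and post-onset stimulus rates.

    Deterministic given ``task.rng_seed`` and the profile list.  Returns a
    long-format :class:`pandas.DataFrame` with columns :data:`TRIAL_COLUMNS`.
    """
    if len(neurons) == 0:
        raise ValidationError("at least one neuron profile is required")
    rng = np.random.default_rng(task.rng_seed)
    n_trials = task.n_trials
    n_images = task.n_groupings * task.n_exemplars

    # image k belongs to grouping k // n_exemplars; each image shown n_reps times
    image_ids = np.repeat(np.arange(n_images), task.n_reps)
    order = rng.permutation(n_trials)
    image_ids = image_ids[order]
    groupings = image_ids // task.n_exemplars

    pause_dur = rng.uniform(*task.pause_range_s, size=n_trials)
    stim_dur = rng.uniform(*task.stim_range_s, size=n_trials)
    win = task.analysis_window_s

    frames = []
    for profile in neurons:
        grouping_rates = _stimulus_rates(profile, task.n_groupings)
        base = profile.baseline_rate_hz
        rate_baseline = _poisson_rate(rng, np.full(n_trials, base), win)
        rate_pause = _poisson_rate(
            rng, np.full(n_trials, base * profile.pause_gain), pause_dur
        )
        rate_stim = _poisson_rate(rng, grouping_rates[groupings], win)
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": profile.neuron_id,
                    "trial_index": np.arange(n_trials),
                    "image_id": image_ids,
                    "grouping": groupings,
                    "pause_dur_s": pause_dur,
                    "stim_dur_s": stim_dur,
                    "rate_baseline_hz": rate_baseline,
                    "rate_pause_hz": rate_pause,
                    "rate_stim_hz": rate_stim,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def session_to_csv(
    trials: pd.DataFrame, path, task: TaskConfig | None = None, meta_path=None
) -> None:
    """Write a session table as CSV, optionally with a JSON config sidecar."""
    trials.to_csv(path, index=False)
    if task is not None and meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write(task.to_json())


def session_from_csv(path) -> pd.DataFrame:
    """Read a session table, validating the column schema."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"session CSV missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]
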