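"""Visual responsiveness and pause-period activity classification.

A unit is called visually responsive when its firing rate in the 500 ms
window after stimulus onset differs from the rate in a 500 ms baseline
window of the preceding ITI, by a two-tailed paired t-test across trials
(p < alpha, default 0.05).  Responsive units are typed excitatory or
inhibitory by the sign of the mean stimulus-minus-baseline difference.
The same contract applied to the pause-period rate yields the pause
activity classification.

Population summaries normalise each unit's period rates as z-scores
against its own baseline distribution before averaging within response
classes, giving the characteristic excitatory / inhibitory / flat period
time courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .session_synth import ValidationError

__all__ = [
    "ResponsivenessResult",
    "classify_visual_responsiveness",
    "classify_pause_activity",
    "classify_session",
    "normalized_timecourse",
]

logger = logging.getLogger(__name__)

Sign = Literal["excitatory", "inhibitory", "none"]

PERIOD_COLUMNS = {
    "baseline": "rate_baseline_hz",
    "pause": "rate_pause_hz",
    "stimulus": "rate_stim_hz",
}


@dataclass(frozen=True)
class ResponsivenessResult:
    neuron_id: str
    visually_responsive: bool
    response_sign: Sign
    pause_active: bool
    pause_sign: Sign
    t_statistic: float
    p_value: float
    pause_t_statistic: float
    pause_p_value: float
    n_trials: int


def _paired_test(a: np.ndarray, b: np.ndarray, alpha: float) -> tuple[bool, Sign, float, float]:
    """Two-tailed paired t-test of a vs b; sign from the mean difference.

    Zero variance of the differences with zero mean difference is a
    degenerate no-effect case and reports p = 1.
    """
    if len(a) < 2 or len(a) != len(b):
        raise ValidationError("paired test needs >= 2 complete trial pairs")
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return False, "none", 0.0, 1.0
        # constant nonzero difference: infinitely strong effect
        t = np.inf if diff.mean() > 0 else -np.inf
        return True, "excitatory" if diff.mean() > 0 else "inhibitory", t, 0.0
    t, p = stats.ttest_rel(a, b)
    if p < alpha:
        return True, "excitatory" if diff.mean() > 0 else "inhibitory", float(t), float(p)
    return False, "none", float(t), float(p)


def classify_visual_responsiveness(
    trials: pd.DataFrame, alpha: float = 0.05
) -> ResponsivenessResult:
    """Classify one unit's trial table (visual + pause classification)."""
    ids = trials["neuron_id"].unique()
    if len(ids) != 1:
        raise ValidationError("expected a single neuron's trial table")
    stim = trials["rate_stim_hz"].to_numpy()
    base = trials["rate_baseline_hz"].to_numpy()
    pause = trials["rate_pause_hz"].to_numpy()
    responsive, sign, t, p = _paired_test(stim, base, alpha)
    p_active, p_sign, pt, pp = _paired_test(pause, base, alpha)
    return ResponsivenessResult(
        neuron_id=str(ids[0]),
        visually_responsive=responsive,
        response_sign=sign,
        pause_active=p_active,
        pause_sign=p_sign,
        t_statistic=t,
        p_value=p,
        pause_t_statistic=pt,
        pause_p_value=pp,
        n_trials=len(trials),
    )


def classify_pause_activity(
    trials: pd.DataFrame, alpha: float = 0.05
) -> tuple[bool, Sign, float, float]:
    """Pause-vs-baseline paired comparison for one unit.

    Returns ``(pause_active, pause_sign, t, p)``.
    """
    ids = trials["neuron_id"].unique()
    if len(ids) != 1:
        raise ValidationError("expected a single neuron's trial table")
    return _paired_test(
        trials["rate_pause_hz"].to_numpy(),
        trials["rate_baseline_hz"].to_numpy(),
        alpha,
    )


def classify_session(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify every unit in a session table; one row per unit."""
    rows = [
        classify_visual_responsiveness(sub, alpha)
        for _, sub in trials.groupby("neuron_id", sort=True)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def normalized_timecourse(
    trials: pd.DataFrame, classes: pd.DataFrame
) -> pd.DataFrame:
    """Class-average baseline-normalised rate for each task period.

    Each unit's mean rate per period is z-scored against that unit's
    baseline mean and standard deviation (across trials), then averaged
    within the excitatory / inhibitory / nonresponsive classes.  Units with
    zero baseline variance cannot be normalised and are excluded with a
    warning.

    ``classes`` is the output of :func:`classify_session`.  Returns a frame
    indexed by response class with one column per period and an ``n_neurons``
    count.
    """
    sign_of = classes.set_index("neuron_id")["response_sign"].to_dict()
    per_neuron = []
    for neuron_id, sub in trials.groupby("neuron_id", sort=True):
        base = sub["rate_baseline_hz"].to_numpy()
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            logger.warning("neuron %s: zero baseline variance, excluded", neuron_id)
            continue
        cls = sign_of.get(str(neuron_id), sign_of.get(neuron_id, "none"))
        label = cls if cls != "none" else "nonresponsive"
        per_neuron.append(
            {
                "response_class": label,
                "baseline": 0.0,
                "pause": (sub["rate_pause_hz"].mean() - mu) / sd,
                "stimulus": (sub["rate_stim_hz"].mean() - mu) / sd,
            }
        )
    if not per_neuron:
        raise ValidationError("no neuron with usable baseline variance")
    df = pd.DataFrame(per_neuron)
    out = df.groupby("response_class").mean()
    out["n_neurons"] = df.groupby("response_class").size()
    return out
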