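"""Stimulus-grouping selectivity: ANOVA, Tukey HSD, the selectivity index,
the chance-level simulation, and the scrambled-vs-original comparison.

A visually responsive unit is stimulus selective when a one-way ANOVA over
the stimulus-window rates of the five groupings is significant (p < alpha).
Selective units get a preferred grouping from Tukey HSD post-hoc pairwise
comparisons — the grouping whose mean rate deviates most from the unit's
baseline mean (largest increase for excitatory units, largest suppression
for inhibitory ones), required to take part in at least one significant
pair — and a selectivity index

    SI = (P - O) / (P + O)          (excitatory)
    SI = (O - P) / (O + P)          (inhibitory)

where P is the mean rate for the preferred grouping and O the mean of the
other groupings' mean rates.  SI = 0.33 corresponds to a 2:1 response
ratio.  The chance simulation replaces real rates with per-trial draws
uniform between each unit's min and max rate and re-runs the ANOVA,
estimating the fraction of units that would appear selective with no true
tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .session_synth import ValidationError

__all__ = [
    "SelectivityResult",
    "ChanceSimConfig",
    "anova_selectivity",
    "preferred_grouping",
    "tukey_significant_pairs",
    "selectivity_index",
    "analyze_session_selectivity",
    "chance_simulation",
    "scrambled_vs_original",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectivityResult:
    neuron_id: str
    anova_F: float
    anova_p: float
    selective: bool
    preferred_grouping: int | None = None
    si: float | None = None
    tukey_significant_pairs: tuple = ()


@dataclass(frozen=True)
class ChanceSimConfig:
    """Null simulation: per-trial rates uniform in [rate_min, rate_max].

    ``rate_min`` / ``rate_max`` may be scalars (shared by every simulated
    unit) or length-``n_neurons`` sequences of per-unit bounds, mirroring
    the per-unit min/max ranges of a recorded population.
    """

    n_neurons: int = 77
    rate_min: float | tuple = 0.0
    rate_max: float | tuple = 20.0
    n_groupings: int = 5
    trials_per_grouping: int = 32
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.trials_per_grouping < 2:
            raise ValidationError("need n_neurons >= 1, trials_per_grouping >= 2")
        lo = np.broadcast_to(np.asarray(self.rate_min, float), (self.n_neurons,))
        hi = np.broadcast_to(np.asarray(self.rate_max, float), (self.n_neurons,))
        if np.any(lo > hi) or np.any(lo < 0):
            raise ValidationError("need 0 <= rate_min <= rate_max per neuron")


def _grouping_rates(trials: pd.DataFrame) -> list[np.ndarray]:
    groups = [
        sub["rate_stim_hz"].to_numpy()
        for _, sub in trials.groupby("grouping", sort=True)
    ]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groupings with >= 2 trials each")
    return groups


def anova_selectivity(trials: pd.DataFrame, alpha: float = 0.05) -> SelectivityResult:
    """One-way fixed-effects ANOVA of stimulus-window rates by grouping."""
    groups = _grouping_rates(trials)
    if np.ptp(np.concatenate(groups)) == 0:
        return SelectivityResult(
            neuron_id=str(trials["neuron_id"].iloc[0]),
            anova_F=0.0, anova_p=1.0, selective=False,
        )
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # degenerate within-group variance
        f, p = 0.0, 1.0
    return SelectivityResult(
        neuron_id=str(trials["neuron_id"].iloc[0]),
        anova_F=float(f),
        anova_p=float(p),
        selective=bool(p < alpha),
    )


@lru_cache(maxsize=64)
def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_significant_pairs(groups: list[np.ndarray], alpha: float) -> list[tuple]:
    """Index pairs whose means differ by Tukey's HSD criterion.

    Uses the Tukey–Kramer statistic
    ``q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` against the
    studentized-range critical value with k groups and N - k degrees of
    freedom.  The critical value is cached per (alpha, k, df), which makes
    screening thousands of units cheap; it is the same decision rule as
    computing each pair's studentized-range p-value and thresholding.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / df
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            if msw == 0:
                if means[i] != means[j]:
                    pairs.append((i, j))
                continue
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            if q > _studentized_range_crit(alpha, k, df):
                pairs.append((i, j))
    return pairs


def preferred_grouping(
    trials: pd.DataFrame,
    anova_result: SelectivityResult,
    alpha: float = 0.05,
    sign: str = "excitatory",
) -> tuple[int | None, tuple]:
    """Tukey HSD post-hoc: find the preferred grouping of a selective unit.

    The candidate is the grouping whose mean stimulus rate deviates most
    from the unit's baseline mean — above it for excitatory units, below it
    for inhibitory ones.  The candidate must appear in at least one
    significant Tukey pair; otherwise preference is ambiguous and ``None``
    is returned with the (possibly empty) significant-pair list.
    """
    if not anova_result.selective:
        raise ValidationError("preferred_grouping requires a selective neuron")
    groups = _grouping_rates(trials)
    labels = sorted(trials["grouping"].unique())
    sig_pairs = tuple(
        (labels[i], labels[j]) for i, j in tukey_significant_pairs(groups, alpha)
    )
    baseline_mean = trials["rate_baseline_hz"].mean()
    means = np.array([g.mean() for g in groups])
    dev = means - baseline_mean
    if sign == "inhibitory":
        candidate = int(np.argmin(dev))
    else:
        candidate = int(np.argmax(dev))
    label = labels[candidate]
    if not any(label in pair for pair in sig_pairs):
        logger.info(
            "neuron %s: preferred grouping ambiguous (no significant Tukey pair)",
            trials["neuron_id"].iloc[0],
        )
        return None, sig_pairs
    return label, sig_pairs


def selectivity_index(
    pref_mean: float, other_means, sign: str = "excitatory"
) -> float:
    """Selectivity index from the preferred mean and the other means.

    Excitatory: (P - O) / (P + O); inhibitory: (O - P) / (O + P), where O
    is the mean of ``other_means``.  Clipped at 0 when the preferred
    direction is violated.  A 2:1 ratio gives SI = 1/3.
    """
    P = float(pref_mean)
    O = float(np.mean(other_means))
    if P < 0 or O < 0:
        raise ValidationError("rates must be non-negative")
    if P + O == 0:
        raise ValidationError("SI undefined when all rates are zero")
    si = (P - O) / (P + O)
    if sign == "inhibitory":
        si = -si
    return max(si, 0.0)


def analyze_session_selectivity(
    trials: pd.DataFrame,
    classes: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full single-unit selectivity analysis for a session.

    ``classes`` (from ``responsiveness.classify_session``) restricts the
    analysis to visually responsive units and supplies their response sign;
    without it every unit is analysed as excitatory.  Returns one row per
    analysed unit with ANOVA, preference and SI columns.
    """
    signs: dict = {}
    if classes is not None:
        responsive = classes[classes["visually_responsive"]]
        signs = responsive.set_index("neuron_id")["response_sign"].to_dict()
        trials = trials[trials["neuron_id"].astype(str).isin(
            {str(k) for k in signs}
        )]
    rows = []
    for neuron_id, sub in trials.groupby("neuron_id", sort=True):
        sign = signs.get(str(neuron_id), signs.get(neuron_id, "excitatory"))
        res = anova_selectivity(sub, alpha)
        pref, pairs, si = None, (), None
        if res.selective:
            pref, pairs = preferred_grouping(sub, res, alpha, sign=sign)
            if pref is not None:
                means = sub.groupby("grouping")["rate_stim_hz"].mean()
                si = selectivity_index(
                    means.loc[pref], means.drop(pref).to_numpy(), sign=sign
                )
        rows.append(
            {
                "neuron_id": str(neuron_id),
                "anova_F": res.anova_F,
                "anova_p": res.anova_p,
                "selective": res.selective,
                "preferred_grouping": pref,
                "si": si,
                "n_significant_pairs": len(pairs),
                "response_sign": sign,
            }
        )
    return pd.DataFrame(rows)


def chance_simulation(cfg: ChanceSimConfig) -> dict:
    """Fraction of untuned simulated units that the ANOVA flags selective.

    Each simulated unit draws ``trials_per_grouping`` i.i.d. per-trial
    rates uniform in its [rate_min, rate_max] for every grouping; the same
    one-way ANOVA then runs per unit.  With no planted tuning the
    significant fraction estimates the analysis' false-positive rate and
    should sit near alpha.
    """
    lo = np.broadcast_to(np.asarray(cfg.rate_min, float), (cfg.n_neurons,))
    hi = np.broadcast_to(np.asarray(cfg.rate_max, float), (cfg.n_neurons,))
    if np.all(lo == hi):
        logger.warning("degenerate rate range: F undefined, fraction 0")
        return {"n_neurons": cfg.n_neurons, "n_significant": 0, "fraction": 0.0}
    rng = np.random.default_rng(cfg.rng_seed)
    rates = rng.uniform(
        lo[:, None, None],
        hi[:, None, None],
        size=(cfg.n_neurons, cfg.n_groupings, cfg.trials_per_grouping),
    )
    # vectorised one-way ANOVA across neurons (axis 0 = neurons)
    f, p = stats.f_oneway(*np.swapaxes(rates, 0, 1), axis=1)
    n_sig = int(np.sum(p < cfg.alpha))
    return {
        "n_neurons": cfg.n_neurons,
        "n_significant": n_sig,
        "fraction": n_sig / cfg.n_neurons,
    }


def scrambled_vs_original(
    scrambled_means, original_means
) -> dict:
    """Population-level paired comparison of scrambled vs original rates.

    ``scrambled_means`` and ``original_means`` are per-unit mean stimulus
    rates under the two conditions, aligned by unit.  Two-tailed paired
    t-test across units.
    """
    s = np.asarray(scrambled_means, dtype=float)
    o = np.asarray(original_means, dtype=float)
    if len(s) != len(o) or len(s) < 2:
        raise ValidationError("need >= 2 paired neuron means")
    if np.allclose(s, o):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(s, o)
    return {
        "mean_scrambled": float(s.mean()),
        "mean_original": float(o.mean()),
        "t": float(t),
        "p": float(p),
        "n": len(s),
    }
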