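"""End-to-end orchestration: simulate regions, classify responsiveness,
run selectivity and chance-level analyses, decode the pseudo-population,
and emit a plain-text/JSON report bundle.

A "region" here is a simulated population of units (e.g. mimicking the
Wulst / entopallium / MVL sample sizes) described compactly by counts of
excitatory, inhibitory and non-responsive units, how many carry planted
grouping selectivity, and the gains involved.  Every stage is a pure
function of (config, seed), so a report is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency_stats import ContingencyTable, pearson_chi_square, proportion_report
from .population_decoding import permutation_analysis
from .responsiveness import classify_session, normalized_timecourse
from .selectivity import ChanceSimConfig, analyze_session_selectivity, chance_simulation
from .session_synth import NeuronProfile, TaskConfig, ValidationError, generate_session

__all__ = ["RegionSpec", "PipelineConfig", "make_profiles", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSpec:
    """Compact description of one simulated neural population."""

    name: str
    n_excitatory: int = 10
    n_inhibitory: int = 10
    n_nonresponsive: int = 10
    n_selective: int = 0          # taken from the excitatory units
    target_si: float = 0.5
    baseline_rate_hz: float = 10.0
    exc_gain: float = 2.0
    inh_gain: float = 0.5
    n_pause_modulated: int = 0    # taken from the responsive units
    pause_gain: float = 2.0
    n_groupings: int = 5

    def __post_init__(self) -> None:
        if self.n_excitatory + self.n_inhibitory + self.n_nonresponsive < 1:
            raise ValidationError("region must contain at least one neuron")
        if self.n_selective > self.n_excitatory:
            raise ValidationError("n_selective cannot exceed n_excitatory")
        if self.n_pause_modulated > self.n_excitatory + self.n_inhibitory:
            raise ValidationError("n_pause_modulated cannot exceed responsive count")

    @property
    def n_neurons(self) -> int:
        return self.n_excitatory + self.n_inhibitory + self.n_nonresponsive


@dataclass(frozen=True)
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    regions: tuple[RegionSpec, ...] = ()
    alpha: float = 0.05
    decode_resamples: int = 200
    chance_sim_neurons: int = 77
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValidationError("pipeline needs at least one region")

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        task = TaskConfig.from_json(json.dumps(d.pop("task", {})))
        regions = tuple(RegionSpec(**r) for r in d.pop("regions", []))
        return cls(task=task, regions=regions, **d)


def make_profiles(spec: RegionSpec) -> list[NeuronProfile]:
    """Deterministically expand a region spec into unit profiles.

    Selective units are the first ``n_selective`` excitatory units, with
    preferred groupings assigned round-robin; pause modulation goes to the
    first ``n_pause_modulated`` responsive units.
    """
    profiles = []
    idx = 0
    for i in range(spec.n_excitatory):
        preferred = i % spec.n_groupings if i < spec.n_selective else None
        profiles.append(
            NeuronProfile(
                neuron_id=f"{spec.name}-{idx:03d}",
                response_class="excitatory",
                baseline_rate_hz=spec.baseline_rate_hz,
                stim_gain=spec.exc_gain,
                preferred_grouping=preferred,
                target_si=spec.target_si if preferred is not None else 0.0,
                pause_gain=spec.pause_gain if idx < spec.n_pause_modulated else 1.0,
            )
        )
        idx += 1
    for _ in range(spec.n_inhibitory):
        profiles.append(
            NeuronProfile(
                neuron_id=f"{spec.name}-{idx:03d}",
                response_class="inhibitory",
                baseline_rate_hz=spec.baseline_rate_hz,
                stim_gain=spec.inh_gain,
                pause_gain=spec.pause_gain if idx < spec.n_pause_modulated else 1.0,
            )
        )
        idx += 1
    for _ in range(spec.n_nonresponsive):
        profiles.append(
            NeuronProfile(
                neuron_id=f"{spec.name}-{idx:03d}",
                response_class="nonresponsive",
                baseline_rate_hz=spec.baseline_rate_hz,
            )
        )
        idx += 1
    return profiles


def _region_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(index,)).generate_state(1)[0]
               % 2**31)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage for every region and write the report bundle.

    Writes per-region session/responsiveness/selectivity CSVs, a decoding
    summary CSV, and ``report.json`` with counts, proportions, chi-square
    region comparisons, SI tables and decoding p-values.  Returns the
    report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "regions": {}, "comparisons": {}}

    region_tables: dict[str, dict] = {}
    for i, spec in enumerate(cfg.regions):
        seed = _region_seed(cfg.seed, i)
        task = TaskConfig(**{**asdict(cfg.task), "rng_seed": seed,
                             "n_groupings": spec.n_groupings})
        profiles = make_profiles(spec)
        logger.info("region %s: simulating %d neurons (seed %d)",
                    spec.name, len(profiles), seed)
        trials = generate_session(task, profiles)
        trials.to_csv(out / f"session_{spec.name}.csv", index=False)

        classes = classify_session(trials, cfg.alpha)
        classes.to_csv(out / f"responsiveness_{spec.name}.csv", index=False)
        timecourse = normalized_timecourse(trials, classes)
        timecourse.to_csv(out / f"timecourse_{spec.name}.csv")

        sel = analyze_session_selectivity(trials, classes, cfg.alpha)
        sel.to_csv(out / f"selectivity_{spec.name}.csv", index=False)

        responsive_ids = set(classes.loc[classes["visually_responsive"],
                                         "neuron_id"])
        resp_trials = trials[trials["neuron_id"].astype(str).isin(responsive_ids)]
        decoding = None
        if len(responsive_ids) >= 2:
            decoding = permutation_analysis(
                resp_trials, n_resamples=cfg.decode_resamples,
                seed=_region_seed(cfg.seed, 1000 + i),
            )
            decoding.summary().to_csv(out / f"decoding_{spec.name}.csv", index=False)

        n = len(classes)
        n_resp = int(classes["visually_responsive"].sum())
        n_exc = int((classes["response_sign"] == "excitatory").sum())
        n_inh = int((classes["response_sign"] == "inhibitory").sum())
        n_pause = int((classes["visually_responsive"]
                       & classes["pause_active"]).sum())
        n_sel = int(sel["selective"].sum()) if len(sel) else 0
        si_values = sel["si"].dropna().tolist() if len(sel) else []
        region_tables[spec.name] = {
            "n": n, "n_responsive": n_resp, "n_excitatory": n_exc,
            "n_inhibitory": n_inh, "n_pause_active": n_pause,
            "n_selective": n_sel,
        }
        report["regions"][spec.name] = {
            **region_tables[spec.name],
            "responsive": proportion_report([n_resp], [n], [spec.name])[0],
            "selective": proportion_report([n_sel], [max(n_resp, 1)],
                                           [spec.name])[0],
            "si_mean": float(np.mean(si_values)) if si_values else None,
            "si_sd": float(np.std(si_values, ddof=1)) if len(si_values) > 1 else None,
            "decoding": (
                decoding.summary().to_dict(orient="records")
                if decoding is not None else None
            ),
        }

    names = list(region_tables)
    if len(names) >= 2:
        t = region_tables
        resp_table = ContingencyTable.from_proportions(
            [t[r]["n_responsive"] for r in names],
            [t[r]["n"] for r in names],
            row_labels=names, col_labels=("responsive", "nonresponsive"),
        )
        report["comparisons"]["responsive_by_region"] = pearson_chi_square(resp_table)
        for a, b in combinations(names, 2):
            for key, num, den in (
                ("excitatory_inhibitory", "n_excitatory", "n_inhibitory"),
                ("pause_active", "n_pause_active", "n_responsive"),
                ("selective", "n_selective", "n_responsive"),
            ):
                try:
                    if key == "excitatory_inhibitory":
                        table = ContingencyTable(
                            [[t[a][num], t[a][den]], [t[b][num], t[b][den]]]
                        )
                    else:
                        table = ContingencyTable.from_proportions(
                            [t[a][num], t[b][num]], [t[a][den], t[b][den]],
                            row_labels=(a, b),
                        )
                    report["comparisons"][f"{key}:{a}_vs_{b}"] = pearson_chi_square(
                        table
                    )
                except ValidationError as err:
                    logger.warning("comparison %s %s-%s skipped: %s", key, a, b, err)

    chance = chance_simulation(
        ChanceSimConfig(
            n_neurons=cfg.chance_sim_neurons,
            rate_min=0.0,
            rate_max=2.0 * cfg.regions[0].baseline_rate_hz,
            alpha=cfg.alpha,
            rng_seed=_region_seed(cfg.seed, 9999),
        )
    )
    report["chance_simulation"] = chance

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
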