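"""Scenario engines: PSA-stratum analyses, hazard-ratio sweeps, CTBS grid.

Each scenario patches the parameter registry at one or more grid points and
re-runs the deterministic model, producing one outcome row (per strategy,
with deltas against conventional imaging) per grid point. PSA-stratum
scenarios patch only the imaging-finding parameters — all other model inputs
are held at their base values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .markov import run_cohort
from .parameters import ParameterRegistry, load_default_parameters
from .synthetic import (
    DEFAULT_PSA_MIX,
    LifeTable,
    PSA_STRATA,
    stratum_finding_probabilities,
)
from .tree import Strategy, StrategyConfig, allocate_treatment, classify

__all__ = ["ScenarioSpec", "run_scenario", "default_grid"]

_KINDS = ("psa_stratum", "hr_fn_sweep", "hr_mdt_sweep", "ctbs_accuracy_grid")

#: sweep ranges explored by the sensitivity analyses
HR_FN_RANGE = (0.75, 2.50)       # spans harm (<1) and benefit (>1)
HR_MDT_RANGE = (0.125, 1.000)
CTBS_SENS_RANGE = (0.15, 0.65)
CTBS_SPEC_RANGE = (0.40, 1.00)
_N_GRID = 9


def default_grid(kind: str) -> np.ndarray | list:
    if kind == "hr_fn_sweep":
        return np.linspace(*HR_FN_RANGE, _N_GRID)
    if kind == "hr_mdt_sweep":
        return np.linspace(*HR_MDT_RANGE, _N_GRID)
    if kind == "ctbs_accuracy_grid":
        sens = np.linspace(*CTBS_SENS_RANGE, _N_GRID)
        spec = np.linspace(*CTBS_SPEC_RANGE, _N_GRID)
        return [(s, p) for s in sens for p in spec]
    if kind == "psa_stratum":
        return list(PSA_STRATA)
    raise ValueError(f"unknown scenario kind {kind!r}")


@dataclass
class ScenarioSpec:
    kind: str
    grid: np.ndarray | list | None = None
    overrides: Mapping[str, float] = field(default_factory=dict)
    psa_mix: tuple = DEFAULT_PSA_MIX

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.grid is None:
            self.grid = default_grid(self.kind)
        if len(self.grid) == 0:
            raise ValueError("scenario grid must be nonempty")
        if self.kind == "hr_fn_sweep":
            vals = np.asarray(self.grid, dtype=float)
            if not (vals.min() < 1.0 < vals.max()):
                raise ValueError(
                    "hr_fn_sweep grid must cover values below and above 1 "
                    "(harm and benefit)"
                )
        if self.kind == "hr_mdt_sweep":
            vals = np.asarray(self.grid, dtype=float)
            if vals.min() < HR_MDT_RANGE[0] - 1e-12 or vals.max() > 1.0 + 1e-12:
                raise ValueError("hr_mdt_sweep grid must lie in [0.125, 1.0]")


def _point_outcomes(
    registry: ParameterRegistry,
    strategies,
    life_table,
    fn_detection_rate,
    horizon,
    discount_rate,
    half_cycle,
) -> dict[Strategy, dict]:
    params = registry.point_set()
    out = {}
    for strat in strategies:
        config = StrategyConfig(strat, fn_detection_rate)
        pre = classify(config, params)
        initial = allocate_treatment(pre, params)
        _, summary = run_cohort(
            initial, params, config, life_table=life_table, horizon=horizon,
            discount_rate=discount_rate, half_cycle=half_cycle,
            store_trace=False,
        )
        out[strat] = {
            "life_years": float(np.asarray(summary.life_years)),
            "qalys": float(np.asarray(summary.qalys)),
            "pca_deaths": float(np.asarray(summary.pca_deaths)),
        }
    return out


def run_scenario(
    spec: ScenarioSpec,
    registry: ParameterRegistry | None = None,
    strategies: tuple[Strategy, ...] = tuple(Strategy),
    life_table: LifeTable | None = None,
    fn_detection_rate: float = 0.10,
    horizon: int | None = None,
    discount_rate: float | None = None,
    half_cycle: bool = False,
) -> pd.DataFrame:
    """Evaluate the model across the scenario grid (deterministic runs).

    Returns one row per (grid point, strategy) with life-years, QALYs and
    prostate-cancer deaths per 1000 plus deltas against conventional imaging.
    """
    registry = registry or load_default_parameters()
    if spec.overrides:
        registry = registry.patch(dict(spec.overrides))

    rows = []
    for point in spec.grid:
        if spec.kind == "hr_fn_sweep":
            patched = registry.patch({"hr_fn_progression": float(point)})
            label = {"hr_fn_progression": float(point)}
        elif spec.kind == "hr_mdt_sweep":
            patched = registry.patch({"hr_mdt": float(point)})
            label = {"hr_mdt": float(point)}
        elif spec.kind == "ctbs_accuracy_grid":
            sens, specificity = point
            patched = registry.patch(
                {"sens_ctbs": float(sens), "spec_ctbs": float(specificity)}
            )
            label = {"sens_ctbs": float(sens), "spec_ctbs": float(specificity)}
        else:  # psa_stratum: patch imaging-finding parameters only
            probs = stratum_finding_probabilities(registry, spec.psa_mix)
            row = probs.set_index("stratum").loc[point]
            p_det = float(row["p_detect"])
            p_met = float(row["p_metastatic_given_detected"])
            patched = registry.patch(
                {
                    "p_detect_psma": p_det,
                    "p_no_disease_psma": 1.0 - p_det,
                    "p_metastatic_given_detected": p_met,
                    "p_localized_given_detected": 1.0 - p_met,
                }
            )
            label = {"psa_stratum": point}

        outcomes = _point_outcomes(
            patched, strategies, life_table, fn_detection_rate, horizon,
            discount_rate, half_cycle,
        )
        ref = outcomes.get(Strategy.CTBS_ALONE)
        for strat, vals in outcomes.items():
            rec = dict(label)
            rec["strategy"] = strat.value
            rec.update(vals)
            if ref is not None:
                rec["d_life_years"] = vals["life_years"] - ref["life_years"]
                rec["d_qalys"] = vals["qalys"] - ref["qalys"]
                rec["d_pca_deaths"] = vals["pca_deaths"] - ref["pca_deaths"]
            rows.append(rec)
    return pd.DataFrame(rows)
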