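"""Model/Results surface tying the tree, engine, PSA and reporting together.

:class:`ImagingStrategyModel` is built from a parameter registry and a
background-mortality table. Its :meth:`~ImagingStrategyModel.evaluate` runs
the deterministic point configuration; :meth:`~ImagingStrategyModel.fit`
runs the Monte Carlo probabilistic analysis and returns a results object
carrying per-iteration draws, means with 95% uncertainty intervals, strategy
deltas and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace, OutcomeSummary, compare_strategies, run_cohort
from .parameters import ParameterRegistry, load_default_parameters
from .reporting import Report, render_tables
from .synthetic import LifeTable, default_life_table
from .tree import (
    Strategy,
    StrategyConfig,
    allocate_treatment,
    classify,
    detection_counts,
    treatment_initiation,
)
from .uncertainty import PSARun, run_psa

__all__ = ["ImagingStrategyModel", "PointResults", "PSAResults"]


class ImagingStrategyModel:
    """Decision tree + Markov cohort model of three imaging strategies.

    Parameters
    ----------
    registry
        Model inputs; defaults to the published input table.
    life_table
        Age-indexed background mortality; defaults to the calibrated
        Gompertz schedule (life expectancy ~17 y at age 66).
    strategies
        Strategies to evaluate (default: all three).
    horizon, discount_rate, half_cycle, fn_detection_rate
        Engine settings; defaults follow the base-case analysis (lifetime
        horizon to age 110, 3% discounting, no half-cycle correction, 10%
        yearly identification of false negatives).
    """

    def __init__(
        self,
        registry: ParameterRegistry | None = None,
        life_table: LifeTable | None = None,
        strategies: tuple[Strategy, ...] = tuple(Strategy),
        horizon: int | None = None,
        discount_rate: float | None = None,
        half_cycle: bool = False,
        fn_detection_rate: float = 0.10,
    ):
        self.registry = registry or load_default_parameters()
        self.life_table = life_table or default_life_table()
        self.strategies = tuple(strategies)
        self.horizon = horizon
        self.discount_rate = discount_rate
        self.half_cycle = half_cycle
        self.fn_detection_rate = fn_detection_rate

    @classmethod
    def from_config(cls, path, **kwargs) -> "ImagingStrategyModel":
        """Build a model from a YAML parameter config file."""
        return cls(registry=ParameterRegistry.from_yaml(path), **kwargs)

    def _config(self, strategy: Strategy) -> StrategyConfig:
        return StrategyConfig(strategy, self.fn_detection_rate)

    def evaluate(self, store_traces: bool = True) -> "PointResults":
        """Deterministic run at the point estimates."""
        params = self.registry.point_set()
        initial, traces, summaries = {}, {}, {}
        detection, treatment = {}, {}
        for strat in self.strategies:
            config = self._config(strat)
            pre = classify(config, params)
            init = allocate_treatment(pre, params)
            trace, summary = run_cohort(
                init, params, config, life_table=self.life_table,
                horizon=self.horizon, discount_rate=self.discount_rate,
                half_cycle=self.half_cycle, store_trace=store_traces,
            )
            initial[strat] = init
            traces[strat] = trace
            summaries[strat] = summary
            detection[strat.value] = {
                k: float(np.asarray(v)) for k, v in detection_counts(pre).items()
            }
            treatment[strat.value] = {
                k: float(np.asarray(v))
                for k, v in treatment_initiation(pre, params).items()
            }
        return PointResults(self, initial, traces, summaries, detection, treatment)

    def fit(
        self, n_iterations: int = 10_000, seed: int = 2024,
        include_markov: bool = True,
    ) -> "PSAResults":
        """Probabilistic sensitivity analysis (Monte Carlo over inputs)."""
        run = run_psa(
            self.registry, self.strategies, n_iterations=n_iterations,
            seed=seed, life_table=self.life_table,
            fn_detection_rate=self.fn_detection_rate, horizon=self.horizon,
            discount_rate=self.discount_rate, half_cycle=self.half_cycle,
            include_markov=include_markov,
        )
        return PSAResults(self, run)


@dataclass
class PointResults:
    """Deterministic model outputs at the point estimates."""

    model: ImagingStrategyModel
    initial_distributions: dict[Strategy, object]
    traces: dict[Strategy, CohortTrace | None]
    outcomes: dict[Strategy, OutcomeSummary]
    detection: dict[str, dict[str, float]]
    treatment: dict[str, dict[str, float]]

    @property
    def deltas(self) -> pd.DataFrame:
        return compare_strategies(self.outcomes)

    def outcome_frame(self) -> pd.DataFrame:
        rows = {
            s.value: {
                "life_years": float(np.asarray(o.life_years)),
                "qalys": float(np.asarray(o.qalys)),
                "pca_deaths": float(np.asarray(o.pca_deaths)),
            }
            for s, o in self.outcomes.items()
        }
        return pd.DataFrame(rows).T

    def report(self) -> Report:
        merged = {
            s: {**self.detection[s], **self.treatment[s]} for s in self.detection
        }
        for strat, out in self.outcomes.items():
            merged[strat.value].update(
                life_years=float(np.asarray(out.life_years)),
                qalys=float(np.asarray(out.qalys)),
                pca_deaths=float(np.asarray(out.pca_deaths)),
            )
        return render_tables(merged)

    def summary(self) -> str:
        text = self.report().text
        if Strategy.CTBS_ALONE in self.outcomes:
            text += "\n\nDeltas vs conventional imaging\n" + (
                self.deltas.round(1).to_string()
            )
        return text


@dataclass
class PSAResults:
    """Monte Carlo results: draws, summaries, uncertainty intervals."""

    model: ImagingStrategyModel
    run: PSARun

    @property
    def draws(self) -> pd.DataFrame:
        return self.run.draws

    @property
    def summary_frame(self) -> pd.DataFrame:
        return self.run.summary

    def mean(self, strategy: Strategy, outcome: str) -> float:
        return self.run.summary_for(strategy, outcome)[0]

    def ui(self, strategy: Strategy, outcome: str) -> tuple[float, float]:
        return self.run.summary_for(strategy, outcome)[1]

    def report(self) -> Report:
        return render_tables(self.run.summary)

    def summary(self) -> str:
        header = (
            f"Probabilistic sensitivity analysis: {self.run.n_iterations} "
            f"iterations, seed {self.run.seed}\n"
        )
        return header + self.report().text

    def to_csv(self, path) -> None:
        self.run.draws.to_csv(path, index=False)
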