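"""Probabilistic sensitivity analysis: Monte Carlo over sampled parameters.

Parameter uncertainty is propagated to every model output by drawing full
parameter sets from their fitted distributions and re-running the decision
tree and Markov engine for each draw. The same draw is applied to all
strategies within an iteration (common random numbers), so uncertainty in
strategy differences reflects the correlation induced by shared inputs.
Outcomes are summarised as the arithmetic mean and the empirical 2.5th/97.5th
percentiles (the 95% uncertainty interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import compare_strategies, invalid_parameter_mask, run_cohort
from .parameters import ParameterRegistry, ParameterSet
from .synthetic import LifeTable
from .tree import (
    Strategy,
    StrategyConfig,
    allocate_treatment,
    classify,
    detection_counts,
    treatment_initiation,
)

__all__ = ["PSARun", "run_psa", "summarize_ui"]

DEFAULT_ITERATIONS = 10_000
_MAX_RESAMPLE_ROUNDS = 20


def summarize_ui(samples) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and empirical 95% interval of outcome samples.

    Percentiles use linear interpolation. Below 100 samples the percentile
    interval is noisy; a warning is emitted and the same method applied.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        warnings.warn(
            f"only {samples.size} samples: percentile interval will be wide/noisy",
            stacklevel=2,
        )
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return float(samples.mean()), (float(lo), float(hi))


@dataclass
class PSARun:
    """Monte Carlo run: per-iteration outcomes and their summary."""

    n_iterations: int
    seed: int
    draws: pd.DataFrame         # one row per (iteration, strategy)
    summary: pd.DataFrame       # mean / ui_low / ui_high per (strategy, outcome)
    deltas: pd.DataFrame | None = None
    n_resampled: int = 0

    def summary_for(self, strategy: Strategy, outcome: str) -> tuple:
        row = self.summary.loc[(strategy.value, outcome)]
        return float(row["mean"]), (float(row["ui_low"]), float(row["ui_high"]))


def _sample_valid(
    registry: ParameterRegistry, seed: int, n: int, config: StrategyConfig
) -> tuple[ParameterSet, int]:
    """Draw n parameter sets, resampling draws with invalid transition rows."""
    params = registry.sample(seed, n)
    bad = invalid_parameter_mask(params, config)
    n_resampled = 0
    round_ = 0
    offset = n
    while np.any(bad):
        k = int(bad.sum())
        n_resampled += k
        round_ += 1
        if round_ > _MAX_RESAMPLE_ROUNDS:
            raise RuntimeError("could not draw valid parameter sets")
        warnings.warn(
            f"resampling {k} parameter draw(s) with out-of-range transition rows",
            stacklevel=2,
        )
        repl = registry.sample(seed, offset + k).select(slice(offset, offset + k))
        for name in params.values:
            arr = np.asarray(params.values[name], dtype=float).copy()
            arr[bad] = np.asarray(repl.values[name])
            params.values[name] = arr
        offset += k
        bad = invalid_parameter_mask(params, config)
    return params, n_resampled


def run_psa(
    registry: ParameterRegistry,
    strategies: tuple[Strategy, ...] = tuple(Strategy),
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 2024,
    life_table: LifeTable | None = None,
    fn_detection_rate: float = 0.10,
    horizon: int | None = None,
    discount_rate: float | None = None,
    half_cycle: bool = False,
    include_markov: bool = True,
) -> PSARun:
    """Propagate parameter uncertainty to model outcomes.

    Per iteration the same sampled parameter set feeds every strategy's
    decision tree (detection and treatment-initiation counts per 1000) and,
    when ``include_markov`` is set, the Markov engine (discounted life-years,
    QALYs, prostate-cancer deaths per 1000). Reproducible given ``seed``.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    cfg0 = StrategyConfig(Strategy.CTBS_ALONE, fn_detection_rate)
    params, n_resampled = _sample_valid(registry, seed, n_iterations, cfg0)

    frames = []
    summaries = {}
    for strat in strategies:
        config = StrategyConfig(strat, fn_detection_rate)
        pre = classify(config, params)
        cols: dict[str, np.ndarray] = {}
        cols.update(detection_counts(pre))
        cols.update(treatment_initiation(pre, params))
        if include_markov:
            initial = allocate_treatment(pre, params)
            _, summary = run_cohort(
                initial, params, config,
                life_table=life_table, horizon=horizon,
                discount_rate=discount_rate, half_cycle=half_cycle,
                store_trace=False,
            )
            summaries[strat] = summary
            cols["life_years"] = np.asarray(summary.life_years)
            cols["qalys"] = np.asarray(summary.qalys)
            cols["pca_deaths"] = np.asarray(summary.pca_deaths)
        df = pd.DataFrame(
            {k: np.broadcast_to(v, (n_iterations,)) for k, v in cols.items()}
        )
        df.insert(0, "iteration", np.arange(n_iterations))
        df.insert(1, "strategy", strat.value)
        frames.append(df)

    draws = pd.concat(frames, ignore_index=True)

    records = []
    outcome_cols = [c for c in draws.columns if c not in ("iteration", "strategy")]
    for strat in strategies:
        sub = draws[draws["strategy"] == strat.value]
        for col in outcome_cols:
            mean, (lo, hi) = _mean_ui(sub[col].to_numpy())
            records.append(
                {"strategy": strat.value, "outcome": col,
                 "mean": mean, "ui_low": lo, "ui_high": hi}
            )

    deltas = None
    if include_markov and Strategy.CTBS_ALONE in strategies:
        ref = draws[draws["strategy"] == Strategy.CTBS_ALONE.value]
        for strat in strategies:
            if strat is Strategy.CTBS_ALONE:
                continue
            sub = draws[draws["strategy"] == strat.value]
            for col in ("life_years", "qalys", "pca_deaths"):
                diff = sub[col].to_numpy() - ref[col].to_numpy()
                mean, (lo, hi) = _mean_ui(diff)
                records.append(
                    {"strategy": strat.value, "outcome": f"d_{col}",
                     "mean": mean, "ui_low": lo, "ui_high": hi}
                )
        deltas = compare_strategies(summaries)

    summary = pd.DataFrame(records).set_index(["strategy", "outcome"])
    return PSARun(
        n_iterations=n_iterations, seed=seed, draws=draws, summary=summary,
        deltas=deltas, n_resampled=n_resampled,
    )


def _mean_ui(samples: np.ndarray) -> tuple[float, tuple[float, float]]:
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return float(samples.mean()), (float(lo), float(hi))
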