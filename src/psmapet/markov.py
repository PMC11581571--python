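"""Annual-cycle Markov cohort engine.

Propagates the entry-state occupancy from the decision tree over a lifetime
horizon (age 66 to 110 by default), accumulating discounted life-years and
QALYs and cumulative deaths. Background mortality takes precedence each
cycle: the age-specific all-cause probability ``qx`` is applied to every
alive state and disease transitions are scaled by ``1 - qx`` (competing
allocation). Only the mCRPC state can lead to prostate-cancer death.

Hazard ratios act on annual probabilities through the constant-hazard
conversion ``p -> 1 - (1 - p)^hr``. All operations broadcast over a leading
batch axis so the probabilistic analysis can run vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .states import ALIVE, DEATH_STATES, IDX, N_STATES, STATES, UTILITY_PARAM
from .synthetic import LifeTable, default_life_table
from .tree import InitialDistribution, Strategy, StrategyConfig

__all__ = [
    "hr_adjust",
    "build_transitions",
    "run_cohort",
    "compare_strategies",
    "invalid_parameter_mask",
    "CohortTrace",
    "OutcomeSummary",
]

_ROW_TOL = 1e-10


def hr_adjust(p, hr):
    """Apply a hazard ratio to an annual probability.

    Probability -> rate -> scaled rate -> probability under a constant
    hazard: ``1 - (1 - p)^hr``.
    """
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any((p == 1) & (hr != 1)):
        raise ValueError("p = 1 cannot be hazard-adjusted")
    if np.any(hr < 0):
        raise ValueError("hazard ratio must be non-negative")
    out = 1.0 - (1.0 - p) ** hr
    return float(out) if out.ndim == 0 else out


_SPLIT_LOC = ("tx_loc_no_treatment", "tx_loc_local", "tx_loc_systemic")
_SPLIT_MET = ("tx_met_systemic", "tx_met_mdt")

# destination state indices for newly incident / newly detected disease
_LOC_STATES = (IDX["loc_no_treatment"], IDX["loc_local"], IDX["loc_systemic"])
_MET_STATES = (IDX["met_adt_arsi"], IDX["met_mdt"])
_ND_ROWS = tuple(
    IDX[s] for s in (
        "nd_no_treatment", "nd_radiation", "nd_systemic",
        "fp_loc_no_treatment", "fp_loc_local", "fp_loc_systemic",
        "fp_met_systemic", "fp_met_mdt",
    )
)


def _g(params: ParameterSet, name: str) -> np.ndarray:
    return np.asarray(params[name], dtype=float)


def build_transitions(
    params: ParameterSet, config: StrategyConfig | None = None
) -> np.ndarray:
    """Per-cycle disease transition matrix (background mortality excluded).

    Rows sum to one; absorbing death states are identity rows. The matrix is
    age-independent — mortality is layered on during propagation.
    """
    names = [
        "tp_nd_to_localized", "tp_nd_to_metastatic",
        "tp_loc_no_tx_to_metastatic", "tp_loc_local_to_metastatic",
        "tp_loc_local_to_nd_after", "tp_loc_systemic_to_metastatic",
        "tp_nd_after_to_metastatic", "tp_met_adt_arsi_to_mcrpc",
        "tp_mcrpc_to_pca_death", "hr_mdt", "hr_fn_progression",
        *_SPLIT_LOC, *_SPLIT_MET,
    ]
    batch = np.broadcast_shapes(*[np.shape(_g(params, n)) for n in names])
    D = np.zeros(batch + (N_STATES, N_STATES))

    from .tree import _split

    lc = [np.broadcast_to(p, batch) for p in _split(params, _SPLIT_LOC)]
    mt = [np.broadcast_to(p, batch) for p in _split(params, _SPLIT_MET)]
    p_ndl = _g(params, "tp_nd_to_localized")
    p_ndm = _g(params, "tp_nd_to_metastatic")
    fn_rate = config.fn_detection_rate if config is not None else 0.10

    def put(row, col, value):
        D[..., row, col] = np.broadcast_to(value, batch)

    # states with no-radiographic-disease dynamics (true-negative profiles
    # and false positives): incident disease is treatment-allocated with the
    # same management splits as at entry
    for row in _ND_ROWS:
        for j, dest in enumerate(_LOC_STATES):
            put(row, dest, p_ndl * lc[j])
        for j, dest in enumerate(_MET_STATES):
            put(row, dest, p_ndm * mt[j])

    for row, p_name in (
        (IDX["loc_no_treatment"], "tp_loc_no_tx_to_metastatic"),
        (IDX["loc_local"], "tp_loc_local_to_metastatic"),
        (IDX["loc_systemic"], "tp_loc_systemic_to_metastatic"),
    ):
        p = _g(params, p_name)
        for j, dest in enumerate(_MET_STATES):
            put(row, dest, p * mt[j])
    # only local treatment can clear radiographic disease
    put(IDX["loc_local"], IDX["nd_after_localized"],
        _g(params, "tp_loc_local_to_nd_after"))

    p_after = _g(params, "tp_nd_after_to_metastatic")
    for j, dest in enumerate(_MET_STATES):
        put(IDX["nd_after_localized"], dest, p_after * mt[j])

    p_prog = _g(params, "tp_met_adt_arsi_to_mcrpc")
    put(IDX["met_adt_arsi"], IDX["mcrpc"], p_prog)
    put(IDX["met_mdt"], IDX["mcrpc"], hr_adjust(p_prog, _g(params, "hr_mdt")))
    put(IDX["mcrpc"], IDX["death_pca"], _g(params, "tp_mcrpc_to_pca_death"))

    # undetected disease: accelerated progression, plus per-year correct
    # identification moving patients to the detected counterpart states
    hr_fn = _g(params, "hr_fn_progression")
    fn_loc_prog = hr_adjust(_g(params, "tp_loc_no_tx_to_metastatic"), hr_fn)
    put(IDX["fn_localized"], IDX["fn_metastatic"], fn_loc_prog)
    for j, dest in enumerate(_LOC_STATES):
        put(IDX["fn_localized"], dest, fn_rate * lc[j])
    fn_met_prog = hr_adjust(p_prog, hr_fn)
    put(IDX["fn_metastatic"], IDX["mcrpc"], fn_met_prog)
    for j, dest in enumerate(_MET_STATES):
        put(IDX["fn_metastatic"], dest, fn_rate * mt[j])

    for row in DEATH_STATES:
        put(row, row, 1.0)

    # diagonal residual: probability of remaining in the same state
    off = D.sum(axis=-1)
    idx = np.arange(N_STATES)
    resid = 1.0 - (off - D[..., idx, idx])
    if np.any(resid < -_ROW_TOL):
        raise RuntimeError("transition row exceeds probability 1")
    D[..., idx, idx] = np.maximum(resid, 0.0)

    rows = D.sum(axis=-1)
    if np.any(np.abs(rows - 1.0) > _ROW_TOL):
        raise RuntimeError("transition rows do not sum to 1")
    return D


def invalid_parameter_mask(
    params: ParameterSet, config: StrategyConfig | None = None
) -> np.ndarray:
    """Boolean mask of batched draws whose transition rows would exceed 1."""
    fn_rate = config.fn_detection_rate if config is not None else 0.10
    hr_fn = _g(params, "hr_fn_progression")
    sums = [
        _g(params, "tp_nd_to_localized") + _g(params, "tp_nd_to_metastatic"),
        _g(params, "tp_loc_local_to_nd_after")
        + _g(params, "tp_loc_local_to_metastatic"),
        fn_rate + 1.0 - (1.0 - _g(params, "tp_loc_no_tx_to_metastatic")) ** hr_fn,
        fn_rate + 1.0 - (1.0 - _g(params, "tp_met_adt_arsi_to_mcrpc")) ** hr_fn,
    ]
    bad = np.zeros(np.broadcast_shapes(*[np.shape(s) for s in sums]), dtype=bool)
    for s in sums:
        bad |= np.asarray(s) > 1.0
    return bad


@dataclass
class CohortTrace:
    """State-occupancy matrix over annual cycles."""

    occupancy: np.ndarray  # shape (T+1, ..., N_STATES)
    start_age: int

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0])

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        if occ.ndim != 2:
            raise ValueError("to_frame requires an unbatched trace")
        rows = [
            {"cycle": t, "age": self.start_age + t, "state": STATES[s],
             "occupancy": occ[t, s]}
            for t in range(occ.shape[0])
            for s in range(N_STATES)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class OutcomeSummary:
    """Discounted life-years/QALYs and cumulative deaths per 1000 patients."""

    strategy: Strategy
    life_years: np.ndarray | float
    qalys: np.ndarray | float
    pca_deaths: np.ndarray | float
    all_deaths: np.ndarray | float
    horizon: int
    discount_rate: float

    def to_dict(self) -> dict:
        def val(x):
            x = np.asarray(x)
            return float(x) if x.ndim == 0 else x.tolist()

        return {
            "strategy": self.strategy.value,
            "life_years": val(self.life_years),
            "qalys": val(self.qalys),
            "pca_deaths": val(self.pca_deaths),
            "all_deaths": val(self.all_deaths),
            "horizon": self.horizon,
            "discount_rate": self.discount_rate,
        }


def _utility_vector(params: ParameterSet, batch: tuple) -> np.ndarray:
    u = np.zeros(batch + (N_STATES,))
    for state, pname in UTILITY_PARAM.items():
        u[..., IDX[state]] = np.broadcast_to(_g(params, pname), batch)
    return u


def run_cohort(
    initial: InitialDistribution,
    params: ParameterSet,
    config: StrategyConfig | None = None,
    life_table: LifeTable | None = None,
    horizon: int | None = None,
    discount_rate: float | None = None,
    half_cycle: bool = False,
    store_trace: bool = True,
) -> tuple[CohortTrace | None, OutcomeSummary]:
    """Propagate the cohort over annual cycles from the assumed entry age.

    Life-years accrue for alive states and QALYs weight occupancy by state
    utility, both discounted at ``1 / (1 + r)^cycle``; death counts are
    cumulative and undiscounted. Deterministic given its inputs.
    """
    if life_table is None:
        life_table = default_life_table()
    start_age = int(round(float(np.mean(_g(params, "median_age")))))
    if discount_rate is None:
        discount_rate = float(np.mean(_g(params, "discount_rate")))
    if discount_rate < 0:
        raise ValueError("discount_rate must be non-negative")
    # the final cycle applies the life table's closure row (qx = 1), so the
    # default lifetime horizon leaves the cohort fully absorbed
    max_T = int(life_table.age[-1]) - start_age + 1
    T = max_T if horizon is None else int(horizon)
    if T < 1:
        raise ValueError("horizon must be >= 1")
    if T > max_T:
        raise ValueError(f"life table ends before age {start_age + T}")

    occ0 = np.asarray(initial.occupancy, dtype=float)
    if np.any(np.abs(occ0.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("initial distribution is not normalized")

    D = build_transitions(params, config)
    batch = np.broadcast_shapes(occ0.shape[:-1], D.shape[:-2])
    occ = np.broadcast_to(occ0, batch + (N_STATES,)).copy()
    u = _utility_vector(params, batch)

    ly = np.zeros(batch)
    qaly = np.zeros(batch)
    trace = np.empty((T + 1,) + batch + (N_STATES,)) if store_trace else None
    if store_trace:
        trace[0] = occ

    oc = IDX["death_other"]
    v = 1.0
    disc = 1.0 / (1.0 + discount_rate)
    for t in range(T):
        q = life_table.qx_at(start_age + t)
        alive = 1.0 - occ[..., DEATH_STATES[0]] - occ[..., DEATH_STATES[1]]
        # disease transitions apply to survivors of background mortality
        occ_a = occ.copy()
        occ_a[..., DEATH_STATES[0]] = 0.0
        occ_a[..., DEATH_STATES[1]] = 0.0
        moved = np.einsum("...i,...ij->...j", occ_a, D)
        nxt = (1.0 - q) * moved
        nxt[..., DEATH_STATES[0]] += occ[..., DEATH_STATES[0]]
        nxt[..., DEATH_STATES[1]] += occ[..., DEATH_STATES[1]]
        nxt[..., oc] += q * alive

        if half_cycle:
            alive_next = 1.0 - nxt[..., DEATH_STATES[0]] - nxt[..., DEATH_STATES[1]]
            ly += v * 0.5 * (alive + alive_next)
            qaly += v * 0.5 * ((occ * u).sum(axis=-1) + (nxt * u).sum(axis=-1))
        else:
            ly += v * alive
            qaly += v * (occ * u).sum(axis=-1)

        occ = nxt
        if store_trace:
            trace[t + 1] = occ
        v *= disc

    summary = OutcomeSummary(
        strategy=initial.strategy,
        life_years=ly * 1000.0,
        qalys=qaly * 1000.0,
        pca_deaths=occ[..., IDX["death_pca"]] * 1000.0,
        all_deaths=(occ[..., IDX["death_pca"]] + occ[..., IDX["death_other"]])
        * 1000.0,
        horizon=T,
        discount_rate=float(discount_rate),
    )
    trace_obj = CohortTrace(trace, start_age) if store_trace else None
    return trace_obj, summary


def compare_strategies(
    summaries: dict[Strategy, OutcomeSummary],
    reference: Strategy = Strategy.CTBS_ALONE,
) -> pd.DataFrame:
    """Pairwise outcome differences (strategy minus reference) per 1000."""
    if reference not in summaries:
        raise ValueError(f"reference strategy {reference} missing from summaries")
    horizons = {s.horizon for s in summaries.values()}
    if len(horizons) > 1:
        raise ValueError(f"summaries have mismatched horizons: {horizons}")
    ref = summaries[reference]

    def mean(x):
        return float(np.mean(np.asarray(x)))

    rows = []
    for strat, summ in summaries.items():
        rows.append(
            {
                "strategy": strat.value,
                "life_years": mean(summ.life_years),
                "qalys": mean(summ.qalys),
                "pca_deaths": mean(summ.pca_deaths),
                "d_life_years": mean(summ.life_years) - mean(ref.life_years),
                "d_qalys": mean(summ.qalys) - mean(ref.qalys),
                "d_pca_deaths": mean(summ.pca_deaths) - mean(ref.pca_deaths),
            }
        )
    return pd.DataFrame(rows).set_index("strategy")
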