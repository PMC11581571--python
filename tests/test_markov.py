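"""Markov cohort engine: hazard conversion, transitions, accrual oracles."""

import numpy as np
import pytest

from psmapet.markov import (
    build_transitions,
    compare_strategies,
    hr_adjust,
    run_cohort,
)
from psmapet.parameters import ParameterSet
from psmapet.states import DEATH_STATES, IDX, N_STATES
from psmapet.tree import InitialDistribution, Strategy, StrategyConfig, allocate_treatment, classify

from conftest import chain_params


def _unit_initial(state: str, strategy=Strategy.PSMA_ALONE) -> InitialDistribution:
    occ = np.zeros(N_STATES)
    occ[IDX[state]] = 1.0
    return InitialDistribution(strategy, occ)


class TestHazardAdjust:
    def test_identity_and_zero_hazard(self):
        assert hr_adjust(0.37, 1.0) == pytest.approx(0.37)
        assert hr_adjust(0.37, 0.0) == 0.0

    def test_matches_explicit_rate_conversion(self):
        # probability -> rate -> scaled rate -> probability
        p, hr = 0.1611, 0.25
        expected = 1.0 - np.exp(-(-np.log(1.0 - p)) * hr)
        assert hr_adjust(p, hr) == pytest.approx(expected, abs=1e-12)
        assert hr_adjust(p, hr) == pytest.approx(0.0430, abs=5e-5)

    def test_certain_event_cannot_be_adjusted(self):
        with pytest.raises(ValueError):
            hr_adjust(1.0, 0.5)
        with pytest.raises(ValueError):
            hr_adjust(0.5, -1.0)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, point_params):
        D = build_transitions(point_params, StrategyConfig(Strategy.CTBS_ALONE))
        assert np.allclose(D.sum(-1), 1.0, atol=1e-10)
        assert np.all(D >= 0)

    def test_absorbing_death_states(self, point_params):
        D = build_transitions(point_params)
        for d in DEATH_STATES:
            row = np.zeros(N_STATES)
            row[d] = 1.0
            assert np.allclose(D[d], row)

    def test_untreated_localized_progression_mass(self, point_params):
        D = build_transitions(point_params)
        row = D[IDX["loc_no_treatment"]]
        met_mass = row[IDX["met_adt_arsi"]] + row[IDX["met_mdt"]]
        assert met_mass == pytest.approx(0.0494, abs=1e-9)

    def test_mdt_progression_is_hazard_adjusted(self, point_params):
        D = build_transitions(point_params)
        assert D[IDX["met_mdt"], IDX["mcrpc"]] == pytest.approx(
            hr_adjust(0.1611, 0.25), abs=1e-12
        )

    def test_fn_localized_progression_accelerated(self, point_params):
        D = build_transitions(point_params)
        assert D[IDX["fn_localized"], IDX["fn_metastatic"]] == pytest.approx(
            1.0 - (1.0 - 0.0494) ** 1.79, abs=1e-9
        )
        assert D[IDX["fn_localized"], IDX["fn_metastatic"]] == pytest.approx(
            0.0867, abs=5e-5
        )

    def test_fn_detection_moves_to_detected_states_with_allocation(
        self, point_params
    ):
        D = build_transitions(point_params, StrategyConfig(Strategy.CTBS_ALONE, 0.10))
        loc_mass = sum(
            D[IDX["fn_localized"], IDX[s]]
            for s in ("loc_no_treatment", "loc_local", "loc_systemic")
        )
        assert loc_mass == pytest.approx(0.10, abs=1e-9)

    def test_batched_parameters_give_batched_matrix(self, registry):
        batch = registry.sample(seed=1, n=50)
        D = build_transitions(batch)
        assert D.shape == (50, N_STATES, N_STATES)
        assert np.allclose(D.sum(-1), 1.0, atol=1e-10)


class TestCohortAccrualOracles:
    def test_no_transitions_no_mortality_gives_horizon_life_years(
        self, no_mortality_table
    ):
        params = chain_params()
        _, summary = run_cohort(
            _unit_initial("nd_no_treatment"), params,
            life_table=no_mortality_table, horizon=10, discount_rate=0.0,
        )
        assert float(summary.life_years) == pytest.approx(10_000.0, abs=1e-6)
        assert float(summary.qalys) == pytest.approx(10_000.0, abs=1e-6)

    def test_two_state_chain_matches_geometric_closed_form(self, no_mortality_table):
        # single cohort in mCRPC: expected years = 1/p (geometric series)
        p = 0.3486
        params = chain_params(tp_mcrpc_to_pca_death=p)
        trace, summary = run_cohort(
            _unit_initial("mcrpc"), params, life_table=no_mortality_table,
            discount_rate=0.0,
        )
        T = trace.n_cycles
        expected = sum((1.0 - p) ** t for t in range(T))
        assert float(summary.life_years) / 1000.0 == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(1.0 / p, abs=1e-9)  # horizon long enough
        occ = trace.occupancy
        analytic = (1.0 - p) ** np.arange(T + 1)
        assert np.allclose(occ[:, IDX["mcrpc"]], analytic, atol=1e-9)

    def test_three_state_chain_matches_analytic_occupancy(self, no_mortality_table):
        # met (ADT+ARSI) -> mCRPC -> death: phase-type closed form
        p1, p2 = 0.1611, 0.3486
        params = chain_params(
            tp_met_adt_arsi_to_mcrpc=p1, tp_mcrpc_to_pca_death=p2
        )
        trace, _ = run_cohort(
            _unit_initial("met_adt_arsi"), params,
            life_table=no_mortality_table, horizon=60, discount_rate=0.0,
        )
        t = np.arange(61)
        occ_met = (1.0 - p1) ** t
        occ_mcrpc = p1 * ((1.0 - p1) ** t - (1.0 - p2) ** t) / (p2 - p1)
        assert np.allclose(trace.occupancy[:, IDX["met_adt_arsi"]], occ_met,
                           atol=1e-9)
        assert np.allclose(trace.occupancy[:, IDX["mcrpc"]], occ_mcrpc, atol=1e-9)

    def test_occupancy_conserved_and_deaths_monotone(self, registry, life_table):
        params = registry.point_set()
        config = StrategyConfig(Strategy.CTBS_ALONE)
        init = allocate_treatment(classify(config, params), params)
        trace, _ = run_cohort(init, params, config, life_table=life_table)
        sums = trace.occupancy.sum(-1)
        assert np.allclose(sums, 1.0, atol=1e-10)
        dead = trace.occupancy[:, IDX["death_pca"]] + trace.occupancy[:, IDX["death_other"]]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_everyone_absorbed_at_lifetime_horizon(self, registry, life_table):
        params = registry.point_set()
        config = StrategyConfig(Strategy.PSMA_ALONE)
        init = allocate_treatment(classify(config, params), params)
        trace, summary = run_cohort(init, params, config, life_table=life_table)
        assert float(np.asarray(summary.all_deaths)) == pytest.approx(1000.0, abs=1e-6)

    def test_qalys_never_exceed_life_years(self, registry, life_table):
        batch = registry.sample(seed=6, n=200)
        for strat in Strategy:
            config = StrategyConfig(strat)
            init = allocate_treatment(classify(config, batch), batch)
            _, summary = run_cohort(init, batch, config, life_table=life_table,
                                    store_trace=False)
            assert np.all(np.asarray(summary.qalys)
                          <= np.asarray(summary.life_years) + 1e-9)

    def test_unit_utilities_and_no_discounting_equate_qalys_and_life_years(
        self, registry, life_table
    ):
        params = registry.point_set()
        for name in params.values:
            if name.startswith("u_"):
                params.values[name] = 1.0
        config = StrategyConfig(Strategy.PSMA_ALONE)
        init = allocate_treatment(classify(config, params), params)
        _, summary = run_cohort(init, params, config, life_table=life_table,
                                discount_rate=0.0, store_trace=False)
        assert float(summary.qalys) == pytest.approx(float(summary.life_years),
                                                     abs=1e-9)

    def test_life_years_strictly_decrease_with_discount_rate(
        self, registry, life_table
    ):
        params = registry.point_set()
        config = StrategyConfig(Strategy.PSMA_ALONE)
        init = allocate_treatment(classify(config, params), params)
        lys = []
        for r in (0.0, 0.015, 0.03, 0.06):
            _, s = run_cohort(init, params, config, life_table=life_table,
                              discount_rate=r, store_trace=False)
            lys.append(float(s.life_years))
        assert all(a > b for a, b in zip(lys, lys[1:]))

    def test_half_cycle_correction_reduces_accrual_for_declining_cohort(
        self, registry, life_table
    ):
        params = registry.point_set()
        config = StrategyConfig(Strategy.PSMA_ALONE)
        init = allocate_treatment(classify(config, params), params)
        _, full = run_cohort(init, params, config, life_table=life_table,
                             store_trace=False)
        _, half = run_cohort(init, params, config, life_table=life_table,
                             half_cycle=True, store_trace=False)
        assert float(half.life_years) < float(full.life_years)

    def test_unnormalized_initial_distribution_rejected(
        self, point_params, life_table
    ):
        occ = np.zeros(N_STATES)
        occ[0] = 0.7
        bad = InitialDistribution(Strategy.PSMA_ALONE, occ)
        with pytest.raises(ValueError, match="normalized"):
            run_cohort(bad, point_params, life_table=life_table)


@pytest.fixture(scope="module")
def base_summaries(registry, life_table):
    params = registry.point_set()
    out = {}
    for strat in Strategy:
        config = StrategyConfig(strat)
        init = allocate_treatment(classify(config, params), params)
        _, out[strat] = run_cohort(init, params, config,
                                   life_table=life_table, store_trace=False)
    return out


class TestStrategyComparison:
    def test_identical_summaries_give_zero_deltas(self, base_summaries):
        same = {s: base_summaries[Strategy.CTBS_ALONE] for s in Strategy}
        deltas = compare_strategies(same)
        assert np.allclose(deltas[["d_life_years", "d_qalys", "d_pca_deaths"]], 0.0)

    def test_psma_strategies_beat_conventional_imaging_at_base_case(
        self, base_summaries
    ):
        deltas = compare_strategies(base_summaries)
        for strat in ("psma", "reflex"):
            assert deltas.loc[strat, "d_life_years"] > 0
            assert deltas.loc[strat, "d_qalys"] > 0
            assert deltas.loc[strat, "d_pca_deaths"] < 0

    def test_strategy_ordering_in_life_years_and_qalys(self, base_summaries):
        eps = 1e-9  # strategies 1 and 2 can tie to rounding in life-years
        ly = {s: float(np.asarray(o.life_years)) for s, o in base_summaries.items()}
        qa = {s: float(np.asarray(o.qalys)) for s, o in base_summaries.items()}
        assert ly[Strategy.PSMA_ALONE] >= ly[Strategy.PSMA_REFLEX] - eps
        assert ly[Strategy.PSMA_REFLEX] >= ly[Strategy.CTBS_ALONE] - eps
        assert qa[Strategy.PSMA_ALONE] >= qa[Strategy.PSMA_REFLEX] - eps
        assert qa[Strategy.PSMA_REFLEX] >= qa[Strategy.CTBS_ALONE] - eps

    def test_mismatched_horizons_rejected(self, registry, life_table):
        params = registry.point_set()
        config = StrategyConfig(Strategy.PSMA_ALONE)
        init = allocate_treatment(classify(config, params), params)
        _, a = run_cohort(init, params, config, life_table=life_table,
                          horizon=10, store_trace=False)
        _, b = run_cohort(init, params, config, life_table=life_table,
                          horizon=20, store_trace=False)
        b = type(b)(**{**b.__dict__, "strategy": Strategy.CTBS_ALONE})
        with pytest.raises(ValueError, match="horizon"):
            compare_strategies({Strategy.PSMA_ALONE: a, Strategy.CTBS_ALONE: b})
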