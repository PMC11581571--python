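"""Decision-tree cohort allocation under the three imaging strategies."""

import numpy as np
import pytest

from psmapet.parameters import ParameterSet
from psmapet.states import IDX
from psmapet.tree import (
    Strategy,
    StrategyConfig,
    allocate_treatment,
    classify,
    detection_counts,
    treatment_initiation,
)


@pytest.fixture(params=list(Strategy), ids=[s.value for s in Strategy])
def any_config(request):
    return StrategyConfig(request.param)


class TestClassify:
    def test_upfront_psma_is_exact_true_state_allocation(self, point_params):
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), point_params)
        assert float(pre.tp_localized) == pytest.approx(0.752 * 0.1861, abs=1e-9)
        assert float(pre.tp_metastatic) == pytest.approx(0.752 * 0.8139, abs=1e-9)
        assert float(pre.true_negative) == pytest.approx(0.248, abs=1e-9)
        assert float(pre.fn_localized) == 0.0 and float(pre.fp_localized) == 0.0

    def test_reflex_true_negative_mass_is_free_times_specificity(self, point_params):
        pre = classify(StrategyConfig(Strategy.PSMA_REFLEX), point_params)
        assert float(pre.true_negative) == pytest.approx(0.248 * 0.91, abs=1e-9)

    def test_perfect_conventional_imaging_collapses_all_strategies(self, point_params):
        perfect = ParameterSet(dict(point_params.values))
        perfect.values["sens_ctbs"] = 1.0
        perfect.values["spec_ctbs"] = 1.0
        pres = {
            s: classify(StrategyConfig(s), perfect) for s in Strategy
        }
        ref = pres[Strategy.PSMA_ALONE]
        for pre in pres.values():
            for f in pre._COMPONENTS:
                assert float(getattr(pre, f)) == pytest.approx(
                    float(getattr(ref, f)), abs=1e-12
                )

    def test_fn_mass_is_diseased_times_one_minus_sensitivity(self, point_params):
        pre = classify(StrategyConfig(Strategy.CTBS_ALONE), point_params)
        diseased = 0.752
        sens = 0.38
        fn = float(pre.fn_localized) + float(pre.fn_metastatic)
        assert fn == pytest.approx(diseased * (1 - sens), abs=1e-12)

    def test_fp_mass_is_disease_free_times_one_minus_specificity(self, point_params):
        for strat in (Strategy.PSMA_REFLEX, Strategy.CTBS_ALONE):
            pre = classify(StrategyConfig(strat), point_params)
            fp = float(pre.fp_localized) + float(pre.fp_metastatic)
            assert fp == pytest.approx(0.248 * 0.09, abs=1e-12)

    def test_higher_sensitivity_strictly_reduces_fn_mass(self, point_params):
        masses = []
        for sens in (0.2, 0.38, 0.6, 0.9):
            p = ParameterSet(dict(point_params.values))
            p.values["sens_ctbs"] = sens
            pre = classify(StrategyConfig(Strategy.CTBS_ALONE), p)
            masses.append(float(pre.fn_localized) + float(pre.fn_metastatic))
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_mass_conserved_for_every_strategy(self, any_config, point_params):
        pre = classify(any_config, point_params)
        assert float(pre.total()) == pytest.approx(1.0, abs=1e-12)

    def test_mass_conserved_under_sampled_batches(self, registry, any_config):
        batch = registry.sample(seed=2, n=500)
        pre = classify(any_config, batch)
        assert np.allclose(pre.total(), 1.0, atol=1e-12)

    def test_out_of_range_probability_rejected(self, point_params):
        bad = ParameterSet(dict(point_params.values))
        bad.values["spec_ctbs"] = 1.2
        with pytest.raises(ValueError, match="spec_ctbs"):
            classify(StrategyConfig(Strategy.CTBS_ALONE), bad)


class TestAllocateTreatment:
    def test_localized_no_treatment_mass_matches_hand_product(self, point_params):
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), point_params)
        init = allocate_treatment(pre, point_params)
        occ = np.asarray(init.occupancy)
        # 0.752 * 0.1861 * 0.3366, printed as 47/1000
        assert occ[IDX["loc_no_treatment"]] == pytest.approx(0.0471, abs=5e-4)

    def test_mdt_mass_matches_hand_product(self, point_params):
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), point_params)
        init = allocate_treatment(pre, point_params)
        occ = np.asarray(init.occupancy)
        # 0.752 * 0.8139 * 0.2038, printed as 125/1000
        assert occ[IDX["met_mdt"]] == pytest.approx(0.1247, abs=5e-4)

    def test_degenerate_split_sends_all_mass_to_one_state(self, point_params):
        p = ParameterSet(dict(point_params.values))
        p.values["tx_loc_no_treatment"] = 1.0
        p.values["tx_loc_local"] = 0.0
        p.values["tx_loc_systemic"] = 0.0
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), p)
        init = allocate_treatment(pre, p)
        occ = np.asarray(init.occupancy)
        assert occ[IDX["loc_no_treatment"]] == pytest.approx(
            float(pre.tp_localized), abs=1e-12
        )
        assert occ[IDX["loc_local"]] == 0.0 and occ[IDX["loc_systemic"]] == 0.0

    def test_invalid_split_rejected(self, point_params):
        p = ParameterSet(dict(point_params.values))
        p.values["tx_met_systemic"] = 0.9  # mdt still 0.2038: sums to 1.1
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), p)
        with pytest.raises(ValueError, match="sum to 1"):
            allocate_treatment(pre, p)

    def test_initial_distribution_normalized(self, any_config, registry):
        batch = registry.sample(seed=2, n=200)
        init = allocate_treatment(classify(any_config, batch), batch)
        assert np.allclose(np.asarray(init.occupancy).sum(-1), 1.0, atol=1e-12)

    def test_fn_states_populated_only_under_ctbs_alone(self, point_params):
        for strat in Strategy:
            init = allocate_treatment(
                classify(StrategyConfig(strat), point_params), point_params
            )
            occ = np.asarray(init.occupancy)
            fn = occ[IDX["fn_localized"]] + occ[IDX["fn_metastatic"]]
            if strat is Strategy.CTBS_ALONE:
                assert fn > 0
            else:
                assert fn == 0.0


class TestReportingSurfaces:
    def test_ctbs_apparent_no_disease_includes_missed_disease(self, point_params):
        pre = classify(StrategyConfig(Strategy.CTBS_ALONE), point_params)
        counts = detection_counts(pre)
        # true negatives (0.248 * 0.91) plus false negatives (0.752 * 0.62)
        assert float(counts["no_radiographic_disease"]) == pytest.approx(692, abs=1)

    def test_treatment_initiation_applies_splits_to_apparent_masses(
        self, point_params
    ):
        pre = classify(StrategyConfig(Strategy.PSMA_ALONE), point_params)
        t = treatment_initiation(pre, point_params)
        assert float(t["nd_no_treatment"]) == pytest.approx(
            248 * 0.5463, abs=0.5
        )
        assert float(t["met_systemic_therapy"]) == pytest.approx(
            612.1 * 0.7962, abs=0.5
        )
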