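import numpy as np
import pytest

from psmapet import load_default_parameters
from psmapet.parameters import ParameterSet
from psmapet.synthetic import LifeTable, default_life_table


@pytest.fixture(scope="session")
def registry():
    return load_default_parameters()


@pytest.fixture(scope="session")
def point_params(registry):
    return registry.point_set()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture()
def no_mortality_table():
    """Life table with (numerically) no background mortality, for oracles."""
    age = np.arange(66, 366)
    qx = np.zeros(len(age))
    qx[-1] = 1.0
    return LifeTable(age=age, qx=qx)


def chain_params(**overrides) -> ParameterSet:
    """Minimal parameter set with all disease transitions switched off.

    Tests override individual probabilities to isolate small analytic chains
    inside the full state space.
    """
    values = {
        "median_age": 66.0,
        "discount_rate": 0.0,
        "p_detect_psma": 0.752,
        "p_no_disease_psma": 0.248,
        "p_localized_given_detected": 0.1861,
        "p_metastatic_given_detected": 0.8139,
        "tp_nd_to_localized": 0.0,
        "tp_nd_to_metastatic": 0.0,
        "tp_loc_local_to_nd_after": 0.0,
        "tp_loc_no_tx_to_metastatic": 0.0,
        "tp_loc_local_to_metastatic": 0.0,
        "tp_loc_systemic_to_metastatic": 0.0,
        "tp_nd_after_to_metastatic": 0.0,
        "tp_met_adt_arsi_to_mcrpc": 0.0,
        "tp_mcrpc_to_pca_death": 0.0,
        "tx_nd_no_treatment": 1.0,
        "tx_nd_radiation": 0.0,
        "tx_nd_systemic": 0.0,
        "tx_loc_no_treatment": 1.0,
        "tx_loc_local": 0.0,
        "tx_loc_systemic": 0.0,
        "tx_loc_local_prostatectomy": 1.0,
        "tx_loc_local_radiation": 0.0,
        "tx_loc_local_cryotherapy": 0.0,
        "tx_met_systemic": 1.0,
        "tx_met_mdt": 0.0,
        "hr_mdt": 1.0,
        "hr_early_vs_delayed": 1.0,
        "hr_fn_progression": 1.0,
        "sens_ctbs": 0.38,
        "spec_ctbs": 0.91,
        "u_no_disease": 1.0,
        "u_no_disease_after_localized": 1.0,
        "u_loc_no_treatment": 1.0,
        "u_loc_local": 1.0,
        "u_loc_systemic": 1.0,
        "u_met_adt_arsi": 1.0,
        "u_met_mdt": 1.0,
        "u_mcrpc": 1.0,
    }
    values.update(overrides)
    return ParameterSet(values, provenance="test-chain")
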