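"""Health-state space shared by the decision tree and the Markov engine.

States combine the disease compartment with the treatment profile assigned at
imaging. False-negative (FN) compartments exist only under conventional
imaging alone; false-positive (FP) compartments carry the treatment/utility
profile of the wrongly assigned state while retaining the transition dynamics
of their true state (no radiographic disease).
"""

from __future__ import annotations

import numpy as np

STATES = (
    "nd_no_treatment",        # 0  no radiographic disease, no treatment
    "nd_radiation",           # 1  no radiographic disease, local radiation
    "nd_systemic",            # 2  no radiographic disease, systemic therapy
    "loc_no_treatment",       # 3  localized disease, no treatment
    "loc_local",              # 4  localized disease, local treatment
    "loc_systemic",           # 5  localized disease, systemic treatment
    "nd_after_localized",     # 6  no radiographic disease after localized
    "met_adt_arsi",           # 7  metastatic, ADT + ARSI
    "met_mdt",                # 8  metastatic, metastasis-directed treatment
    "mcrpc",                  # 9  metastatic castration-resistant
    "death_pca",              # 10 death from prostate cancer
    "death_other",            # 11 death from other causes
    "fn_localized",           # 12 localized disease, false-negative imaging
    "fn_metastatic",          # 13 metastatic disease, false-negative imaging
    "fp_loc_no_treatment",    # 14 disease-free, managed as localized/no tx
    "fp_loc_local",           # 15 disease-free, managed as localized/local
    "fp_loc_systemic",        # 16 disease-free, managed as localized/systemic
    "fp_met_systemic",        # 17 disease-free, managed as metastatic/systemic
    "fp_met_mdt",             # 18 disease-free, managed as metastatic/MDT
)

N_STATES = len(STATES)
IDX = {name: i for i, name in enumerate(STATES)}

DEATH_STATES = (IDX["death_pca"], IDX["death_other"])
ALIVE = np.array([i for i in range(N_STATES) if i not in DEATH_STATES])

#: states whose transition row is that of "no radiographic disease"
ND_DYNAMICS = np.array(
    [IDX[s] for s in (
        "nd_no_treatment", "nd_radiation", "nd_systemic",
        "fp_loc_no_treatment", "fp_loc_local", "fp_loc_systemic",
        "fp_met_systemic", "fp_met_mdt",
    )]
)

#: per-state utility parameter names (death states have utility zero)
UTILITY_PARAM = {
    "nd_no_treatment": "u_no_disease",
    "nd_radiation": "u_no_disease",
    "nd_systemic": "u_no_disease",
    "loc_no_treatment": "u_loc_no_treatment",
    "loc_local": "u_loc_local",
    "loc_systemic": "u_loc_systemic",
    "nd_after_localized": "u_no_disease_after_localized",
    "met_adt_arsi": "u_met_adt_arsi",
    "met_mdt": "u_met_mdt",
    "mcrpc": "u_mcrpc",
    # utility attaches to the underlying disease state, detected or not:
    # undiagnosed localized disease is untreated localized disease; the
    # metastatic-disease utility row stands in for undiagnosed metastasis
    "fn_localized": "u_loc_no_treatment",
    "fn_metastatic": "u_met_adt_arsi",
    # false positives occupy the utility profile of the assigned state
    "fp_loc_no_treatment": "u_loc_no_treatment",
    "fp_loc_local": "u_loc_local",
    "fp_loc_systemic": "u_loc_systemic",
    "fp_met_systemic": "u_met_adt_arsi",
    "fp_met_mdt": "u_met_mdt",
}
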