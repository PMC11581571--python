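"""Diagnostic decision tree: cohort allocation into entry health states.

Three strategies are compared for a cohort imaged at biochemical recurrence:

1. ``PSMA_ALONE``   - upfront PSMA-PET, treated as the criterion standard
                      (true positives and true negatives only);
2. ``PSMA_REFLEX``  - CT + bone scan (CTBS) first, PSMA-PET reflex if CTBS is
                      negative/equivocal: every truly diseased patient is
                      eventually detected, but positive CTBS reads include
                      false positives among the disease-free;
3. ``CTBS_ALONE``   - conventional imaging only: true/false positives and
                      true/false negatives all occur.

False positives are classified localized vs metastatic in proportion to the
true disease mix; false negatives enter dedicated undetected-disease states
with a per-year probability of later correct identification.

All operations broadcast over a leading batch axis, so a sampled batch of
parameter sets yields batched allocations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .states import IDX, N_STATES, STATES

__all__ = [
    "Strategy",
    "StrategyConfig",
    "PreTreatmentDistribution",
    "InitialDistribution",
    "classify",
    "allocate_treatment",
    "treatment_initiation",
    "detection_counts",
]


class Strategy(str, Enum):
    PSMA_ALONE = "psma"
    PSMA_REFLEX = "reflex"
    CTBS_ALONE = "ctbs"


@dataclass(frozen=True)
class StrategyConfig:
    strategy: Strategy
    fn_detection_rate: float = 0.10  # per-year later identification of FNs
    fp_classification_rule: str = "proportional_to_disease_mix"

    def __post_init__(self):
        if not 0.0 <= self.fn_detection_rate <= 1.0:
            raise ValueError("fn_detection_rate must lie in [0, 1]")
        if self.fp_classification_rule != "proportional_to_disease_mix":
            raise ValueError(
                f"unknown fp_classification_rule {self.fp_classification_rule!r}"
            )


@dataclass
class PreTreatmentDistribution:
    """Cohort mass by true disease status and test result (pre-treatment).

    Fields are floats or arrays broadcast over a batch axis and sum to 1.
    """

    strategy: Strategy
    true_negative: np.ndarray      # disease-free, read as no disease
    tp_localized: np.ndarray       # localized disease, detected
    tp_metastatic: np.ndarray      # metastatic disease, detected
    fp_localized: np.ndarray       # disease-free, read as localized
    fp_metastatic: np.ndarray      # disease-free, read as metastatic
    fn_localized: np.ndarray       # localized disease, missed
    fn_metastatic: np.ndarray      # metastatic disease, missed

    _COMPONENTS = (
        "true_negative", "tp_localized", "tp_metastatic",
        "fp_localized", "fp_metastatic", "fn_localized", "fn_metastatic",
    )

    def total(self) -> np.ndarray:
        return sum(np.asarray(getattr(self, f)) for f in self._COMPONENTS)

    # apparent (as-imaged) categories: this is the report surface, so missed
    # disease counts as "no radiographic disease"
    @property
    def apparent_no_disease(self) -> np.ndarray:
        return self.true_negative + self.fn_localized + self.fn_metastatic

    @property
    def apparent_localized(self) -> np.ndarray:
        return self.tp_localized + self.fp_localized

    @property
    def apparent_metastatic(self) -> np.ndarray:
        return self.tp_metastatic + self.fp_metastatic


@dataclass
class InitialDistribution:
    """Entry-state occupancy after treatment allocation (sums to 1)."""

    strategy: Strategy
    occupancy: np.ndarray  # shape (..., N_STATES)

    def per_1000(self) -> pd.Series:
        occ = np.asarray(self.occupancy)
        if occ.ndim > 1:
            occ = occ.mean(axis=tuple(range(occ.ndim - 1)))
        return pd.Series(occ * 1000.0, index=list(STATES), name=self.strategy.value)

    def to_csv(self, path) -> None:
        self.per_1000().rename_axis("state").to_frame("per_1000").to_csv(path)


def _check_prob(name: str, value) -> np.ndarray:
    value = np.asarray(value, dtype=float)
    if np.any((value < 0) | (value > 1)):
        raise ValueError(f"{name} outside [0, 1]")
    return value


def classify(
    config: StrategyConfig, params: ParameterSet
) -> PreTreatmentDistribution:
    """Allocate the cohort by true disease status and imaging result."""
    d = _check_prob("p_detect_psma", params["p_detect_psma"])
    m = _check_prob("p_metastatic_given_detected",
                    params["p_metastatic_given_detected"])
    loc = d * (1.0 - m)          # true localized disease prevalence
    met = d * m                  # true metastatic disease prevalence
    free = 1.0 - d               # truly disease-free

    def build(tn, tpl, tpm, fpl=0.0, fpm=0.0, fnl=0.0, fnm=0.0):
        parts = np.broadcast_arrays(
            *(np.asarray(x, dtype=float) for x in (tn, tpl, tpm, fpl, fpm, fnl, fnm))
        )
        return PreTreatmentDistribution(config.strategy, *(p.copy() for p in parts))

    if config.strategy is Strategy.PSMA_ALONE:
        # criterion standard: exact true-state allocation
        return build(free, loc, met)

    spec = _check_prob("spec_ctbs", params["spec_ctbs"])
    fp = free * (1.0 - spec)
    # false positives split localized : metastatic as the true disease mix
    fp_loc = fp * (1.0 - m)
    fp_met = fp * m

    if config.strategy is Strategy.PSMA_REFLEX:
        # every truly diseased patient is detected (CTBS-positive or reflex
        # PSMA after a negative/equivocal CTBS) and correctly classified
        return build(free * spec, loc, met, fp_loc, fp_met)

    sens = _check_prob("sens_ctbs", params["sens_ctbs"])
    return build(
        free * spec, loc * sens, met * sens, fp_loc, fp_met,
        loc * (1.0 - sens), met * (1.0 - sens),
    )


def _split(params: ParameterSet, names: tuple[str, ...]) -> list[np.ndarray]:
    """Fetch a management split, normalising away printed rounding (<=0.005)."""
    parts = [np.asarray(params[n], dtype=float) for n in names]
    total = sum(parts)
    if np.any(np.abs(total - 1.0) > 0.005):
        raise ValueError(f"treatment split {names} does not sum to 1")
    return [p / total for p in parts]


_ND_SPLIT = ("tx_nd_no_treatment", "tx_nd_radiation", "tx_nd_systemic")
_LOC_SPLIT = ("tx_loc_no_treatment", "tx_loc_local", "tx_loc_systemic")
_MET_SPLIT = ("tx_met_systemic", "tx_met_mdt")


def allocate_treatment(
    pre: PreTreatmentDistribution, params: ParameterSet
) -> InitialDistribution:
    """Multiply each detected-finding mass through its management split.

    False-negative compartments receive no treatment allocation until they
    are identified in a later cycle; false positives receive the assigned
    state's management (localized or metastatic split).
    """
    nd = _split(params, _ND_SPLIT)
    lc = _split(params, _LOC_SPLIT)
    mt = _split(params, _MET_SPLIT)
    # local-modality sub-split (prostatectomy/radiation/cryotherapy) is
    # recorded bookkeeping within the same health state; validated only
    if all(n in params for n in
           ("tx_loc_local_prostatectomy", "tx_loc_local_radiation",
            "tx_loc_local_cryotherapy")):
        _split(params, ("tx_loc_local_prostatectomy", "tx_loc_local_radiation",
                        "tx_loc_local_cryotherapy"))

    shape = np.shape(pre.total())
    occ = np.zeros(shape + (N_STATES,))
    tn = np.asarray(pre.true_negative)
    occ[..., IDX["nd_no_treatment"]] = tn * nd[0]
    occ[..., IDX["nd_radiation"]] = tn * nd[1]
    occ[..., IDX["nd_systemic"]] = tn * nd[2]
    tl = np.asarray(pre.tp_localized)
    occ[..., IDX["loc_no_treatment"]] = tl * lc[0]
    occ[..., IDX["loc_local"]] = tl * lc[1]
    occ[..., IDX["loc_systemic"]] = tl * lc[2]
    tm = np.asarray(pre.tp_metastatic)
    occ[..., IDX["met_adt_arsi"]] = tm * mt[0]
    occ[..., IDX["met_mdt"]] = tm * mt[1]
    fl = np.asarray(pre.fp_localized)
    occ[..., IDX["fp_loc_no_treatment"]] = fl * lc[0]
    occ[..., IDX["fp_loc_local"]] = fl * lc[1]
    occ[..., IDX["fp_loc_systemic"]] = fl * lc[2]
    fm = np.asarray(pre.fp_metastatic)
    occ[..., IDX["fp_met_systemic"]] = fm * mt[0]
    occ[..., IDX["fp_met_mdt"]] = fm * mt[1]
    occ[..., IDX["fn_localized"]] = pre.fn_localized
    occ[..., IDX["fn_metastatic"]] = pre.fn_metastatic

    total = occ.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-9):
        raise ValueError("initial distribution does not sum to 1")
    return InitialDistribution(pre.strategy, occ)


def detection_counts(pre: PreTreatmentDistribution) -> dict[str, np.ndarray]:
    """Disease-detection report per 1000 (apparent, as-imaged categories)."""
    return {
        "no_radiographic_disease": pre.apparent_no_disease * 1000.0,
        "localized_disease": pre.apparent_localized * 1000.0,
        "metastatic_disease": pre.apparent_metastatic * 1000.0,
    }


def treatment_initiation(
    pre: PreTreatmentDistribution, params: ParameterSet
) -> dict[str, np.ndarray]:
    """Treatment-initiation report per 1000 patients imaged.

    Management splits apply to the apparent finding categories: patients with
    false imaging results are managed like those with the same (true) reads.
    """
    nd = _split(params, _ND_SPLIT)
    lc = _split(params, _LOC_SPLIT)
    mt = _split(params, _MET_SPLIT)
    a_nd = pre.apparent_no_disease * 1000.0
    a_loc = pre.apparent_localized * 1000.0
    a_met = pre.apparent_metastatic * 1000.0
    return {
        "nd_no_treatment": a_nd * nd[0],
        "nd_local_treatment": a_nd * nd[1],
        "nd_systemic_therapy": a_nd * nd[2],
        "loc_no_treatment": a_loc * lc[0],
        "loc_local_treatment": a_loc * lc[1],
        "loc_systemic_therapy": a_loc * lc[2],
        "met_systemic_therapy": a_met * mt[0],
        "met_mdt": a_met * mt[1],
    }
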