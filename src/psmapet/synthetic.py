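"""Synthetic model inputs: background mortality and an institutional cohort.

Two inputs the analysis assumes are not printed anywhere and are generated
here so every stage of the model runs self-contained:

* an age-indexed all-cause mortality schedule for males from age 66, built
  from a Gompertz hazard calibrated to a period life expectancy at 66 of
  about 17 years, and
* a per-patient cohort (PSA level, imaging-finding category, management
  category) whose aggregate frequencies match the published institutional
  point estimates, closing the loop counts -> beta/Dirichlet parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .parameters import (
    ParameterRegistry,
    ParameterSpec,
    load_default_parameters,
)

__all__ = [
    "LifeTable",
    "SyntheticCohort",
    "make_life_table",
    "calibrate_gompertz_level",
    "default_life_table",
    "generate_cohort",
    "estimate_registry_from_cohort",
    "stratum_finding_probabilities",
    "PSA_STRATA",
    "DEFAULT_PSA_MIX",
]

START_AGE = 66
END_AGE = 110

#: a-priori PSA categories (ng/mL) used by the stratified scenario analyses
PSA_STRATA = ("0-1.99", "2.00-4.99", ">=5.00")
_STRATUM_BOUNDS = {"0-1.99": (0.2, 1.99), "2.00-4.99": (2.0, 4.99),
                   ">=5.00": (5.0, 25.0)}

#: default stratum mix, chosen so the cohort's median PSA is ~1.8 ng/mL
DEFAULT_PSA_MIX = (0.52, 0.33, 0.15)

#: logit shifts making detection / metastatic-given-detected increase with PSA
DEFAULT_DETECTION_SHIFTS = (-0.45, 0.35, 0.90)
DEFAULT_METASTATIC_SHIFTS = (-0.30, 0.30, 0.70)

FINDINGS = ("none", "localized", "metastatic")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability ``qx`` by integer age."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        if len(self.age) != len(self.qx):
            raise ValueError("age and qx must have equal length")
        # zero rows are permitted so analytic no-mortality oracles can run;
        # generated tables always have qx > 0
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("qx must lie in [0, 1]")

    def qx_at(self, age: int) -> float:
        idx = int(age) - int(self.age[0])
        if idx < 0 or idx >= len(self.qx):
            raise ValueError(f"age {age} outside life table range")
        return float(self.qx[idx])

    def survival(self) -> np.ndarray:
        """S(t): probability of surviving t whole years past the first age."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])

    def life_expectancy(self) -> float:
        """Period life expectancy at the table's first age.

        Curtate expectation plus a half year for the year of death.
        """
        s = self.survival()
        return float(s[1:].sum() + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(age=df["age"].to_numpy(int), qx=df["qx"].to_numpy(float))


def make_life_table(
    level_param: float,
    slope_param: float,
    start_age: int = START_AGE,
    end_age: int = END_AGE,
) -> LifeTable:
    """Gompertz mortality schedule ``qx = 1 - exp(-a * exp(b (age - 66)))``.

    ``level_param`` (a) sets mortality at the start age; ``slope_param`` (b)
    its exponential rise with age. The final age is closed out at qx = 1.
    """
    if level_param <= 0 or slope_param < 0:
        raise ValueError("level_param must be > 0 and slope_param >= 0")
    age = np.arange(start_age, end_age + 1)
    qx = 1.0 - np.exp(-level_param * np.exp(slope_param * (age - start_age)))
    qx = np.minimum(qx, 1.0)
    if qx[0] >= 0.2:
        raise ValueError(
            f"implausible schedule: qx({start_age}) = {qx[0]:.3f} >= 0.2"
        )
    qx[-1] = 1.0  # closure: nobody survives past the table
    return LifeTable(age=age, qx=qx)


def calibrate_gompertz_level(
    target_life_expectancy: float = 17.0, slope_param: float = 0.09
) -> float:
    """Level parameter giving the requested life expectancy at age 66."""

    def gap(log_level: float) -> float:
        lt = make_life_table(np.exp(log_level), slope_param)
        return lt.life_expectancy() - target_life_expectancy

    log_level = optimize.brentq(gap, np.log(1e-5), np.log(0.15))
    return float(np.exp(log_level))


@lru_cache(maxsize=8)
def _default_level(target: float, slope: float) -> float:
    return calibrate_gompertz_level(target, slope)


def default_life_table(
    target_life_expectancy: float = 17.0, slope_param: float = 0.09
) -> LifeTable:
    """Calibrated default background-mortality table (male, from age 66)."""
    return make_life_table(
        _default_level(target_life_expectancy, slope_param), slope_param
    )


# ---------------------------------------------------------------------------
# synthetic institutional cohort
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def stratum_finding_probabilities(
    registry: ParameterRegistry | None = None,
    psa_mix=DEFAULT_PSA_MIX,
    detection_shifts=DEFAULT_DETECTION_SHIFTS,
    metastatic_shifts=DEFAULT_METASTATIC_SHIFTS,
) -> pd.DataFrame:
    """Per-stratum imaging-finding probabilities, monotone in PSA.

    Detection and metastatic-given-detected probabilities are shifted on the
    logit scale per stratum, plus a common offset solved so that the
    mix-weighted average reproduces the overall registry point exactly.
    """
    registry = registry or load_default_parameters()
    mix = np.asarray(psa_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"psa_mix must sum to 1, got {mix.sum()}")

    def adjusted(point: float, shifts) -> np.ndarray:
        base = _logit(point)
        shifts = np.asarray(shifts, dtype=float)

        def gap(c):
            return float(mix @ _expit(base + shifts + c) - point)

        c = optimize.brentq(gap, -5.0, 5.0)
        return _expit(base + shifts + c)

    p_detect = adjusted(registry["p_detect_psma"].point, detection_shifts)
    p_met = adjusted(registry["p_metastatic_given_detected"].point,
                     metastatic_shifts)
    return pd.DataFrame(
        {
            "stratum": list(PSA_STRATA),
            "weight": mix,
            "p_detect": p_detect,
            "p_metastatic_given_detected": p_met,
        }
    )


@dataclass
class SyntheticCohort:
    """Per-patient synthetic cohort at the moment of imaging."""

    data: pd.DataFrame  # columns: psa_level, psa_stratum, finding, management

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SyntheticCohort":
        return cls(pd.read_csv(path))


_ND_MANAGEMENT = ("no_treatment", "radiation", "systemic")
_LOC_MANAGEMENT = ("no_treatment", "local", "systemic")
_MET_MANAGEMENT = ("systemic", "mdt")


def generate_cohort(
    n: int,
    registry: ParameterRegistry | None = None,
    psa_mix=DEFAULT_PSA_MIX,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate ``n`` patients (PSA level, imaging finding, management).

    PSA levels are log-uniform within each a-priori stratum; imaging findings
    use the stratum-adjusted detection probabilities (mix-weighted average
    equal to the overall registry point); management is drawn from the
    finding-conditional allocation splits.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    registry = registry or load_default_parameters()
    probs = stratum_finding_probabilities(registry, psa_mix)
    ps = registry.point_set()
    rng = np.random.default_rng(seed)

    stratum_idx = rng.choice(len(PSA_STRATA), size=n, p=probs["weight"].to_numpy())
    lo = np.array([_STRATUM_BOUNDS[s][0] for s in PSA_STRATA])[stratum_idx]
    hi = np.array([_STRATUM_BOUNDS[s][1] for s in PSA_STRATA])[stratum_idx]
    psa = np.exp(rng.uniform(np.log(lo), np.log(hi)))

    p_det = probs["p_detect"].to_numpy()[stratum_idx]
    p_met = probs["p_metastatic_given_detected"].to_numpy()[stratum_idx]
    detected = rng.random(n) < p_det
    metastatic = detected & (rng.random(n) < p_met)
    finding = np.where(~detected, "none",
                       np.where(metastatic, "metastatic", "localized"))

    management = np.empty(n, dtype=object)
    for mask, cats, names in (
        (finding == "none", _ND_MANAGEMENT,
         ("tx_nd_no_treatment", "tx_nd_radiation", "tx_nd_systemic")),
        (finding == "localized", _LOC_MANAGEMENT,
         ("tx_loc_no_treatment", "tx_loc_local", "tx_loc_systemic")),
        (finding == "metastatic", _MET_MANAGEMENT,
         ("tx_met_systemic", "tx_met_mdt")),
    ):
        k = int(mask.sum())
        if k:
            split = np.array([ps[nm] for nm in names])
            management[mask] = rng.choice(cats, size=k, p=split / split.sum())

    df = pd.DataFrame(
        {
            "psa_level": np.round(psa, 3),
            "psa_stratum": np.array(PSA_STRATA)[stratum_idx],
            "finding": finding,
            "management": management,
        }
    )
    return SyntheticCohort(df)


def _beta_spec(name: str, successes: int, failures: int, base: ParameterSpec,
               group=None) -> ParameterSpec:
    """Beta spec from smoothed event counts (successes+1, failures+1)."""
    a, b = successes + 1, failures + 1
    return dc_replace(
        base,
        point=a / (a + b),
        ui_low=float(stats.beta.ppf(0.025, a, b)),
        ui_high=float(stats.beta.ppf(0.975, a, b)),
    )


def estimate_registry_from_cohort(
    cohort: SyntheticCohort, base_registry: ParameterRegistry | None = None
) -> ParameterRegistry:
    """Re-estimate the institutional registry rows from cohort counts.

    Beta rows use smoothed event counts (successes + 1, failures + 1);
    Dirichlet rows use category counts + 1. Rows not informed by the cohort
    (transition probabilities, hazard ratios, test accuracy, utilities) are
    carried over from ``base_registry``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    base = base_registry or load_default_parameters()
    df = cohort.data
    n = len(df)
    n_det = int((df["finding"] != "none").sum())
    n_met = int((df["finding"] == "metastatic").sum())

    def counts(mask, cats):
        sub = df.loc[mask, "management"].value_counts()
        out = np.array([sub.get(c, 0) for c in cats], dtype=float)
        if (out == 0).any():
            warnings.warn(
                "empty management category in cohort; using smoothed counts",
                stacklevel=2,
            )
        return out + 1.0

    dirichlet_counts = {
        "nd_management": (
            df["finding"] == "none", _ND_MANAGEMENT,
            ("tx_nd_no_treatment", "tx_nd_radiation", "tx_nd_systemic")),
        "localized_management": (
            df["finding"] == "localized", _LOC_MANAGEMENT,
            ("tx_loc_no_treatment", "tx_loc_local", "tx_loc_systemic")),
        "metastatic_management": (
            df["finding"] == "metastatic", _MET_MANAGEMENT,
            ("tx_met_systemic", "tx_met_mdt")),
    }
    new_specs: dict[str, ParameterSpec] = {}
    # detection / site composition as complementary pairs
    pairs = {
        "p_detect_psma": (n_det, n - n_det),
        "p_no_disease_psma": (n - n_det, n_det),
        "p_metastatic_given_detected": (n_met, n_det - n_met),
        "p_localized_given_detected": (n_det - n_met, n_met),
    }
    for name, (succ, fail) in pairs.items():
        new_specs[name] = _beta_spec(name, succ, fail, base[name])

    for group, (mask, cats, names) in dirichlet_counts.items():
        alpha = counts(mask, cats)
        total = alpha.sum()
        for j, name in enumerate(names):
            a = alpha[j]
            new_specs[name] = dc_replace(
                base[name],
                point=a / total,
                ui_low=float(stats.beta.ppf(0.025, a, total - a)),
                ui_high=float(stats.beta.ppf(0.975, a, total - a)),
            )

    specs = [new_specs.get(s.name, s) for s in base]
    # printed-rounding tolerance does not apply to exact count ratios, but
    # pair points are exact complements so group sums remain exactly 1
    return ParameterRegistry(specs)
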