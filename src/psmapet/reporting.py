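"""Rendering of detection/treatment and long-term-outcome tables.

A :class:`Report` pairs a text rendering (counts per 1000 rounded to
integers, with 95% uncertainty intervals when a PSA supplies them) with a
CSV rendering built from the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import Strategy

__all__ = ["Report", "render_tables"]

_STRATEGY_LABEL = {
    "psma": "PSMA-PET alone",
    "reflex": "PSMA-PET if CTBS negative",
    "ctbs": "Conventional imaging alone",
}

_DETECTION_ROWS = [
    ("no_radiographic_disease", "No radiographic disease"),
    ("localized_disease", "Localized disease"),
    ("metastatic_disease", "Metastatic disease"),
]
_TREATMENT_ROWS = [
    ("nd_no_treatment", "No radiographic disease: no treatment"),
    ("nd_local_treatment", "No radiographic disease: local treatment"),
    ("nd_systemic_therapy", "No radiographic disease: systemic therapy"),
    ("loc_no_treatment", "Localized disease: no treatment"),
    ("loc_local_treatment", "Localized disease: local treatment"),
    ("loc_systemic_therapy", "Localized disease: systemic therapy"),
    ("met_systemic_therapy", "Metastatic disease: systemic therapy"),
    ("met_mdt", "Metastatic disease: metastasis-directed treatment"),
]
_OUTCOME_ROWS = [
    ("life_years", "Life-years"),
    ("qalys", "QALYs"),
    ("pca_deaths", "Deaths from prostate cancer"),
]


@dataclass
class Report:
    detection: pd.DataFrame
    treatment: pd.DataFrame
    outcomes: pd.DataFrame | None

    @property
    def text(self) -> str:
        parts = [
            "Disease detection per 1000 patients",
            self.detection.to_string(),
            "",
            "Treatment initiation per 1000 patients",
            self.treatment.to_string(),
        ]
        if self.outcomes is not None:
            parts += ["", "Long-term outcomes per 1000 patients",
                      self.outcomes.to_string()]
        return "\n".join(parts)

    def to_csv(self, path) -> None:
        frames = [
            self.detection.assign(block="detection"),
            self.treatment.assign(block="treatment"),
        ]
        if self.outcomes is not None:
            frames.append(self.outcomes.assign(block="outcomes"))
        pd.concat(frames).rename_axis("variable").to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        frames = [self.detection, self.treatment]
        if self.outcomes is not None:
            frames.append(self.outcomes)
        return pd.concat(frames)


def _cell(mean: float, ui=None) -> str:
    if ui is None:
        return f"{mean:.0f}"
    return f"{mean:.0f} ({ui[0]:.0f}-{ui[1]:.0f})"


def render_tables(results, strategies: tuple[Strategy, ...] | None = None) -> Report:
    """Build detection / treatment / outcome tables from model results.

    ``results`` is either the summary frame of a PSA run (index:
    (strategy, outcome); columns mean/ui_low/ui_high) or a mapping
    ``{strategy value: {outcome: value}}`` from a point run.
    """
    if results is None or (hasattr(results, "empty") and results.empty) or (
        isinstance(results, dict) and not results
    ):
        raise ValueError("cannot render empty results")

    if isinstance(results, pd.DataFrame):
        def get(strat: str, outcome: str):
            try:
                row = results.loc[(strat, outcome)]
            except KeyError:
                return None
            return float(row["mean"]), (float(row["ui_low"]), float(row["ui_high"]))
        strat_values = sorted({s for s, _ in results.index},
                              key=list(_STRATEGY_LABEL).index)
    else:
        def get(strat: str, outcome: str):
            val = results.get(strat, {}).get(outcome)
            return None if val is None else (float(np.asarray(val)), None)
        strat_values = list(results)

    if strategies is not None:
        strat_values = [s.value for s in strategies]
    missing = [s for s in strat_values if get(s, "no_radiographic_disease") is None]
    if missing:
        raise ValueError(f"missing strategy column(s): {missing}")

    def block(rows):
        data = {}
        for strat in strat_values:
            col = []
            for key, _label in rows:
                found = get(strat, key)
                col.append("" if found is None else _cell(found[0], found[1]))
            data[_STRATEGY_LABEL.get(strat, strat)] = col
        return pd.DataFrame(data, index=[label for _k, label in rows])

    detection = block(_DETECTION_ROWS)
    treatment = block(_TREATMENT_ROWS)
    has_outcomes = any(
        get(s, key) is not None for s in strat_values for key, _ in _OUTCOME_ROWS
    )
    outcomes = block(_OUTCOME_ROWS) if has_outcomes else None
    return Report(detection, treatment, outcomes)
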