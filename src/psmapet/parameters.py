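"""Model input registry and uncertainty distributions.

Every model input is a :class:`ParameterSpec`: a point estimate, a 95%
uncertainty interval, and a sampling-distribution family (beta, a member of a
jointly-sampled Dirichlet composition, log-normal for hazard ratios, or fixed).
The registry fits sampling distributions from the printed point + interval and
produces either the deterministic point configuration or reproducible Monte
Carlo draws (:class:`ParameterSet`).

Distribution fitting conventions
--------------------------------
* Beta rows keep the printed point as the exact distribution mean (it drives
  the deterministic run); the single remaining degree of freedom, the
  concentration ``alpha + beta``, is fitted by least squares on the printed
  2.5th/97.5th percentiles.
* Dirichlet groups keep the printed points as the exact mean composition and
  fit one effective-sample-size concentration per group against the printed
  marginal intervals (each marginal of Dirichlet(p * nu) is
  Beta(p_i * nu, (1 - p_i) * nu)).
* Log-normal rows treat the printed hazard-ratio point as the median and fit
  the log-scale sigma by least squares on the interval bounds in log space.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterRegistry",
    "ParameterConfigError",
    "load_default_parameters",
    "fit_beta_from_ui",
    "fit_lognormal_from_ui",
    "fit_dirichlet_concentration",
    "sample_parameter_set",
    "sample_parameter_sets",
    "median_os_to_annual_prob",
]

_FAMILIES = frozenset({"beta", "dirichlet", "lognormal", "fixed"})

#: Tolerance on the sum of a printed Dirichlet composition (printed rounding).
GROUP_SUM_TOL = 0.005


class ParameterConfigError(ValueError):
    """Raised when a parameter file or spec is malformed."""


@dataclass(frozen=True)
class ParameterSpec:
    """One input row: point estimate, 95% UI, and distribution family."""

    name: str
    point: float
    ui_low: float | None = None
    ui_high: float | None = None
    family: str = "fixed"
    group: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterConfigError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        if self.family in ("beta", "dirichlet"):
            if not 0.0 <= self.point <= 1.0:
                raise ParameterConfigError(
                    f"{self.name}: beta/dirichlet point {self.point} outside [0, 1]"
                )
        if self.family == "lognormal" and self.point <= 0:
            raise ParameterConfigError(
                f"{self.name}: log-normal point must be positive, got {self.point}"
            )
        if self.family == "dirichlet" and self.group is None:
            raise ParameterConfigError(f"{self.name}: dirichlet row needs a group")
        if self.ui_low is not None and self.ui_high is not None:
            if not self.ui_low <= self.point <= self.ui_high:
                raise ParameterConfigError(
                    f"{self.name}: point {self.point} outside UI "
                    f"({self.ui_low}, {self.ui_high})"
                )

    @property
    def has_ui(self) -> bool:
        return self.ui_low is not None and self.ui_high is not None


@dataclass
class ParameterSet:
    """A complete point or sampled configuration of all model inputs.

    ``values`` maps parameter names to floats (point/single draw) or to
    1-d arrays of length ``n`` (batched draws used by the PSA engine).
    """

    values: dict[str, float | np.ndarray]
    provenance: str = "point"
    n: int | None = None

    def __getitem__(self, name: str) -> float | np.ndarray:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def select(self, index) -> "ParameterSet":
        """Extract one iteration (or a sub-batch) from a batched set."""
        out = {
            k: (np.asarray(v)[index] if np.ndim(v) else v)
            for k, v in self.values.items()
        }
        n = None
        for v in out.values():
            if np.ndim(v):
                n = int(np.shape(v)[0])
        return ParameterSet(out, provenance=self.provenance, n=n)


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

def fit_beta_from_ui(
    point: float, ui_low: float, ui_high: float
) -> tuple[float, float]:
    """Fit Beta shape parameters from a point estimate and 95% interval.

    The mean is pinned to ``point`` exactly; the concentration ``alpha + beta``
    is chosen to minimise the squared distance between the distribution's
    2.5th/97.5th percentiles and ``(ui_low, ui_high)``.
    """
    if not 0.0 < point < 1.0:
        raise ValueError(f"point must lie in (0, 1), got {point}")
    if not 0.0 <= ui_low < ui_high <= 1.0:
        raise ValueError(f"invalid interval ({ui_low}, {ui_high})")
    if not ui_low < point < ui_high:
        raise ValueError(
            f"point {point} outside its uncertainty interval ({ui_low}, {ui_high})"
        )

    def loss(log10_nu: float) -> float:
        nu = 10.0 ** log10_nu
        a, b = point * nu, (1.0 - point) * nu
        qlo, qhi = stats.beta.ppf([0.025, 0.975], a, b)
        return (qlo - ui_low) ** 2 + (qhi - ui_high) ** 2

    res = optimize.minimize_scalar(loss, bounds=(0.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    nu = 10.0 ** res.x
    return point * nu, (1.0 - point) * nu


def fit_lognormal_from_ui(
    point: float, ui_low: float, ui_high: float
) -> tuple[float, float]:
    """Fit (mu, sigma) of a log-normal from a median point and 95% interval.

    The median is pinned to ``point`` (hazard-ratio points are conventionally
    medians/MLEs); sigma minimises the squared log-space distance of
    ``mu +/- 1.96 sigma`` from the printed bounds, which has the closed form
    ``sigma = ln(ui_high / ui_low) / (2 * 1.96)``.
    """
    if point <= 0 or ui_low <= 0 or ui_high <= 0:
        raise ValueError("log-normal inputs must be positive")
    if ui_low >= ui_high:
        raise ValueError(f"invalid interval ({ui_low}, {ui_high})")
    mu = float(np.log(point))
    sigma = float(np.log(ui_high / ui_low) / (2.0 * stats.norm.ppf(0.975)))
    return mu, sigma


def fit_dirichlet_concentration(
    points: np.ndarray, ui_lows: np.ndarray, ui_highs: np.ndarray
) -> float:
    """Fit one total concentration nu for a Dirichlet composition.

    Each marginal of Dirichlet(p * nu) is Beta(p_i nu, (1 - p_i) nu); nu is
    chosen by least squares over all members' printed marginal 95% intervals.
    Returns the effective sample size nu (> 0).
    """
    points = np.asarray(points, dtype=float)
    lows = np.asarray(ui_lows, dtype=float)
    highs = np.asarray(ui_highs, dtype=float)

    def loss(log10_nu: float) -> float:
        nu = 10.0 ** log10_nu
        a = points * nu
        b = (1.0 - points) * nu
        qlo = stats.beta.ppf(0.025, a, b)
        qhi = stats.beta.ppf(0.975, a, b)
        return float(np.sum((qlo - lows) ** 2 + (qhi - highs) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(0.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(10.0 ** res.x)


def median_os_to_annual_prob(median_survival_months: float) -> float:
    """Annual death probability from a median overall survival in months.

    Under an exponential survival assumption the annual probability is
    ``1 - 0.5 ** (12 / median)``.
    """
    if median_survival_months <= 0:
        raise ValueError("median survival must be positive")
    return 1.0 - 0.5 ** (12.0 / median_survival_months)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class ParameterRegistry:
    """Ordered registry of :class:`ParameterSpec` rows with sampling support."""

    def __init__(self, specs: list[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ParameterConfigError(f"duplicate parameter name {spec.name!r}")
            self._specs[spec.name] = spec
        self.validate()

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def groups(self) -> dict[str, list[ParameterSpec]]:
        out: dict[str, list[ParameterSpec]] = {}
        for spec in self:
            if spec.family == "dirichlet":
                out.setdefault(spec.group, []).append(spec)
        return out

    def validate(self) -> None:
        for group, members in self.groups().items():
            total = sum(m.point for m in members)
            if abs(total - 1.0) > GROUP_SUM_TOL:
                raise ParameterConfigError(
                    f"dirichlet group {group!r} points sum to {total:.4f}, not 1"
                )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_yaml(cls, source) -> "ParameterRegistry":
        """Load a registry from a YAML config (path, file object, or string)."""
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def from_yaml_text(cls, text: str) -> "ParameterRegistry":
        return cls._from_mapping(yaml.safe_load(text))

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ParameterRegistry":
        if not isinstance(raw, Mapping) or "parameters" not in raw:
            raise ParameterConfigError("config must contain a 'parameters' list")
        specs = []
        for entry in raw["parameters"]:
            if "name" not in entry:
                raise ParameterConfigError(f"parameter entry missing 'name': {entry}")
            name = entry["name"]
            try:
                scale = entry.get("scale", "value")
                if scale not in ("percent", "value"):
                    raise ParameterConfigError(
                        f"{name}: unknown scale {scale!r}"
                    )
                factor = 0.01 if scale == "percent" else 1.0
                point = float(entry["point"]) * factor
                lo = entry.get("ui_low")
                hi = entry.get("ui_high")
                specs.append(
                    ParameterSpec(
                        name=name,
                        point=point,
                        ui_low=None if lo is None else float(lo) * factor,
                        ui_high=None if hi is None else float(hi) * factor,
                        family=entry.get("family", "fixed"),
                        group=entry.get("group"),
                        description=entry.get("description", ""),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, ParameterConfigError):
                    raise
                raise ParameterConfigError(f"malformed entry for {name!r}: {exc}") from exc
        return cls(specs)

    def to_yaml(self, path) -> None:
        entries = []
        for spec in self:
            entry = {"name": spec.name, "point": spec.point, "family": spec.family,
                     "scale": "value"}
            if spec.has_ui:
                entry["ui_low"] = spec.ui_low
                entry["ui_high"] = spec.ui_high
            if spec.group:
                entry["group"] = spec.group
            if spec.description:
                entry["description"] = spec.description
            entries.append(entry)
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": entries}, fh, sort_keys=False)

    def patch(self, overrides: Mapping[str, float]) -> "ParameterRegistry":
        """Return a copy with point estimates replaced (scenario overrides).

        Patched rows are held fixed at the override value; unknown names are
        rejected. Members of a Dirichlet group are renormalised so the group
        still sums to one.
        """
        unknown = [k for k in overrides if k not in self._specs]
        if unknown:
            raise KeyError(f"unknown parameter(s) in override: {unknown}")
        specs = []
        group_touch = {self._specs[k].group for k in overrides
                       if self._specs[k].family == "dirichlet"}
        new_points = {}
        for grp in group_touch:
            members = [m for m in self if m.group == grp]
            pts = {m.name: overrides.get(m.name, m.point) for m in members}
            total = sum(pts.values())
            for k, v in pts.items():
                new_points[k] = v / total
        for spec in self:
            if spec.name in new_points:
                specs.append(replace(spec, point=new_points[spec.name],
                                     ui_low=None, ui_high=None, family="fixed",
                                     group=None))
            elif spec.name in overrides:
                val = float(overrides[spec.name])
                specs.append(replace(spec, point=val, ui_low=None, ui_high=None,
                                     family="fixed", group=None))
            else:
                specs.append(spec)
        return ParameterRegistry(specs)

    # -- point and sampled configurations -----------------------------------
    def point_set(self) -> ParameterSet:
        """Deterministic configuration: every row at its point estimate.

        Dirichlet groups are renormalised to sum to exactly one (the printed
        points carry rounding error up to ``GROUP_SUM_TOL``).
        """
        values: dict[str, float] = {s.name: s.point for s in self}
        for members in self.groups().values():
            total = sum(m.point for m in members)
            for m in members:
                values[m.name] = m.point / total
        return ParameterSet(values, provenance="point")

    def _sampling_units(self):
        """Canonical ordered list of independent sampling units."""
        units = []
        seen_groups = set()
        for spec in self:
            if spec.family == "dirichlet":
                if spec.group not in seen_groups:
                    seen_groups.add(spec.group)
                    units.append(("group", spec.group))
            else:
                units.append(("param", spec.name))
        return units

    def _fitted(self, name: str):
        """Cache fitted distribution parameters per spec."""
        cache = getattr(self, "_fit_cache", None)
        if cache is None:
            cache = self._fit_cache = {}
        if name not in cache:
            spec = self._specs[name]
            if spec.family == "beta" and spec.has_ui:
                cache[name] = fit_beta_from_ui(spec.point, spec.ui_low, spec.ui_high)
            elif spec.family == "lognormal" and spec.has_ui:
                cache[name] = fit_lognormal_from_ui(
                    spec.point, spec.ui_low, spec.ui_high
                )
            else:
                cache[name] = None
        return cache[name]

    def _group_concentration(self, group: str) -> float:
        cache = getattr(self, "_group_cache", None)
        if cache is None:
            cache = self._group_cache = {}
        if group not in cache:
            members = self.groups()[group]
            total = sum(m.point for m in members)
            pts = np.array([m.point / total for m in members])
            if all(m.has_ui for m in members):
                cache[group] = fit_dirichlet_concentration(
                    pts,
                    np.array([m.ui_low for m in members]),
                    np.array([m.ui_high for m in members]),
                )
            else:
                cache[group] = np.inf
        return cache[group]

    def sample(self, seed: int, n: int) -> ParameterSet:
        """Draw ``n`` independent parameter sets (batched, reproducible).

        Each sampling unit (standalone row or Dirichlet group) has its own
        deterministic stream keyed by ``(seed, unit index)``, so draw ``i`` of
        any parameter does not depend on ``n``.
        """
        values: dict[str, np.ndarray] = {}
        for idx, (kind, key) in enumerate(self._sampling_units()):
            rng = np.random.default_rng([int(seed), idx])
            if kind == "group":
                members = self.groups()[key]
                nu = self._group_concentration(key)
                total = sum(m.point for m in members)
                pts = np.array([m.point / total for m in members])
                if np.isinf(nu):
                    draws = np.tile(pts, (n, 1))
                else:
                    draws = rng.dirichlet(pts * nu, size=n)
                for j, m in enumerate(members):
                    values[m.name] = draws[:, j]
            else:
                spec = self._specs[key]
                if spec.family == "beta" and spec.has_ui:
                    a, b = self._fitted(key)
                    values[key] = rng.beta(a, b, size=n)
                elif spec.family == "lognormal" and spec.has_ui:
                    mu, sigma = self._fitted(key)
                    values[key] = rng.lognormal(mu, sigma, size=n)
                else:  # fixed, or no interval printed: held constant
                    values[key] = np.full(n, spec.point)
        return ParameterSet(values, provenance=f"sampled(seed={seed})", n=n)


def load_default_parameters() -> ParameterRegistry:
    """Registry of all published input rows (the shipped default config)."""
    ref = importlib.resources.files("psmapet").joinpath("data/default_inputs.yaml")
    return ParameterRegistry.from_yaml_text(ref.read_text())


def sample_parameter_sets(
    registry: ParameterRegistry, seed: int, n: int
) -> ParameterSet:
    """Module-level alias for :meth:`ParameterRegistry.sample`."""
    return registry.sample(seed, n)


def sample_parameter_set(
    registry: ParameterRegistry, seed: int, iteration: int = 0
) -> ParameterSet:
    """Single reproducible draw: iteration ``i`` of the seeded batch stream."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    batch = registry.sample(seed, iteration + 1)
    out = batch.select(iteration)
    out.provenance = f"sampled(seed={seed}, iteration={iteration})"
    return out
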