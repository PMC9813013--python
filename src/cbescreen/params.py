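"""Model parameters: typed containers, validation, dot-path access, serialization.

All monetary values are stored in million Vietnamese dong (VND); US dollars are
computed only at reporting time.  Probabilities are per month unless stated
otherwise.  The packaged defaults (see :func:`cbescreen.synthetic.default_parameters`)
describe a cohort of HER2-positive breast-cancer patients diagnosed at mean age
44 in Vietnam, evaluated under a clinical-breast-examination (CBE) screening
scenario versus no screening.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "ParameterError",
    "DFSCurve",
    "LifeTable",
    "MBCMortality",
    "CostInputs",
    "Costs",
    "TreatmentMix",
    "UtilityBands",
    "UtilitySet",
    "EconSettings",
    "ModelParameters",
    "get_path",
    "set_path",
    "iter_paths",
]


class ParameterError(ValueError):
    """Raised when a parameter violates its documented invariant."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value!r}")


# ---------------------------------------------------------------------------
# Disease-free survival curve
# ---------------------------------------------------------------------------

@dataclass
class DFSCurve:
    """Parametric disease-free-survival curve with cure adjustment.

    The curve governs *recurrence* only; death in the DFS states comes from the
    background life table.  ``S(t) = exp(-(t/scale)**shape)`` with time in
    months; ``family='exponential'`` pins ``shape`` to 1 so that ``scale`` is
    the reciprocal of the constant monthly rate.

    A cured fraction ramps from 0 at diagnosis to ``max_cure_rate`` at
    ``cure_threshold`` months (linearly by default, or as a step at the
    threshold when ``cure_ramp='step'``) and multiplies the per-cycle
    recurrence probability by one minus that fraction.  ``mbc_split`` is the
    fraction of recurrences that are metastatic.
    """

    family: str = "weibull"
    shape: float = 0.9
    scale: float = 300.0
    cure_threshold: float = 120.0
    max_cure_rate: float = 0.95
    mbc_split: float = 0.72
    cure_ramp: str = "linear"

    @classmethod
    def exponential(cls, rate: float, **kwargs) -> "DFSCurve":
        """Constant-hazard curve with the given monthly event rate."""
        if rate <= 0:
            raise ParameterError(f"exponential rate must be positive, got {rate!r}")
        return cls(family="exponential", shape=1.0, scale=1.0 / rate, **kwargs)

    @property
    def rate(self) -> float:
        if self.family != "exponential":
            raise AttributeError("rate is defined for exponential curves only")
        return 1.0 / self.scale

    def validate(self) -> None:
        if self.family not in ("weibull", "exponential"):
            raise ParameterError(f"unknown DFS curve family {self.family!r}")
        if self.family == "exponential" and self.shape != 1.0:
            raise ParameterError("exponential curve requires shape == 1")
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError("DFS curve shape and scale must be positive")
        if self.cure_threshold < 0:
            raise ParameterError("cure_threshold must be non-negative")
        _check_prob("max_cure_rate", self.max_cure_rate)
        _check_prob("mbc_split", self.mbc_split)
        if self.cure_ramp not in ("linear", "step"):
            raise ParameterError(f"cure_ramp must be 'linear' or 'step', got {self.cure_ramp!r}")

    # survival / hazard -----------------------------------------------------

    def survival(self, t: float | np.ndarray) -> float | np.ndarray:
        """S(t): probability of remaining event-free at ``t`` months."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ParameterError("survival time must be non-negative")
        out = np.exp(-((t / self.scale) ** self.shape))
        return float(out) if out.ndim == 0 else out

    def cycle_event_probability(self, t: float | np.ndarray) -> float | np.ndarray:
        """Conditional probability of an event in cycle [t, t+1): 1 - S(t+1)/S(t)."""
        t = np.asarray(t, dtype=float)
        out = 1.0 - np.exp(
            ((t / self.scale) ** self.shape) - (((t + 1.0) / self.scale) ** self.shape)
        )
        return float(out) if out.ndim == 0 else out

    def cure_multiplier(self, t: float | np.ndarray) -> float | np.ndarray:
        """1 - cured fraction at ``t`` months; multiplies the recurrence probability."""
        t = np.asarray(t, dtype=float)
        if self.cure_ramp == "step":
            frac = np.where(t >= self.cure_threshold, self.max_cure_rate, 0.0)
        elif self.cure_threshold == 0:
            frac = np.full_like(t, self.max_cure_rate)
        else:
            frac = self.max_cure_rate * np.minimum(t / self.cure_threshold, 1.0)
        out = 1.0 - frac
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Background mortality
# ---------------------------------------------------------------------------

class LifeTable:
    """Annual death probabilities by integer age.

    Ages must be contiguous; lookups use the row for ``floor(age)`` and ages
    beyond the last row reuse the final ``q_annual`` (open-ended last row).
    """

    def __init__(self, ages, q_annual):
        self.ages = np.asarray(ages, dtype=int)
        self.q_annual = np.asarray(q_annual, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ages.size == 0 or self.ages.size != self.q_annual.size:
            raise ParameterError("life table needs matching, non-empty age and q columns")
        if not np.array_equal(np.diff(self.ages), np.ones(self.ages.size - 1, dtype=int)):
            raise ParameterError("life table ages must be contiguous integers")
        if np.any((self.q_annual < 0) | (self.q_annual > 1)):
            raise ParameterError("life table q_annual values must lie in [0, 1]")

    def annual(self, age: float) -> float:
        """q_annual at floor(age); constant within each year of age."""
        if age < self.ages[0]:
            raise ParameterError(
                f"age {age} below life table range starting at {self.ages[0]}"
            )
        idx = min(int(math.floor(age)) - int(self.ages[0]), self.ages.size - 1)
        return float(self.q_annual[idx])

    def monthly(self, age: float) -> float:
        """Monthly death probability at this age (constant-hazard split of q_annual)."""
        return annual_to_monthly(self.annual(age))

    def to_records(self) -> list[list[float]]:
        return [[int(a), float(q)] for a, q in zip(self.ages, self.q_annual)]

    @classmethod
    def from_records(cls, records) -> "LifeTable":
        ages = [r[0] for r in records]
        qs = [r[1] for r in records]
        return cls(ages, qs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.q_annual, other.q_annual)
        )

    def __repr__(self) -> str:
        return f"LifeTable(ages {self.ages[0]}..{self.ages[-1]})"


def annual_to_monthly(q_annual: float) -> float:
    """Convert an annual death probability to a monthly one: 1 - (1-q)^(1/12)."""
    if not (0.0 <= q_annual <= 1.0):
        raise ParameterError(f"q_annual must be in [0, 1], got {q_annual!r}")
    return 1.0 - (1.0 - q_annual) ** (1.0 / 12.0)


@dataclass
class MBCMortality:
    """Monthly death probabilities in metastatic disease, by year since entry.

    Year 5+ applies to every month beyond the fifth year.
    """

    year1: float = 0.0324
    year2: float = 0.0446
    year3: float = 0.0492
    year4: float = 0.0511
    year5plus: float = 0.0541

    def validate(self) -> None:
        for f in fields(self):
            _check_prob(f"mbc_mortality.{f.name}", getattr(self, f.name))

    def by_year(self, year: int) -> float:
        """Monthly death probability in the given year since mBC entry (1-based)."""
        if year < 1:
            raise ParameterError(f"year since mBC entry must be >= 1, got {year}")
        names = ("year1", "year2", "year3", "year4", "year5plus")
        return getattr(self, names[min(year, 5) - 1])

    def by_month(self, month: int) -> float:
        """Monthly death probability for month-in-state (1-based)."""
        return self.by_year((month - 1) // 12 + 1)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

@dataclass
class CostInputs:
    """Per-perspective cost inputs, million VND.

    ``cbe_per_person`` is the one-off screening cost per screened woman;
    dividing it by the programme's detection rate gives the screening cost per
    diagnosed case.  ``diagnosis`` is the one-off diagnostic work-up charged in
    both scenarios.  Monthly treatment costs apply while in the corresponding
    states; ``mbc_targeted_monthly`` is the full targeted course amortised over
    the average 40-month metastatic survival.
    """

    cbe_per_person: float
    diagnosis: float
    monthly_chemo: float
    monthly_targeted: float
    monthly_followup: float
    mbc_targeted_monthly: float
    mbc_supportive_monthly: float

    def validate(self, label: str = "costs") -> None:
        for f in fields(self):
            _check_nonneg(f"{label}.{f.name}", getattr(self, f.name))

    def __add__(self, other: "CostInputs") -> "CostInputs":
        return CostInputs(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in fields(self)
            }
        )


PERSPECTIVES = ("patient", "public_payer", "healthcare_sector")


@dataclass
class Costs:
    """Cost inputs for the patient and public-payer perspectives.

    The healthcare-sector perspective is their component-wise sum by
    construction, which guarantees perspective additivity.  ``detection_rate``
    is the proportion of screened women with a diagnostic-positive CBE and is
    shared across perspectives.
    """

    patient: CostInputs
    public_payer: CostInputs
    detection_rate: float = 0.0006

    def validate(self) -> None:
        self.patient.validate("costs.patient")
        self.public_payer.validate("costs.public_payer")
        if not (0.0 < self.detection_rate <= 1.0):
            raise ParameterError(
                f"detection_rate must be in (0, 1], got {self.detection_rate!r}"
            )

    @property
    def healthcare_sector(self) -> CostInputs:
        return self.patient + self.public_payer

    def for_perspective(self, perspective: str) -> CostInputs:
        if perspective == "patient":
            return self.patient
        if perspective == "public_payer":
            return self.public_payer
        if perspective == "healthcare_sector":
            return self.healthcare_sector
        raise ParameterError(
            f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}"
        )


@dataclass
class TreatmentMix:
    """Fractions of patients on targeted therapy.

    ``dfs_targeted`` applies to DFS on-treatment and non-metastatic recurrence
    (the remainder receive chemotherapy only); ``mbc_targeted`` is the fraction
    of metastatic patients on the amortised targeted course.
    """

    dfs_targeted: float = 1.0
    mbc_targeted: float = 0.0

    def validate(self) -> None:
        _check_prob("mix.dfs_targeted", self.dfs_targeted)
        _check_prob("mix.mbc_targeted", self.mbc_targeted)


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

@dataclass
class UtilityBands:
    """Utility for one state group, by age band, plus the pooled mean."""

    under40: float
    age40_49: float
    age50_59: float
    age60plus: float
    pooled: float

    def validate(self, label: str) -> None:
        for f in fields(self):
            _check_prob(f"{label}.{f.name}", getattr(self, f.name))

    def at_age(self, age: float) -> float:
        a = math.floor(age)
        if a < 40:
            return self.under40
        if a < 50:
            return self.age40_49
        if a < 60:
            return self.age50_59
        return self.age60plus

    def rescaled(self, new_pooled: float) -> "UtilityBands":
        """Shift the pooled mean, scaling every age band proportionally.

        Band values are capped at 1 (a utility cannot exceed full health).
        """
        if self.pooled == 0:
            raise ParameterError("cannot rescale a utility group with pooled mean 0")
        r = new_pooled / self.pooled
        return UtilityBands(
            under40=min(self.under40 * r, 1.0),
            age40_49=min(self.age40_49 * r, 1.0),
            age50_59=min(self.age50_59 * r, 1.0),
            age60plus=min(self.age60plus * r, 1.0),
            pooled=new_pooled,
        )


@dataclass
class UtilitySet:
    """Utilities by state group.

    Non-metastatic recurrence shares the DFS on-treatment utilities and
    remission shares DFS off-treatment, so three groups cover five alive
    states.
    """

    on_treatment: UtilityBands
    off_treatment: UtilityBands
    mbc: UtilityBands

    def validate(self) -> None:
        self.on_treatment.validate("utilities.on_treatment")
        self.off_treatment.validate("utilities.off_treatment")
        self.mbc.validate("utilities.mbc")

    def is_ordered(self) -> bool:
        """Whether the metastatic utility sits below the off-treatment utility.

        Holds for the packaged default set; independent sensitivity draws may
        legitimately cross, so this is informative rather than enforced.
        """
        return self.mbc.pooled <= self.off_treatment.pooled


# ---------------------------------------------------------------------------
# Settings and the full parameter set
# ---------------------------------------------------------------------------

@dataclass
class EconSettings:
    """Evaluation settings: discounting, cohort age, horizon, reporting."""

    discount_rate: float = 0.015           # annual, applied to costs and outcomes
    start_age: float = 44.0                # mean age at diagnosis, years
    horizon_months: int = 672              # lifetime: to cohort age 100
    exchange_rate: float = 22759.0         # VND per USD
    wtp_highly: float = 63.2               # 1x GDP per capita, million VND/QALY
    wtp_cost_effective: float = 189.6      # 3x GDP per capita, million VND/QALY

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be non-negative")
        if self.start_age < 0:
            raise ParameterError("start_age must be non-negative")
        if self.horizon_months < 1:
            raise ParameterError("horizon_months must be at least 1")
        if self.exchange_rate <= 0:
            raise ParameterError("exchange_rate must be positive")
        if not (0 < self.wtp_highly <= self.wtp_cost_effective):
            raise ParameterError("WTP thresholds must be positive and ordered")


@dataclass
class ModelParameters:
    """Complete parameter set; the single source of truth for both scenarios."""

    start_dfs_no_screening: float
    start_dfs_screening: float
    dfs: DFSCurve
    remission_to_mbc: float
    mbc_mortality: MBCMortality
    life_table: LifeTable
    costs: Costs
    mix: TreatmentMix
    utilities: UtilitySet
    settings: EconSettings

    def validate(self) -> "ModelParameters":
        _check_prob("start_dfs_no_screening", self.start_dfs_no_screening)
        _check_prob("start_dfs_screening", self.start_dfs_screening)
        _check_prob("remission_to_mbc", self.remission_to_mbc)
        self.dfs.validate()
        self.mbc_mortality.validate()
        self.life_table.validate()
        self.costs.validate()
        self.mix.validate()
        self.utilities.validate()
        self.settings.validate()
        if self.settings.start_age < self.life_table.ages[0]:
            raise ParameterError("start_age below life table coverage")
        return self

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return _to_dict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return _from_dict(cls, d)


def _to_dict(obj):
    if isinstance(obj, LifeTable):
        return {"records": obj.to_records()}
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_dict(cls, d):
    kwargs = {}
    known = {f.name: f for f in fields(cls)}
    for key, value in d.items():
        if key not in known:
            raise ParameterError(f"unknown parameter key {key!r} for {cls.__name__}")
        ftype = known[key].type
        typename = ftype if isinstance(ftype, str) else getattr(ftype, "__name__", "")
        target = _FIELD_CLASSES.get(typename)
        if target is LifeTable:
            kwargs[key] = LifeTable.from_records(value["records"])
        elif target is not None:
            kwargs[key] = _from_dict(target, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_FIELD_CLASSES = {
    "DFSCurve": DFSCurve,
    "MBCMortality": MBCMortality,
    "LifeTable": LifeTable,
    "Costs": Costs,
    "CostInputs": CostInputs,
    "TreatmentMix": TreatmentMix,
    "UtilitySet": UtilitySet,
    "UtilityBands": UtilityBands,
    "EconSettings": EconSettings,
}


# ---------------------------------------------------------------------------
# Dot-path access (used by the DSA/PSA and the configuration loader)
# ---------------------------------------------------------------------------

def get_path(params: ModelParameters, path: str) -> float:
    """Read a scalar parameter by dot-address, e.g. ``'costs.patient.monthly_targeted'``."""
    obj = params
    for part in path.split("."):
        if not hasattr(obj, part):
            raise ParameterError(f"unknown parameter path {path!r} (no field {part!r})")
        obj = getattr(obj, part)
    return obj


def set_path(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with the dot-addressed scalar set to ``value``.

    Setting ``utilities.<group>.pooled`` rescales that group's age bands
    proportionally, keeping the band-to-pooled ratios fixed.
    """
    new = params.copy()
    parts = path.split(".")
    obj = new
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise ParameterError(f"unknown parameter path {path!r} (no field {part!r})")
        obj = getattr(obj, part)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise ParameterError(f"unknown parameter path {path!r} (no field {leaf!r})")
    if isinstance(obj, UtilityBands) and leaf == "pooled":
        group = parts[-2]
        setattr(new.utilities, group, obj.rescaled(value))
    else:
        current = getattr(obj, leaf)
        if isinstance(current, (int, float)) and not isinstance(current, bool):
            setattr(obj, leaf, type(current)(value) if isinstance(current, int) else float(value))
        else:
            setattr(obj, leaf, value)
    return new


def iter_paths(params: ModelParameters, prefix: str = "") -> Iterator[str]:
    """Yield every scalar dot-path in the parameter set (life table excluded)."""
    for f in fields(params):
        value = getattr(params, f.name)
        path = f"{prefix}{f.name}"
        if isinstance(value, LifeTable):
            continue
        if is_dataclass(value):
            yield from iter_paths(value, prefix=path + ".")
        elif isinstance(value, (int, float)):
            yield path
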