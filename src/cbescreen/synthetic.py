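"""Synthetic fixtures and the packaged default parameter set.

Two of the model's inputs were only ever available to the original analysts
privately: the national life table and the trial disease-free-survival curve.
This module generates clearly-labelled synthetic stand-ins — a
Gompertz–Makeham life table emulating adult female mortality and censored
event data drawn from a known Weibull — so the whole pipeline is exercisable
and testable end to end.  Users with the real inputs load them instead (see
:mod:`cbescreen.config`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    Costs,
    CostInputs,
    DFSCurve,
    EconSettings,
    LifeTable,
    MBCMortality,
    ModelParameters,
    ParameterError,
    TreatmentMix,
    UtilityBands,
    UtilitySet,
)

__all__ = [
    "SyntheticLifeTableSpec",
    "make_life_table",
    "SyntheticDFSSpec",
    "make_dfs_events",
    "DFSFitResult",
    "fit_dfs_curve",
    "default_parameters",
]


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLifeTableSpec:
    """Gompertz–Makeham hazard: h(x) = makeham + baseline * exp(slope * x).

    Defaults give q_annual ≈ 0.003 at age 44 and ≈ 0.06 at 80, an
    exponentially rising adult female mortality profile.
    """

    baseline_hazard: float = 4e-5   # Gompertz level at age 0, per year
    slope_per_year: float = 0.092   # log-hazard increase per year of age
    makeham: float = 4e-4           # age-independent hazard, per year
    age_min: int = 0
    age_max: int = 100

    def validate(self) -> None:
        if self.baseline_hazard < 0 or self.makeham < 0 or self.slope_per_year < 0:
            raise ParameterError("hazard components must be non-negative")
        if self.baseline_hazard == 0 and self.makeham == 0:
            raise ParameterError("hazard must be positive somewhere")
        if not (0 <= self.age_min < self.age_max):
            raise ParameterError("need 0 <= age_min < age_max")

    def cumulative_hazard(self, x0: float, x1: float) -> float:
        """Integral of the hazard over [x0, x1] in years (closed form)."""
        a, b, c = self.baseline_hazard, self.slope_per_year, self.makeham
        gomp = a * (x1 - x0) if b == 0 else (a / b) * (np.exp(b * x1) - np.exp(b * x0))
        return c * (x1 - x0) + gomp

    def q_annual(self, age: int) -> float:
        return 1.0 - float(np.exp(-self.cumulative_hazard(age, age + 1)))


def make_life_table(spec: SyntheticLifeTableSpec | None = None) -> LifeTable:
    """Deterministic life table from the closed-form hazard, ages 0..100."""
    spec = spec or SyntheticLifeTableSpec()
    spec.validate()
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qs = [spec.q_annual(int(a)) for a in ages]
    return LifeTable(ages, qs)


# ---------------------------------------------------------------------------
# DFS event data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDFSSpec:
    """Event-table generator emulating trial disease-free-survival data.

    Event times are Weibull (months); censoring is an independent constant
    monthly hazard (the default yields roughly a fifth of subjects censored);
    event types are metastatic with probability ``mbc_split``.
    """

    shape: float = 0.9
    scale: float = 300.0
    n: int = 5000
    censor_rate: float = 0.0008  # per month; censors about 20% of subjects
    mbc_split: float = 0.72
    seed: int = 0

    def validate(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError("Weibull shape and scale must be positive")
        if self.n < 10:
            raise ParameterError("need at least 10 subjects")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ParameterError("censor_rate must be in [0, 1]")
        if not (0.0 <= self.mbc_split <= 1.0):
            raise ParameterError("mbc_split must be in [0, 1]")


def make_dfs_events(spec: SyntheticDFSSpec | None = None) -> pd.DataFrame:
    """Right-censored event table: time_months, event (0/1), type (nm/mbc/na)."""
    spec = spec or SyntheticDFSSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t_event = spec.scale * rng.weibull(spec.shape, size=spec.n)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
    else:
        t_cens = np.full(spec.n, np.inf)
    observed = t_event <= t_cens
    time = np.where(observed, t_event, t_cens)
    is_mbc = rng.random(spec.n) < spec.mbc_split
    etype = np.where(observed, np.where(is_mbc, "mbc", "nm"), "na")
    return pd.DataFrame({
        "time_months": time,
        "event": observed.astype(int),
        "type": etype,
    })


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

@dataclass
class DFSFitResult:
    """Fitted curve plus the estimator covariance (for the PSA's normal draw)."""

    curve: DFSCurve
    params: dict            # natural-scale estimates by name
    covariance: np.ndarray  # covariance of the natural-scale estimates
    log_likelihood: float
    n_events: int


def fit_dfs_curve(events: pd.DataFrame, family: str = "weibull") -> DFSFitResult:
    """Maximum-likelihood parametric fit under right censoring (via lifelines).

    Weibull is parametrised as S(t) = exp(-(t/scale)**shape); exponential is
    the shape-1 special case whose MLE is total exposure over event count.
    """
    from lifelines import ExponentialFitter, WeibullFitter

    if "time_months" not in events or "event" not in events:
        raise ParameterError("event table needs 'time_months' and 'event' columns")
    n_events = int(events["event"].sum())
    if n_events < 2:
        raise ParameterError("need at least 2 observed events to fit a curve")
    T = events["time_months"].to_numpy(dtype=float)
    E = events["event"].to_numpy(dtype=int)

    if family == "exponential":
        f = ExponentialFitter().fit(T, E)
        scale = float(f.lambda_)  # mean lifetime; rate = 1/scale
        cov = np.asarray(f.variance_matrix_)
        curve = DFSCurve(family="exponential", shape=1.0, scale=scale)
        est = {"scale": scale}
    elif family == "weibull":
        f = WeibullFitter().fit(T, E)
        scale = float(f.lambda_)
        shape = float(f.rho_)
        vm = f.variance_matrix_
        cov = vm.loc[["lambda_", "rho_"], ["lambda_", "rho_"]].to_numpy()
        curve = DFSCurve(family="weibull", shape=shape, scale=scale)
        est = {"scale": scale, "shape": shape}
    else:
        raise ParameterError(f"unknown curve family {family!r}")
    return DFSFitResult(
        curve=curve, params=est, covariance=cov,
        log_likelihood=float(f.log_likelihood_), n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Packaged default parameter set
# ---------------------------------------------------------------------------

def default_parameters() -> ModelParameters:
    """The packaged base case.

    Starting distributions, transition inputs, per-perspective costs and
    age-banded utilities are the published Vietnamese base-case values.  The
    DFS curve and the life table are synthetic stand-ins for inputs that were
    never published: a Weibull with shape 0.9 and scale 300 months (about 65%
    event-free at 10 years, a plausible adjuvant-HER2 figure) and the
    Gompertz–Makeham table from :func:`make_life_table`.
    """
    costs = Costs(
        patient=CostInputs(
            cbe_per_person=0.0066,
            diagnosis=2.76,
            monthly_chemo=9.1,
            monthly_targeted=50.3,
            monthly_followup=0.58,
            mbc_targeted_monthly=15.1,
            mbc_supportive_monthly=1.23,
        ),
        public_payer=CostInputs(
            cbe_per_person=0.0264,
            diagnosis=0.79,
            monthly_chemo=5.67,
            monthly_targeted=34.4,
            monthly_followup=0.14,
            mbc_targeted_monthly=10.3,
            mbc_supportive_monthly=0.24,
        ),
        detection_rate=0.0006,
    )
    utilities = UtilitySet(
        on_treatment=UtilityBands(0.8182, 0.7922, 0.6900, 0.6946, pooled=0.7662),
        off_treatment=UtilityBands(0.9229, 0.8663, 0.8647, 0.7729, pooled=0.8545),
        mbc=UtilityBands(0.7275, 0.7044, 0.6135, 0.6176, pooled=0.6813),
    )
    params = ModelParameters(
        start_dfs_no_screening=0.833,
        start_dfs_screening=0.924,
        dfs=DFSCurve(
            family="weibull", shape=0.9, scale=300.0,
            cure_threshold=120.0, max_cure_rate=0.95, mbc_split=0.72,
            cure_ramp="linear",
        ),
        remission_to_mbc=0.0076,
        mbc_mortality=MBCMortality(
            year1=0.0324, year2=0.0446, year3=0.0492, year4=0.0511, year5plus=0.0541,
        ),
        life_table=make_life_table(),
        costs=costs,
        mix=TreatmentMix(dfs_targeted=1.0, mbc_targeted=0.0),
        utilities=utilities,
        settings=EconSettings(
            discount_rate=0.015,
            start_age=44.0,
            horizon_months=672,
            exchange_rate=22759.0,
            wtp_highly=63.2,
            wtp_cost_effective=189.6,
        ),
    )
    return params.validate()
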