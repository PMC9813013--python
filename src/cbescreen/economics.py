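"""Cost and outcome accrual over a cohort trace, ICERs, and classification.

Everything monetary is in million VND internally; USD appears only at
reporting time via :func:`vnd_to_usd`.  Accruals are half-cycle corrected and
discounted at the annual rate converted to a per-cycle factor
``(1 + r)^(-t/12)``; one-off costs are charged undiscounted at cycle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .engine import (
    CohortTrace,
    State,
    StateSpace,
    discount_factors,
    half_cycle_membership,
    life_years,
)
from .params import (
    PERSPECTIVES,
    CostInputs,
    ModelParameters,
    ParameterError,
    TreatmentMix,
    UtilitySet,
)

__all__ = [
    "utility_vector",
    "qalys",
    "cost_vector",
    "one_off_cost",
    "accrue_costs",
    "cost_per_diagnosis",
    "compute_icer",
    "vnd_to_usd",
    "classify_cost_effectiveness",
    "IcerFragment",
    "PerspectiveResult",
    "CEAResult",
    "run_cea",
]

# expanded base state -> utility group (0 on-treatment/NM, 1 off/remission, 2 mBC)
_UTILITY_GROUP = {
    State.DFS_ON: 0,
    State.NM_REC: 0,
    State.DFS_OFF: 1,
    State.REMISSION: 1,
    State.MBC: 2,
}


def utility_vector(space: StateSpace, utilities: UtilitySet, age: float) -> np.ndarray:
    """Utility of each expanded state at the cohort's current age (0 for dead)."""
    groups = (utilities.on_treatment, utilities.off_treatment, utilities.mbc)
    u = np.zeros(space.n_states)
    for i in range(space.n_states):
        base = State(space.base_of[i])
        if base is State.DEAD:
            continue
        u[i] = groups[_UTILITY_GROUP[base]].at_age(age)
    return u


def qalys(trace: CohortTrace, utilities: UtilitySet, annual_discount: float = 0.0) -> float:
    """Discounted quality-adjusted life-years per person.

    Each cycle's half-cycle-corrected occupancy is weighted by the state-group
    utility at the age band containing the cohort's current age.
    """
    eff = half_cycle_membership(trace)
    H = trace.horizon
    df = discount_factors(H, annual_discount)
    ages = trace.age_at_cycle[:H]
    total = 0.0
    # utilities change only when the cohort crosses a band boundary
    u = None
    last_band_age = None
    for t in range(H):
        band_age = int(np.floor(ages[t]))
        if band_age != last_band_age:
            u = utility_vector(trace.space, utilities, ages[t])
            last_band_age = band_age
        total += float(eff[t] @ u) * df[t]
    return total / 12.0


def cost_vector(space: StateSpace, costs: CostInputs, mix: TreatmentMix) -> np.ndarray:
    """Monthly cost of each expanded state, million VND.

    On-treatment and non-metastatic-recurrence months cost a mix-weighted
    blend of targeted therapy and chemotherapy; off-treatment and remission
    accrue follow-up care; metastatic months accrue the amortised targeted
    course for the targeted fraction plus supportive care for everyone.
    """
    c = np.zeros(space.n_states)
    active = mix.dfs_targeted * costs.monthly_targeted + (1.0 - mix.dfs_targeted) * costs.monthly_chemo
    mbc = mix.mbc_targeted * costs.mbc_targeted_monthly + costs.mbc_supportive_monthly
    c[space.indices(State.DFS_ON)] = active
    c[space.indices(State.NM_REC)] = active
    c[space.indices(State.DFS_OFF)] = costs.monthly_followup
    c[space.indices(State.REMISSION)] = costs.monthly_followup
    c[space.indices(State.MBC)] = mbc
    return c


def cost_per_diagnosis(cbe_per_person: float, detection_rate: float) -> float:
    """Screening cost per diagnosed case: CBE cost per person / detection rate."""
    if detection_rate <= 0:
        raise ParameterError("detection_rate must be positive")
    return cbe_per_person / detection_rate


def one_off_cost(costs: CostInputs, detection_rate: float, scenario: str) -> float:
    """Cycle-0 one-off cost: diagnostic work-up in both arms, plus the
    screening cost per diagnosis in the screening arm only."""
    if scenario not in ("screening", "no_screening"):
        raise ParameterError(f"unknown scenario {scenario!r}")
    total = costs.diagnosis
    if scenario == "screening":
        total += cost_per_diagnosis(costs.cbe_per_person, detection_rate)
    return total


def accrue_costs(
    trace: CohortTrace,
    params: ModelParameters,
    perspective: str,
    scenario: str,
) -> float:
    """Discounted total cost per person for one perspective and scenario."""
    costs = params.costs.for_perspective(perspective)
    c = cost_vector(trace.space, costs, params.mix)
    eff = half_cycle_membership(trace)
    df = discount_factors(trace.horizon, params.settings.discount_rate)
    monthly = float((eff @ c) @ df)
    return monthly + one_off_cost(costs, params.costs.detection_rate, scenario)


# ---------------------------------------------------------------------------
# ICERs and reporting
# ---------------------------------------------------------------------------

@dataclass
class IcerFragment:
    """Incremental comparison of two scenarios."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    dominant: bool          # screening cheaper and more effective
    undefined: bool         # zero effect difference


def compute_icer(delta_cost: float, delta_qaly: float, delta_ly: float) -> IcerFragment:
    """ICERs per QALY and per life-year with dominance/undefined flags."""
    undefined = delta_qaly == 0.0
    return IcerFragment(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        delta_ly=delta_ly,
        icer_per_qaly=None if undefined else delta_cost / delta_qaly,
        icer_per_ly=None if delta_ly == 0.0 else delta_cost / delta_ly,
        dominant=(delta_cost < 0 and delta_qaly > 0),
        undefined=undefined,
    )


def vnd_to_usd(amount_million_vnd: float, rate_vnd_per_usd: float = 22759.0) -> int:
    """Convert million VND to whole US dollars, rounding half-up."""
    if rate_vnd_per_usd <= 0:
        raise ParameterError("exchange rate must be positive")
    usd = (
        Decimal(repr(float(amount_million_vnd)))
        * Decimal("1e6")
        / Decimal(repr(float(rate_vnd_per_usd)))
    )
    return int(usd.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def classify_cost_effectiveness(
    icer_million_vnd: float, wtp_highly: float = 63.2, wtp_cost_effective: float = 189.6
) -> str:
    """WHO GDP-based classification of an ICER per QALY."""
    if wtp_highly > wtp_cost_effective:
        raise ParameterError("thresholds must be ordered")
    if icer_million_vnd <= wtp_highly:
        return "highly_cost_effective"
    if icer_million_vnd <= wtp_cost_effective:
        return "cost_effective"
    return "not_cost_effective"


@dataclass
class PerspectiveResult:
    """Base-case results for one perspective (million VND)."""

    perspective: str
    ly_screening: float
    ly_no_screening: float
    qaly_screening: float
    qaly_no_screening: float
    cost_screening: float
    cost_no_screening: float
    icer: IcerFragment
    classification: str | None

    def icer_per_qaly_usd(self, rate: float) -> int | None:
        if self.icer.icer_per_qaly is None:
            return None
        return vnd_to_usd(self.icer.icer_per_qaly, rate)


@dataclass
class CEAResult:
    """Full base-case cost-effectiveness comparison across perspectives."""

    perspectives: dict
    trace_screening: CohortTrace
    trace_no_screening: CohortTrace
    params: ModelParameters

    def __getitem__(self, perspective: str) -> PerspectiveResult:
        return self.perspectives[perspective]

    def summary_frame(self) -> pd.DataFrame:
        """Tabular summary: one row per perspective and scenario, plus increments."""
        rows = []
        rate = self.params.settings.exchange_rate
        for p in PERSPECTIVES:
            r = self.perspectives[p]
            rows.append([p, "screening", r.ly_screening, r.qaly_screening,
                         r.cost_screening, np.nan, np.nan, ""])
            rows.append([p, "no_screening", r.ly_no_screening, r.qaly_no_screening,
                         r.cost_no_screening, np.nan, np.nan, ""])
            rows.append([
                p, "increment", r.icer.delta_ly, r.icer.delta_qaly, r.icer.delta_cost,
                np.nan if r.icer.icer_per_ly is None else r.icer.icer_per_ly,
                np.nan if r.icer.icer_per_qaly is None else r.icer.icer_per_qaly,
                r.classification or "",
            ])
        df = pd.DataFrame(
            rows,
            columns=["perspective", "scenario", "life_years", "qalys",
                     "cost_million_vnd", "icer_per_ly_million_vnd",
                     "icer_per_qaly_million_vnd", "classification"],
        )
        df["icer_per_qaly_usd"] = [
            vnd_to_usd(v, rate) if np.isfinite(v) else pd.NA
            for v in df["icer_per_qaly_million_vnd"]
        ]
        return df


def run_cea(params: ModelParameters, horizon: int | None = None) -> CEAResult:
    """Run both scenarios and compare them from all three perspectives.

    The scenarios share every transition probability; only the starting
    distribution differs (screening shifts mass from metastatic to
    disease-free entry — the downstaging effect).
    """
    from .engine import DEFAULT_SPACE, run_cohort
    from .natural_history import NaturalHistoryModel

    params.validate()
    H = horizon if horizon is not None else params.settings.horizon_months
    model = NaturalHistoryModel(params)
    space = model.space
    traces = {}
    for scenario, dfs_start in (
        ("screening", params.start_dfs_screening),
        ("no_screening", params.start_dfs_no_screening),
    ):
        traces[scenario] = run_cohort(
            space.start_distribution(dfs_start), model, H,
            space=space, start_age=params.settings.start_age, validate=False,
        )
    r = params.settings.discount_rate
    ly = {s: life_years(t, r) for s, t in traces.items()}
    qa = {s: qalys(t, params.utilities, r) for s, t in traces.items()}

    perspectives = {}
    for p in PERSPECTIVES:
        cost = {s: accrue_costs(traces[s], params, p, s) for s in traces}
        frag = compute_icer(
            cost["screening"] - cost["no_screening"],
            qa["screening"] - qa["no_screening"],
            ly["screening"] - ly["no_screening"],
        )
        cls = (
            None
            if frag.icer_per_qaly is None
            else classify_cost_effectiveness(
                frag.icer_per_qaly,
                params.settings.wtp_highly,
                params.settings.wtp_cost_effective,
            )
        )
        perspectives[p] = PerspectiveResult(
            perspective=p,
            ly_screening=ly["screening"],
            ly_no_screening=ly["no_screening"],
            qaly_screening=qa["screening"],
            qaly_no_screening=qa["no_screening"],
            cost_screening=cost["screening"],
            cost_no_screening=cost["no_screening"],
            icer=frag,
            classification=cls,
        )
    return CEAResult(
        perspectives=perspectives,
        trace_screening=traces["screening"],
        trace_no_screening=traces["no_screening"],
        params=params,
    )
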