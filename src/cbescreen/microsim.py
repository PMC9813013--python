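"""Individual-level microsimulation oracle.

Simulates individuals one transition at a time under the same per-cycle
probabilities as the cohort engine and accrues life-years, QALYs and costs
with the identical half-cycle/discounting conventions, so its Monte-Carlo
means estimate exactly the cohort model's expectations.  Used as an
independent check of the matrix algebra, never as the production path.

Randomness: one substream per individual, spawned from the master seed, so
results are reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import cost_vector, one_off_cost, utility_vector
from .engine import DEFAULT_SPACE, State, StateSpace, discount_factors
from .natural_history import NaturalHistoryModel
from .params import ModelParameters

__all__ = ["MicrosimResult", "microsim_oracle"]


@dataclass
class MicrosimResult:
    """Monte-Carlo means with standard errors, per person."""

    n_individuals: int
    horizon: int
    ly_mean: float
    ly_se: float
    qaly_mean: float
    qaly_se: float
    cost_mean: float
    cost_se: float


def microsim_oracle(
    start: np.ndarray,
    params: ModelParameters,
    horizon: int,
    n_individuals: int,
    seed: int,
    perspective: str = "healthcare_sector",
    scenario: str = "screening",
    space: StateSpace = DEFAULT_SPACE,
) -> MicrosimResult:
    """Simulate ``n_individuals`` trajectories and accrue outcomes.

    ``start`` is a probability distribution over expanded states; each
    individual draws a starting state and then one categorical transition per
    cycle from the cohort model's own matrices.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    start = np.asarray(start, dtype=float)
    if abs(start.sum() - 1.0) > 1e-9:
        raise ValueError("start distribution must sum to 1")
    model = NaturalHistoryModel(params, space=space)
    n = n_individuals
    H = horizon

    # per-individual substreams: uniforms for the start draw plus one per cycle
    streams = np.random.SeedSequence(seed).spawn(n)
    u = np.empty((n, H + 1))
    for i, ss in enumerate(streams):
        u[i] = np.random.Generator(np.random.PCG64(ss)).random(H + 1)

    states = np.empty((n, H + 1), dtype=np.int16)
    start_cum = np.cumsum(start)
    states[:, 0] = np.minimum(
        np.searchsorted(start_cum, u[:, 0], side="right"), space.n_states - 1
    )

    for t in range(H):
        cum = np.cumsum(model.matrix(t), axis=1)
        rows = cum[states[:, t]]
        nxt = (u[:, t + 1][:, None] >= rows).sum(axis=1)
        states[:, t + 1] = np.minimum(nxt, space.n_states - 1)

    df = discount_factors(H, params.settings.discount_rate)
    dead = space.index(State.DEAD)

    alive = (states != dead).astype(float)
    eff_alive = 0.5 * (alive[:, :-1] + alive[:, 1:])
    ly = (eff_alive @ df) / 12.0

    # utility of each expanded state per cycle (age-band dependent)
    ages = params.settings.start_age + np.arange(H) / 12.0
    U = np.empty((H, space.n_states))
    last = None
    for t in range(H):
        band = int(np.floor(ages[t]))
        if band != last:
            row = utility_vector(space, params.utilities, ages[t])
            last = band
        U[t] = row
    tt = np.arange(H)
    qaly = ((0.5 * (U[tt, states[:, :-1]] + U[tt, states[:, 1:]])) @ df) / 12.0

    costs = params.costs.for_perspective(perspective)
    c = cost_vector(space, costs, params.mix)
    cost = (0.5 * (c[states[:, :-1]] + c[states[:, 1:]])) @ df
    cost = cost + one_off_cost(costs, params.costs.detection_rate, scenario)

    def mean_se(x):
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return m, se

    ly_m, ly_s = mean_se(ly)
    qa_m, qa_s = mean_se(qaly)
    co_m, co_s = mean_se(cost)
    return MicrosimResult(
        n_individuals=n, horizon=H,
        ly_mean=ly_m, ly_se=ly_s,
        qaly_mean=qa_m, qaly_se=qa_s,
        cost_mean=co_m, cost_se=co_s,
    )
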