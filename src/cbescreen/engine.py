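"""Monthly-cycle Markov cohort engine over a tunnel-expanded state space.

The six base health states are expanded by time-in-state where transition
probabilities depend on it: the on-treatment and non-metastatic-recurrence
states for their fixed 12-month treatment course, and metastatic disease for
its year-specific mortality (60 monthly tunnels, the last one absorbing the
time dependence at the year-5+ rate).  Dead is absorbing.

The engine is generic: any object exposing ``matrix(cycle) -> (n, n) ndarray``
over this expanded space can drive it.  Row-stochasticity is enforced hard
(no silent renormalisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "State",
    "StateSpace",
    "DEFAULT_SPACE",
    "CohortTrace",
    "TransitionMatrixError",
    "validate_matrix",
    "run_cohort",
    "half_cycle_membership",
    "life_years",
    "discount_factors",
]


class State(IntEnum):
    """Base health states."""

    DFS_ON = 0
    DFS_OFF = 1
    NM_REC = 2
    REMISSION = 3
    MBC = 4
    DEAD = 5


DEFAULT_TUNNELS = {
    State.DFS_ON: 12,
    State.DFS_OFF: 1,
    State.NM_REC: 12,
    State.REMISSION: 1,
    State.MBC: 60,
    State.DEAD: 1,
}


@dataclass(frozen=True)
class StateSpace:
    """Tunnel-expanded state space.

    Expanded index ``i`` corresponds to base state ``base_of[i]`` in its
    ``month_of[i]``-th month in state (1-based).  Non-tunnelled states have a
    single month.
    """

    tunnel_lengths: dict = field(default_factory=lambda: dict(DEFAULT_TUNNELS))

    def __post_init__(self):
        offsets = {}
        base_of = []
        month_of = []
        pos = 0
        for s in State:
            n = self.tunnel_lengths[s]
            if n < 1:
                raise ValueError(f"tunnel length for {s.name} must be >= 1")
            offsets[s] = pos
            base_of.extend([int(s)] * n)
            month_of.extend(range(1, n + 1))
            pos += n
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "base_of", np.array(base_of, dtype=int))
        object.__setattr__(self, "month_of", np.array(month_of, dtype=int))
        object.__setattr__(self, "n_states", pos)

    def index(self, base: State, month: int = 1) -> int:
        """Expanded index of ``base`` in its ``month``-th month in state."""
        n = self.tunnel_lengths[base]
        if not (1 <= month <= n):
            raise ValueError(f"{base.name} has tunnel months 1..{n}, got {month}")
        return self._offsets[base] + month - 1

    def indices(self, base: State) -> np.ndarray:
        """All expanded indices of a base state."""
        off = self._offsets[base]
        return np.arange(off, off + self.tunnel_lengths[base])

    def start_distribution(self, dfs_fraction: float) -> np.ndarray:
        """Cohort entering at diagnosis: DFS on-treatment month 1 vs mBC month 1."""
        if not (0.0 <= dfs_fraction <= 1.0):
            raise ValueError(f"dfs_fraction must be in [0, 1], got {dfs_fraction!r}")
        start = np.zeros(self.n_states)
        start[self.index(State.DFS_ON, 1)] = dfs_fraction
        start[self.index(State.MBC, 1)] = 1.0 - dfs_fraction
        return start

    def labels(self) -> list[str]:
        return [
            f"{State(b).name}" if self.tunnel_lengths[State(b)] == 1 else f"{State(b).name}_m{m}"
            for b, m in zip(self.base_of, self.month_of)
        ]


DEFAULT_SPACE = StateSpace()


class TransitionMatrixError(ValueError):
    """A transition matrix row failed its stochasticity check."""


def validate_matrix(matrix: np.ndarray, space: StateSpace, atol: float = 1e-9) -> None:
    """Check row-stochasticity; name the offending expanded state on failure."""
    if matrix.shape != (space.n_states, space.n_states):
        raise TransitionMatrixError(
            f"matrix shape {matrix.shape} does not match state space ({space.n_states})"
        )
    if np.any(matrix < -1e-15):
        i = int(np.argwhere(matrix < -1e-15)[0][0])
        raise TransitionMatrixError(f"negative probability in row {space.labels()[i]}")
    sums = matrix.sum(axis=1)
    bad = np.abs(sums - 1.0) > atol
    if np.any(bad):
        i = int(np.argmax(bad))
        raise TransitionMatrixError(
            f"row for state {space.labels()[i]} sums to {sums[i]:.12f}, not 1"
        )
    dead = space.index(State.DEAD)
    if matrix[dead, dead] != 1.0:
        raise TransitionMatrixError("DEAD must be absorbing (self-transition 1)")


@dataclass
class CohortTrace:
    """Occupancy of the expanded state space over monthly cycles.

    Row ``t`` is the cohort distribution at the start of cycle ``t``;
    ``occupancy`` has ``horizon + 1`` rows and each row sums to 1.
    """

    occupancy: np.ndarray
    space: StateSpace
    start_age: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def age_at_cycle(self) -> np.ndarray:
        """Cohort age in years at the start of each cycle."""
        return self.start_age + np.arange(self.occupancy.shape[0]) / 12.0

    def alive(self) -> np.ndarray:
        """Fraction of the cohort alive at the start of each cycle."""
        return 1.0 - self.occupancy[:, self.space.index(State.DEAD)]

    def by_base_state(self) -> np.ndarray:
        """Occupancy collapsed onto the six base states."""
        out = np.zeros((self.occupancy.shape[0], len(State)))
        for s in State:
            out[:, int(s)] = self.occupancy[:, self.space.indices(s)].sum(axis=1)
        return out


def run_cohort(
    start: np.ndarray,
    model,
    horizon: int,
    space: StateSpace = DEFAULT_SPACE,
    start_age: float = 44.0,
    validate: bool = True,
) -> CohortTrace:
    """Propagate a cohort through ``horizon`` monthly cycles.

    ``model`` provides ``matrix(cycle)``; ``start`` may be a single
    distribution or a stack of distributions (one trace per row is not
    returned — stack externally if needed).
    """
    start = np.asarray(start, dtype=float)
    if start.shape != (space.n_states,):
        raise ValueError(f"start distribution must have shape ({space.n_states},)")
    if abs(start.sum() - 1.0) > 1e-9:
        raise ValueError(f"start distribution sums to {start.sum():.12f}, not 1")
    if horizon < 1:
        raise ValueError("horizon must be at least 1 cycle")
    occ = np.empty((horizon + 1, space.n_states))
    occ[0] = start
    for t in range(horizon):
        m = model.matrix(t)
        if validate:
            validate_matrix(m, space)
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occupancy=occ, space=space, start_age=start_age)


def half_cycle_membership(trace: CohortTrace) -> np.ndarray:
    """Effective occupancy per cycle under the half-cycle correction.

    Cycle ``t``'s accrual weight is the average of the cohort distribution at
    the start and end of the cycle, approximating mid-cycle transitions;
    returns ``horizon`` rows.
    """
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def discount_factors(horizon: int, annual_rate: float) -> np.ndarray:
    """Per-cycle discount factors (1 + r)^(-t/12) for t = 0..horizon-1."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.arange(horizon)
    return (1.0 + annual_rate) ** (-t / 12.0)


def life_years(trace: CohortTrace, annual_discount: float = 0.0) -> float:
    """Discounted life-years per person over the trace's horizon."""
    eff = half_cycle_membership(trace)
    alive = 1.0 - eff[:, trace.space.index(State.DEAD)]
    df = discount_factors(trace.horizon, annual_discount)
    return float(np.sum(alive * df) / 12.0)
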