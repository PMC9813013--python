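"""Disease-specific transition probabilities.

Exits from disease-free survival are driven by the parametric DFS curve
(recurrence only, damped by the cure ramp and split 72/28 between metastatic
and non-metastatic recurrence) with death added independently from the
background life table.  The on-treatment and recurrence tunnels discharge
survivors after 12 months; remission progresses to metastatic disease at a
constant monthly probability; metastatic mortality follows the year-specific
schedule.

Discrete-time competing risks are composed multiplicatively with death taking
precedence: stay = (1 - q)(1 - p_rec), death gets q, and recurrence gets
(1 - q) * p_rec, so outflow can never exceed 1.
"""

from __future__ import annotations

import numpy as np

from .engine import DEFAULT_SPACE, State, StateSpace
from .params import DFSCurve, LifeTable, ModelParameters, ParameterError, annual_to_monthly

__all__ = [
    "survival_at",
    "cycle_event_probability",
    "cure_multiplier",
    "dfs_exit_probabilities",
    "background_mortality",
    "annual_to_monthly",
    "NaturalHistoryModel",
    "allowed_transition_mask",
]


def survival_at(curve: DFSCurve, t: float) -> float:
    """Probability of remaining event-free ``t`` months after diagnosis."""
    return curve.survival(t)


def cycle_event_probability(curve: DFSCurve, t: float) -> float:
    """Per-cycle DFS-event probability over [t, t+1): 1 - S(t+1)/S(t)."""
    if np.any(np.asarray(t) < 0):
        raise ParameterError("time must be non-negative")
    return curve.cycle_event_probability(t)


def cure_multiplier(t: float, cure_threshold: float, max_cure_rate: float,
                    ramp: str = "linear") -> float:
    """Hazard multiplier 1 - cure_fraction(t).

    The cured fraction ramps from 0 at diagnosis to ``max_cure_rate`` at the
    threshold (linearly, or as a step at the threshold) and stays there, so
    past the threshold only ``1 - max_cure_rate`` of the cohort can still
    recur.
    """
    return DFSCurve(
        cure_threshold=cure_threshold, max_cure_rate=max_cure_rate, cure_ramp=ramp
    ).cure_multiplier(t)


def dfs_exit_probabilities(
    curve: DFSCurve, t: float, q_background_monthly: float
) -> tuple[float, float, float]:
    """(p_death, p_nm_recurrence, p_mbc_recurrence) for the cycle starting at ``t``.

    Death takes precedence in the joint event; the recurrence probability is
    the curve's per-cycle event probability damped by the cure multiplier and
    split between metastatic and non-metastatic destinations.
    """
    if not (0.0 <= q_background_monthly <= 1.0):
        raise ParameterError("background monthly mortality must be in [0, 1]")
    p_rec = curve.cycle_event_probability(t) * curve.cure_multiplier(t)
    q = q_background_monthly
    p_mbc = (1.0 - q) * p_rec * curve.mbc_split
    p_nm = (1.0 - q) * p_rec * (1.0 - curve.mbc_split)
    if q + p_mbc + p_nm >= 1.0 and q < 1.0:
        raise ParameterError(
            f"total DFS outflow >= 1 for the cycle starting at t={t} months"
        )
    return q, p_nm, p_mbc


def background_mortality(life_table: LifeTable, age: float) -> float:
    """Monthly background death probability at the given (fractional) age."""
    if age < 0:
        raise ParameterError("age must be non-negative")
    return life_table.monthly(age)


class NaturalHistoryModel:
    """Builds the per-cycle transition matrix over the expanded state space.

    Matrices depend on the cycle through the DFS curve (time since diagnosis),
    the cure ramp, and the background mortality at the cohort's current age;
    they are cached per cycle because both scenarios share them.
    """

    def __init__(self, params: ModelParameters, space: StateSpace = DEFAULT_SPACE):
        params.validate()
        self.params = params
        self.space = space
        self._cache: dict[int, np.ndarray] = {}
        self._template = self._build_template()

    def _build_template(self) -> np.ndarray:
        """Cycle-independent part: mBC tunnel and absorbing death."""
        sp = self.space
        p = self.params
        n = sp.n_states
        m = np.zeros((n, n))
        dead = sp.index(State.DEAD)
        m[dead, dead] = 1.0
        mbc = sp.indices(State.MBC)
        months = np.arange(1, mbc.size + 1)
        p_die = np.array([p.mbc_mortality.by_month(int(k)) for k in months])
        m[mbc, dead] = p_die
        # advance the tunnel; the last month self-loops at the year-5+ rate
        m[mbc[:-1], mbc[1:]] = 1.0 - p_die[:-1]
        m[mbc[-1], mbc[-1]] = 1.0 - p_die[-1]
        return m

    def matrix(self, cycle: int) -> np.ndarray:
        if cycle < 0:
            raise ValueError("cycle index must be non-negative")
        cached = self._cache.get(cycle)
        if cached is not None:
            return cached
        sp = self.space
        p = self.params
        dead = sp.index(State.DEAD)
        m = self._template.copy()

        age = p.settings.start_age + cycle / 12.0
        q = background_mortality(p.life_table, age)
        # time in DFS equals the cycle index: DFS is only entered at diagnosis
        q_, p_nm, p_mbc = dfs_exit_probabilities(p.dfs, float(cycle), q)
        stay_dfs = (1.0 - q) * (1.0 - p.dfs.cycle_event_probability(float(cycle))
                                * p.dfs.cure_multiplier(float(cycle)))

        mbc1 = sp.index(State.MBC, 1)
        nm1 = sp.index(State.NM_REC, 1)
        off = sp.index(State.DFS_OFF)
        rem = sp.index(State.REMISSION)

        # DFS on-treatment tunnel: recurrence/death compete; survivors advance,
        # discharging to off-treatment after month 12
        on = sp.indices(State.DFS_ON)
        m[on, dead] = q
        m[on, mbc1] = p_mbc
        m[on, nm1] = p_nm
        m[on[:-1], on[1:]] = stay_dfs
        m[on[-1], off] = stay_dfs

        # DFS off-treatment: same exits, stays otherwise
        m[off, dead] = q
        m[off, mbc1] = p_mbc
        m[off, nm1] = p_nm
        m[off, off] = stay_dfs

        # Non-metastatic recurrence: background death only; discharge to
        # remission is automatic after 12 months if alive
        nm = sp.indices(State.NM_REC)
        m[nm, dead] = q
        m[nm[:-1], nm[1:]] = 1.0 - q
        m[nm[-1], rem] = 1.0 - q

        # Remission: progression to mBC, background death
        p_prog = (1.0 - q) * p.remission_to_mbc
        m[rem, dead] = q
        m[rem, mbc1] = p_prog
        m[rem, rem] = (1.0 - q) * (1.0 - p.remission_to_mbc)

        self._cache[cycle] = m
        return m


def allowed_transition_mask(space: StateSpace = DEFAULT_SPACE) -> np.ndarray:
    """Boolean mask of structurally permitted transitions between base states.

    Used by tests to assert that no forbidden edge ever carries probability:
    DFS states may recur or die; non-metastatic recurrence leads to remission
    or death; remission may progress or die; mBC only dies; dead stays dead.
    """
    allowed_base = {
        State.DFS_ON: {State.DFS_ON, State.DFS_OFF, State.NM_REC, State.MBC, State.DEAD},
        State.DFS_OFF: {State.DFS_OFF, State.NM_REC, State.MBC, State.DEAD},
        State.NM_REC: {State.NM_REC, State.REMISSION, State.DEAD},
        State.REMISSION: {State.REMISSION, State.MBC, State.DEAD},
        State.MBC: {State.MBC, State.DEAD},
        State.DEAD: {State.DEAD},
    }
    n = space.n_states
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            bi = State(space.base_of[i])
            bj = State(space.base_of[j])
            mask[i, j] = bj in allowed_base[bi]
    return mask
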