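"""Continuous-time and event-triggered emotion updates.

Three general state dimensions (arousal, anxiety, satisfaction) relax
linearly at constant per-minute rates toward context-dependent limits and
receive instantaneous increments from discrete social events.  The
partner-specific satisfaction PARTNER_SAT[i, j] rises at 0.1/min while i
is being groomed by j and otherwise decays at the default satisfaction
decay rate.

The LIKE attitude update combines the previous LIKE value with the
current partner-specific satisfaction, weighted by the LIKE-history
weight ``lhw`` (minutes) and the elapsed time ``dt``::

    LIKE(t_n) = max( (lhw * LIKE(t_{n-1}) + dt * PS(t_n)) / (lhw + dt),
                     PS(t_n) )

With PS = 0 this makes ``lhw`` the single-interval half-life of LIKE:
decaying from 1.0 over dt = lhw gives exactly 0.5.  At lhw = 0 LIKE
simply equals PARTNER_SAT.  The equation is not composition-invariant
(splitting an interval decays faster than one spanning update), so the
simulator anchors each dyad's LIKE only at grooming-relevant moments and
evaluates it read-only in between ("lazy" policy), preserving the
half-life semantics; an "eager" per-activation policy is available via
``ModelParams.like_policy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NONE, Agent, Population
from .params import ModelParams

EVENT_KINDS = frozenset({
    "receive_attack", "give_attack", "receive_aggr_signal", "lose_fight",
    "win_fight", "observe_fight", "receive_submission",
    "receive_affil_signal", "give_affil", "receive_affil",
})


@dataclass(frozen=True)
class EmotionEvent:
    kind: str
    actor: int
    receiver: int
    time: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown emotion event kind {self.kind!r}")


@dataclass(frozen=True)
class Context:
    """Lasting social context of one agent."""
    receiving_groom_from: int | None = None
    giving_groom_to: int | None = None
    dominant_within_pers_dist: bool = False


# --------------------------------------------------------------------------
# LIKE attitude update
# --------------------------------------------------------------------------

def update_like(like_prev: float, partner_sat_now: float,
                dt: float, lhw: float) -> float:
    """One LIKE update over ``dt`` minutes; see module docstring."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if lhw < 0:
        raise ValueError("lhw must be non-negative")
    weighted = (lhw * like_prev + dt * partner_sat_now) / (lhw + dt)
    return max(weighted, partner_sat_now)


def like_value(like_prev: np.ndarray, partner_sat_now: np.ndarray,
               dt: np.ndarray, lhw: float) -> np.ndarray:
    """Vectorized read-only LIKE evaluation; dt = 0 returns the anchor."""
    like_prev = np.asarray(like_prev, dtype=float)
    dt = np.asarray(dt, dtype=float)
    denom = lhw + dt
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = (lhw * like_prev + dt * partner_sat_now) / denom
    weighted = np.where(denom > 0, weighted, like_prev)
    return np.maximum(weighted, partner_sat_now)


# --------------------------------------------------------------------------
# relaxation toward context limits
# --------------------------------------------------------------------------

def _toward(value: float, limit: float, rate: float, dt: float) -> float:
    """Move value linearly toward limit at `rate`/min without overshoot."""
    gap = value - limit
    if gap > 0:
        return limit + max(gap - rate * dt, 0.0)
    return limit - max(-gap - rate * dt, 0.0)


def relax_agent(pop: Population, i: int, now: float, params: ModelParams) -> None:
    """Relax agent i's time-dependent state from its last update to `now`."""
    dt = now - pop.last_update[i]
    if dt <= 0:
        return
    pop.last_update[i] = now

    pop.arousal[i] = _toward(pop.arousal[i], pop.arousal_limit[i],
                             params.arousal_rate, dt)

    receiving = pop.groomed_by[i] != NONE
    giving = pop.groom_target[i] != NONE
    if receiving:
        anx_rate = params.anxiety_groom_receive_decay
    elif giving:
        anx_rate = params.anxiety_groom_give_decay
    else:
        anx_rate = params.anxiety_default_decay
    pop.anxiety[i] = max(pop.anxiety[i] - anx_rate * dt, 0.0)

    if receiving:
        pop.satisfaction[i] = min(pop.satisfaction[i]
                                  + params.sat_receive_inc * dt, 1.0)
    elif giving:
        pop.satisfaction[i] = min(pop.satisfaction[i]
                                  + params.sat_give_inc * dt, 1.0)
    else:
        pop.satisfaction[i] = max(pop.satisfaction[i]
                                  - params.sat_default_dec * dt, 0.0)

    row = pop.partner_sat[i]
    if receiving:
        j = pop.groomed_by[i]
        rising = float(row[j])
    np.maximum(row - params.partner_sat_dec * dt, 0.0, out=row)
    if receiving:
        # the entry for the current groomer rises instead of decaying
        row[j] = min(rising + params.sat_receive_inc * dt, 1.0)


def relax_over_time(agent: Agent, dt: float, ctx: Context) -> Agent:
    """Functional relaxation of one agent over ``dt`` minutes.

    The agent's population bookkeeping (grooming pointers) is set from
    ``ctx`` before delegating to :func:`relax_agent`.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    pop = agent.pop
    i = agent.id
    params = pop.params
    pop.groomed_by[i] = (NONE if ctx.receiving_groom_from is None
                         else ctx.receiving_groom_from)
    pop.groom_target[i] = (NONE if ctx.giving_groom_to is None
                           else ctx.giving_groom_to)
    if ctx.receiving_groom_from is not None:
        pop.arousal_limit[i] = params.arousal_limits["being_groomed"]
    elif ctx.giving_groom_to is not None:
        pop.arousal_limit[i] = params.arousal_limits["grooming"]
    elif ctx.dominant_within_pers_dist:
        pop.arousal_limit[i] = params.arousal_limits["dominant_near"]
    else:
        pop.arousal_limit[i] = params.arousal_limits["default"]
    now = pop.last_update[i] + dt
    relax_agent(pop, i, now, params)
    return agent


# --------------------------------------------------------------------------
# instantaneous event increments
# --------------------------------------------------------------------------

def apply_event_deltas(pop: Population, i: int, kind: str,
                       params: ModelParams) -> None:
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown emotion event kind {kind!r}")
    d_arousal, d_anxiety = params.event_increments.get(kind, (0.0, 0.0))
    pop.arousal[i] = min(max(pop.arousal[i] + d_arousal, 0.0), 1.0)
    pop.anxiety[i] = min(max(pop.anxiety[i] + d_anxiety, 0.0), 1.0)


def apply_event(agent: Agent, event: EmotionEvent,
                params: ModelParams) -> Agent:
    """Apply one discrete event's instantaneous emotion deltas to `agent`."""
    apply_event_deltas(agent.pop, agent.id, event.kind, params)
    return agent


def context_arousal_limit(pop: Population, i: int, params: ModelParams) -> float:
    """Arousal target implied by agent i's current lasting context.

    Priority: being groomed (most calming) > grooming > dominant group
    member within personal distance > default.
    """
    if pop.groomed_by[i] != NONE:
        return params.arousal_limits["being_groomed"]
    if pop.groom_target[i] != NONE:
        return params.arousal_limits["grooming"]
    if pop.dominant_near[i]:
        return params.arousal_limits["dominant_near"]
    return params.arousal_limits["default"]
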