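"""Perception, grouping, action selection, movement and aggression.

Action selection is the seat of partner selectivity.  An activated agent
first decides between resting and acting (probability of acting rises
with arousal).  Active options are weighted per candidate partner:

* affiliation (groom <= 1 m, affiliative signal <= 5 m, approach <= 50 m)
  is weighted by an intrinsic motivation term that rises with anxiety and
  falls with satisfaction, times the LIKE mixture
  ``((1 - LPS) + LPS * LIKE_ij) ** gamma`` normalized to mean 1 over the
  candidate set -- selectivity redistributes affiliation among partners
  without changing the overall affiliation propensity. At LPS = 0 the
  mixture is 1 and LIKE values are never read (null model);
* aggression (attack <= 1 m, aggressive signal <= 5 m) falls with
  FEAR_ij and with anxiety;
* submission (leave <= 1 m, submissive signal and avoid <= 5 m) rises
  with FEAR_ij and with anxiety;
* a random walk within the group is always available.

The sharpening exponent ``gamma`` (> 1) makes high selectivity
near-exclusive: at LPS close to 1 small LIKE differences translate into
large odds ratios between partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (NONE, Activity, MoveKind, Population, bearing_deg,
                   torus_delta, wrap_position)
from .emotions import like_value
from .params import ModelParams

AFFILIATIVE = ("groom", "affil_signal", "approach")
SUBMISSIVE = ("leave", "submissive_signal", "avoid")
AGGRESSIVE = ("attack", "aggr_signal")


@dataclass
class CandidateSet:
    """Up to 10 nearest perceivable partners of one agent."""
    ids: np.ndarray          # candidate agent ids, sorted by distance
    dists: np.ndarray
    bearings: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ActionDistribution:
    """Normalized probabilities over (behavior, target) pairs."""
    behaviors: list[str] = field(default_factory=list)
    targets: list[int] = field(default_factory=list)   # NONE for untargeted
    probs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def sample(self, rng: np.random.Generator) -> tuple[str, int]:
        k = rng.choice(len(self.probs), p=self.probs)
        return self.behaviors[k], self.targets[k]


# --------------------------------------------------------------------------
# perception and grouping
# --------------------------------------------------------------------------

def perceive_candidates(pop: Population, i: int) -> CandidateSet:
    """The <= 10 nearest group members within 50 m and ego's view angle.

    Group members within the interaction distance (1 m) are always
    perceived, regardless of the view angle.
    """
    params = pop.params
    d = pop.distances_from(i)
    d[i] = np.inf
    delta = torus_delta(pop.pos[i], pop.pos, params.world_size)
    bearings = np.degrees(np.arctan2(delta[:, 1], delta[:, 0])) % 360.0
    off = np.abs((bearings - pop.heading[i]) % 360.0)
    off = np.minimum(off, 360.0 - off)
    visible = (d <= params.max_dist) & (off <= pop.view[i] / 2.0)
    visible |= d <= params.interact_dist
    idx = np.nonzero(visible)[0]
    order = np.argsort(d[idx], kind="stable")
    idx = idx[order][: params.max_partners]
    return CandidateSet(ids=idx, dists=d[idx], bearings=bearings[idx])


def check_grouping(pop: Population, i: int,
                   rng: np.random.Generator) -> int | None:
    """Return a grouping-approach target, or None if the group is cohesive.

    Grouping is triggered when fewer than ``min_others`` group members are
    within 20 m (judged at 360 degrees) or when any group member is
    farther away than 100 m; the target is a uniformly random group
    member.
    """
    params = pop.params
    d = pop.distances_from(i)
    d[i] = np.inf
    n_near = int(np.count_nonzero(d <= params.near_dist))
    too_far = bool(np.any((d > params.far_dist) & np.isfinite(d)))
    if n_near >= params.min_others and not too_far:
        return None
    others = [k for k in range(pop.n) if k != i]
    return int(others[rng.integers(len(others))])


# --------------------------------------------------------------------------
# action selection
# --------------------------------------------------------------------------

def activity_probability(arousal: float) -> float:
    """Probability of selecting an active behavior rather than resting."""
    return min(max(arousal, 0.0), 1.0)


def affiliation_motivation(anxiety: float, satisfaction: float,
                           params: ModelParams) -> float:
    """Intrinsic affiliation motivation: rises with anxiety (strongly),
    falls with satisfaction (more weakly)."""
    return ((1.0 + params.motiv_anxiety_coef * anxiety)
            * (1.0 - params.motiv_sat_coef * satisfaction))


def action_distribution(pop: Population, i: int, cands: CandidateSet,
                        params: ModelParams,
                        now: float | None = None) -> ActionDistribution:
    """Build the full behavior-partner probability distribution for ego."""
    if now is None:
        now = float(pop.last_update[i])
    w = params.behavior_weights
    anxiety = float(pop.anxiety[i])
    satisfaction = float(pop.satisfaction[i])
    fear_row = pop.dom - pop.dom[i]

    motiv = affiliation_motivation(anxiety, satisfaction, params)
    lps = params.lps
    if lps > 0.0 and len(cands):
        pop.like_reads += len(cands)
        lv = like_value(pop.like[i, cands.ids],
                        pop.partner_sat[i, cands.ids],
                        now - pop.like_time[i, cands.ids], params.lhw)
        mixture = ((1.0 - lps) + lps * lv) ** params.selectivity_gamma
        # selectivity redistributes affiliation among partners without
        # changing the overall affiliation propensity: normalize to a
        # mean of 1 across the candidate set
        mean = mixture.mean()
        mixture = mixture / mean if mean > 0 else np.ones(len(cands))
    else:
        mixture = np.ones(len(cands))

    behaviors: list[str] = []
    targets: list[int] = []
    weights: list[float] = []

    def add(behavior: str, target: int, weight: float) -> None:
        if weight > 0.0:
            behaviors.append(behavior)
            targets.append(target)
            weights.append(weight)

    for k in range(len(cands)):
        j = int(cands.ids[k])
        d = float(cands.dists[k])
        aff = motiv * float(mixture[k])
        agg = max(0.0, 1.0 - fear_row[j]) * max(0.0, 1.0 - anxiety)
        sub = max(0.0, 1.0 + fear_row[j]) * (1.0 + anxiety)
        if d <= params.interact_dist:
            # one groomer per receiver at a time, and no grooming of a
            # group member that is in the middle of a movement bout
            if (pop.groomed_by[j] in (NONE, i)
                    and pop.activity[j] != Activity.MOVE):
                add("groom", j, w["groom"] * aff)
            add("attack", j, w["attack"] * agg)
            add("leave", j, w["leave"] * sub)
        if d <= params.pers_dist:
            add("affil_signal", j, w["affil_signal"] * aff)
            add("aggr_signal", j, w["aggr_signal"] * agg)
            add("submissive_signal", j, w["submissive_signal"] * sub)
            add("avoid", j, w["avoid"] * sub)
        if params.interact_dist < d <= params.max_dist:
            add("approach", j, w["approach"] * aff)

    add("random_walk", NONE, w["random_walk"])

    weights_arr = np.asarray(weights, dtype=float)
    total = weights_arr.sum()
    p_active = activity_probability(pop.arousal[i]) if total > 0 else 0.0
    probs = np.concatenate([[1.0 - p_active],
                            p_active * weights_arr / total
                            if total > 0 else weights_arr])
    return ActionDistribution(behaviors=["rest"] + behaviors,
                              targets=[NONE] + targets,
                              probs=probs / probs.sum())


def select_action(pop: Population, i: int, cands: CandidateSet,
                  params: ModelParams, rng: np.random.Generator,
                  now: float | None = None) -> tuple[str, int]:
    """Sample one behavior-partner combination for ego."""
    dist = action_distribution(pop, i, cands, params, now)
    return dist.sample(rng)


# --------------------------------------------------------------------------
# movement
# --------------------------------------------------------------------------

def execute_movement_step(pop: Population, i: int, dt_seconds: float,
                          rng: np.random.Generator) -> bool:
    """Advance agent i's current movement bout by one step.

    Returns True when the bout terminates (arrival for approach/grouping
    at the interaction distance; escape beyond personal distance for
    avoid/leave/flee).  A random walk never self-terminates.
    """
    params = pop.params
    kind = MoveKind(pop.move_kind[i])
    if kind == MoveKind.NONE:
        raise ValueError("agent has no movement bout in progress")
    step = params.speed * dt_seconds
    world = params.world_size

    if kind == MoveKind.RANDOM_WALK:
        pop.heading[i] = (pop.heading[i]
                          + rng.uniform(-params.random_walk_turn,
                                        params.random_walk_turn)) % 360.0
        rad = math.radians(pop.heading[i])
        pop.pos[i] = wrap_position(
            pop.pos[i] + step * np.array([math.cos(rad), math.sin(rad)]),
            world)
        return False

    j = int(pop.move_target[i])
    delta = torus_delta(pop.pos[i], pop.pos[j], world)
    dist = float(np.hypot(delta[0], delta[1]))

    if kind in (MoveKind.APPROACH, MoveKind.GROUPING):
        if dist <= params.interact_dist:
            return True
        travel = min(step, dist - params.interact_dist)
        pop.pos[i] = wrap_position(pop.pos[i] + delta / dist * travel, world)
        pop.heading[i] = bearing_deg(pop.pos[i], pop.pos[j], world)
        return dist - travel <= params.interact_dist

    # avoid / leave / flee: straight away from the target
    if dist > params.pers_dist:
        return True
    if dist > 0:
        direction = -delta / dist
    else:  # coincident positions: pick the current heading
        rad = math.radians(pop.heading[i])
        direction = np.array([math.cos(rad), math.sin(rad)])
    pop.pos[i] = wrap_position(pop.pos[i] + direction * step, world)
    pop.heading[i] = math.degrees(math.atan2(direction[1], direction[0])) % 360.0
    return dist + step > params.pers_dist


# --------------------------------------------------------------------------
# aggression
# --------------------------------------------------------------------------

def win_probability(dom_i: float, dom_j: float, eta: float) -> float:
    """Sigmoid win chance of i in an escalated fight against j."""
    return 1.0 / (1.0 + math.exp(-eta * (dom_i - dom_j)))


def counter_attack_probability(dom_victim: float, dom_attacker: float,
                               eta_c: float) -> float:
    """Probability the victim counter-attacks; 0.5 at equal rank, higher
    when the attacker ranks below the victim."""
    return 1.0 / (1.0 + math.exp(-eta_c * (dom_victim - dom_attacker)))


# --------------------------------------------------------------------------
# scanning
# --------------------------------------------------------------------------

def maybe_scan(pop: Population, i: int, rng: np.random.Generator) -> bool:
    """While resting, expand the view to 360 degrees with probability
    increasing in arousal.  Refused outside resting bouts."""
    params = pop.params
    if pop.activity[i] != Activity.REST:
        raise ValueError("scanning is only available while resting")
    if rng.uniform() < min(max(pop.arousal[i], 0.0), 1.0):
        pop.view[i] = params.max_angle
        return True
    return False
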