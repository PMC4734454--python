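"""World geometry, agent state and population initialization.

The world is a continuous square torus (default 300 m x 300 m).  Agents
are macaque-like individuals characterized by a fixed dominance strength
``dom`` in [0.05, 1.0], a position and heading, a view angle, a general
emotional state (arousal, anxiety, satisfaction, each in [0, 1]) and two
directed dyadic attitudes per partner:

* ``FEAR[i, j] = dom[j] - dom[i]`` -- fixed, antisymmetric, governs
  aggression and submission tendencies;
* ``LIKE[i, j]`` in [0, 1] -- dynamic, accumulates satisfaction from
  grooming received from j and decays with half-life ``lhw``.

For speed the population state is stored column-wise in numpy arrays on
a :class:`Population`; :class:`Agent` is a light per-index view used by
the functional API and the tests.
"""

from __future__ import annotations

import math
from enum import IntEnum

import numpy as np

from .params import ModelParams

NONE = -1  # sentinel for "no partner"


class Activity(IntEnum):
    REST = 0
    MOVE = 1
    GROOM = 2


class MoveKind(IntEnum):
    NONE = -1
    APPROACH = 0
    AVOID = 1
    LEAVE = 2
    FLEE = 3
    GROUPING = 4
    RANDOM_WALK = 5


# --------------------------------------------------------------------------
# torus geometry
# --------------------------------------------------------------------------

def torus_delta(a: np.ndarray, b: np.ndarray, world: float) -> np.ndarray:
    """Shortest displacement vector(s) from a to b under wrap-around."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - world * np.round(d / world)


def torus_distance(a, b, world: float):
    """Minimal wrap-around Euclidean distance between points on the torus."""
    d = torus_delta(a, b, world)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_position(p: np.ndarray, world: float) -> np.ndarray:
    return np.mod(p, world)


def bearing_deg(a: np.ndarray, b: np.ndarray, world: float) -> float:
    """Bearing from a to b in degrees CCW from the +x axis, in [0, 360)."""
    d = torus_delta(a, b, world)
    return math.degrees(math.atan2(d[1], d[0])) % 360.0


def angle_offset(heading: float, bearing: float) -> float:
    """Absolute angular offset between a heading and a bearing, <= 180."""
    off = (bearing - heading) % 360.0
    return min(off, 360.0 - off)


# --------------------------------------------------------------------------
# attitudes
# --------------------------------------------------------------------------

def fear_attitude(dom_i: float, dom_j: float) -> float:
    """Directed FEAR of i toward j: the dominance difference dom_j - dom_i."""
    return dom_j - dom_i


def fear_matrix(dom: np.ndarray) -> np.ndarray:
    """Antisymmetric dyadic FEAR matrix; entry [i, j] = dom[j] - dom[i]."""
    dom = np.asarray(dom, dtype=float)
    return dom[None, :] - dom[:, None]


# --------------------------------------------------------------------------
# population
# --------------------------------------------------------------------------

class Population:
    """Column-wise state of all agents plus the shared dyadic attitudes."""

    def __init__(self, params: ModelParams):
        n = params.n_agents
        self.params = params
        self.n = n
        self.dom = np.zeros(n)
        self.pos = np.zeros((n, 2))
        self.heading = np.zeros(n)
        self.view = np.full(n, params.view_angle)
        self.arousal = np.full(n, params.default_arousal)
        self.anxiety = np.zeros(n)
        self.satisfaction = np.zeros(n)
        self.arousal_limit = np.full(n, params.arousal_limits["default"])
        self.partner_sat = np.zeros((n, n))
        self.like = np.zeros((n, n))
        self.like_time = np.zeros((n, n))   # last LIKE anchor time per dyad
        self.last_update = np.zeros(n)      # last emotion relax time
        self.my_time = np.zeros(n)          # next scheduled self activation
        # activity bookkeeping
        self.activity = np.full(n, int(Activity.REST), dtype=np.int64)
        self.move_kind = np.full(n, int(MoveKind.NONE), dtype=np.int64)
        self.move_target = np.full(n, NONE, dtype=np.int64)
        self.groom_target = np.full(n, NONE, dtype=np.int64)   # i grooms j
        self.groomed_by = np.full(n, NONE, dtype=np.int64)     # j grooms i
        self.dominant_near = np.zeros(n, dtype=bool)
        # instrumentation: number of LIKE values read during action selection
        self.like_reads = 0

    @property
    def fear(self) -> np.ndarray:
        return fear_matrix(self.dom)

    def agent(self, i: int) -> "Agent":
        return Agent(self, i)

    def distances_from(self, i: int) -> np.ndarray:
        """Torus distances from agent i to every agent (self = 0)."""
        return torus_distance(self.pos[i], self.pos, self.params.world_size)


class Agent:
    """Per-index view onto a :class:`Population` (no state of its own)."""

    __slots__ = ("pop", "id")

    def __init__(self, pop: Population, i: int):
        self.pop = pop
        self.id = int(i)

    def _get(name):  # noqa: N805 - descriptor factory
        def getter(self):
            return self.pop.__dict__[name][self.id]

        def setter(self, value):
            self.pop.__dict__[name][self.id] = value

        return property(getter, setter)

    my_dom = _get("dom")
    pos = _get("pos")
    heading = _get("heading")
    view = _get("view")
    arousal = _get("arousal")
    anxiety = _get("anxiety")
    satisfaction = _get("satisfaction")
    arousal_limit = _get("arousal_limit")
    partner_sat = _get("partner_sat")
    like = _get("like")
    my_time = _get("my_time")
    last_update = _get("last_update")
    activity = _get("activity")

    del _get

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Agent(id={self.id}, dom={self.my_dom:.2f}, "
                f"arousal={self.arousal:.3f}, anxiety={self.anxiety:.3f})")


def init_population(params: ModelParams, rng: np.random.Generator) -> Population:
    """Create a population in its initial configuration.

    Dominance strengths are evenly spaced over [dom_min, dom_max] (agent 0
    lowest-ranking).  Positions are uniform in a disc of 50 m diameter
    centered in the world; headings uniform in [1, 360) degrees; arousal at
    its default, anxiety, satisfaction and all LIKE attitudes at zero; the
    first activation of each agent is drawn from Normal(1, 0.05) minutes.
    """
    params.validate()
    pop = Population(params)
    n = params.n_agents
    if n > 1:
        pop.dom[:] = np.linspace(params.dom_min, params.dom_max, n)
    else:
        pop.dom[:] = params.dom_max

    # uniform points in a disc via rejection-free polar sampling
    radius = params.init_disc_diameter / 2.0
    center = params.world_size / 2.0
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    pop.pos[:, 0] = wrap_position(center + r * np.cos(theta), params.world_size)
    pop.pos[:, 1] = wrap_position(center + r * np.sin(theta), params.world_size)

    pop.heading[:] = rng.uniform(1.0, 360.0, size=n)
    pop.my_time[:] = rng.normal(1.0, 0.05, size=n)
    # truncate at > 0 (time moves forward)
    while np.any(pop.my_time <= 0):
        bad = pop.my_time <= 0
        pop.my_time[bad] = rng.normal(1.0, 0.05, size=int(bad.sum()))
    return pop
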