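"""Model parameters and configuration handling.

All model constants live in a single :class:`ModelParams` dataclass whose
field names mirror the configuration file keys.  Time is measured in
simulated MINUTES throughout; one simulated day has 12 active hours
(720 min), a week 7 days, a year 50 weeks (252 000 min), and a month is
one twelfth of a year (21 000 min).

Two constants are the experimental axes of the model:

``lhw``
    LIKE-history weight (minutes): the timeframe over which earlier
    received grooming is retained in the partner-specific LIKE attitude.
    Equals the single-interval half-life of LIKE decay.
``lps``
    LIKE-partner selectivity in [0, 1]: the degree to which LIKE
    attitudes bias affiliation-partner choice (0 = null model).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

MINUTE = 1.0
HOUR = 60.0
DAY_MINUTES = 720.0          # 12 active hours
WEEK_MINUTES = 7 * DAY_MINUTES
YEAR_MINUTES = 50 * WEEK_MINUTES      # 252 000 min
MONTH_MINUTES = YEAR_MINUTES / 12.0   # 21 000 min

#: Instantaneous emotion changes per discrete social event:
#: kind -> (delta arousal, delta anxiety).  The relative magnitudes honor
#: the documented orderings (receiving an attack raises arousal more than
#: observing a fight; winning, receiving submission or an affiliative
#: signal lower anxiety; received affiliation lowers arousal below its
#: default); the exact values are calibrated model defaults.
DEFAULT_EVENT_INCREMENTS: dict[str, tuple[float, float]] = {
    "receive_attack": (0.4, 0.3),
    "give_attack": (0.3, 0.15),
    "receive_aggr_signal": (0.2, 0.2),
    "lose_fight": (0.2, 0.3),
    "win_fight": (0.0, -0.1),
    "observe_fight": (0.2, 0.1),
    "receive_submission": (-0.05, -0.1),
    "receive_affil_signal": (-0.05, -0.1),
    "give_affil": (-0.02, 0.0),
    "receive_affil": (-0.05, 0.0),
}

#: Target arousal per lasting social context.  Being groomed is the most
#: calming context, grooming slightly less so; having a dominant group
#: member within personal distance keeps arousal elevated.
DEFAULT_AROUSAL_LIMITS: dict[str, float] = {
    "being_groomed": 0.0,
    "grooming": 0.04,
    "dominant_near": 0.3,
    "default": 0.09,
}

#: Base weights of the behavior classes entering action selection.
#: Calibrated so that default runs land mean grooming-bout durations in
#: the empirically plausible 5.7-6.3 min band (see docs/methods.md).
DEFAULT_BEHAVIOR_WEIGHTS: dict[str, float] = {
    "groom": 2.0,
    "affil_signal": 2.0,
    "approach": 1.0,
    "leave": 0.2,
    "submissive_signal": 1.0,
    "avoid": 0.2,
    "attack": 0.16,
    "aggr_signal": 0.6,
    "random_walk": 0.5,
}


@dataclass
class ModelParams:
    """Every constant of the model, with validated defaults."""

    # --- group and world ---------------------------------------------------
    n_agents: int = 20
    world_size: float = 300.0          # m, torus
    dom_min: float = 0.05              # lowest dominance strength
    dom_max: float = 1.00              # highest dominance strength

    # --- distances (m) -----------------------------------------------------
    interact_dist: float = 1.0
    pers_dist: float = 5.0
    near_dist: float = 20.0            # == GROUP_DIST
    max_dist: float = 50.0
    far_dist: float = 100.0
    min_others: int = 3
    init_disc_diameter: float = 50.0

    # --- perception --------------------------------------------------------
    view_angle: float = 120.0          # degrees
    max_angle: float = 360.0
    max_partners: int = 10

    # --- movement ----------------------------------------------------------
    speed: float = 0.6                 # m/s
    move_step_seconds: float = 3.0
    random_walk_turn: float = 30.0     # max |heading change| per step, deg

    # --- emotion dynamics (per-minute rates) -------------------------------
    default_arousal: float = 0.09
    arousal_rate: float = 0.02
    anxiety_default_decay: float = 0.002
    anxiety_groom_give_decay: float = 0.01
    anxiety_groom_receive_decay: float = 0.02
    sat_receive_inc: float = 0.1
    sat_give_inc: float = 0.05
    sat_default_dec: float = 0.02
    partner_sat_dec: float = 0.02      # tied to sat_default_dec by default

    event_increments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_INCREMENTS))
    arousal_limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AROUSAL_LIMITS))

    # --- emotional bookkeeping (swept axes) --------------------------------
    lhw: float = 720.0                 # minutes; LIKE half-life
    lps: float = 0.5                   # partner selectivity in [0, 1]
    like_policy: str = "lazy"          # "lazy" (per-dyad) or "eager"

    # --- action selection --------------------------------------------------
    behavior_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_WEIGHTS))
    selectivity_gamma: float = 1.0     # exponent on the LIKE mixture
    motiv_anxiety_coef: float = 1.0    # anxiety raises affiliation motivation
    motiv_sat_coef: float = 0.5        # satisfaction lowers it (weaker)
    eta: float = 4.0                   # win-chance sigmoid slope
    eta_counter: float = 4.0           # counter-attack sigmoid slope

    # --- timing regime (minutes unless noted) ------------------------------
    groom_schedule_mean: float = 7.5
    groom_schedule_sd: float = 0.375
    act_delay_mean: float = 1.0        # after discrete one-shot acts
    act_delay_sd: float = 0.05
    react_mean_s: float = 0.1          # reaction to signals / observed fights
    react_sd_s: float = 0.005

    # --- horizons and observation ------------------------------------------
    stab_multiplier: float = 10.0
    stab_min_minutes: float = 100.0 * HOUR   # 6 000 min
    record_minutes: float = 504_000.0        # 2 years
    sample_interval: float = 3.5 * DAY_MINUTES   # 2 520 min
    month_minutes: float = MONTH_MINUTES
    pref_threshold: float = 0.10

    # --- bookkeeping -------------------------------------------------------
    log_events: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.lps <= 1.0:
            raise ValueError("lps must lie in [0, 1]")
        if self.lhw < 0:
            raise ValueError("lhw must be non-negative")
        if not (self.interact_dist <= self.pers_dist <= self.near_dist
                <= self.max_dist <= self.far_dist):
            raise ValueError("distances must be ordered "
                             "interact <= pers <= near <= max <= far")
        if self.view_angle > self.max_angle:
            raise ValueError("view_angle must not exceed max_angle")
        if not 0 < self.dom_min <= self.dom_max <= 1.0:
            raise ValueError("dominance range must satisfy 0 < min <= max <= 1")
        rates = [self.arousal_rate, self.anxiety_default_decay,
                 self.anxiety_groom_give_decay, self.anxiety_groom_receive_decay,
                 self.sat_receive_inc, self.sat_give_inc, self.sat_default_dec,
                 self.partner_sat_dec]
        if any(r < 0 for r in rates):
            raise ValueError("all emotion rates must be non-negative")
        if self.record_minutes <= 0 or self.sample_interval <= 0:
            raise ValueError("horizons must be positive")
        if self.like_policy not in ("lazy", "eager"):
            raise ValueError("like_policy must be 'lazy' or 'eager'")
        if any(w < 0 for w in self.behavior_weights.values()):
            raise ValueError("behavior weights must be non-negative")

    # --- derived quantities -------------------------------------------------
    @property
    def move_step_minutes(self) -> float:
        return self.move_step_seconds / 60.0

    @property
    def n_months(self) -> int:
        """Number of whole months in the recording horizon."""
        return int(round(self.record_minutes / self.month_minutes))

    # --- config I/O ---------------------------------------------------------
    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["event_increments"] = {k: list(v) for k, v in
                                 d["event_increments"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        d = dict(d)
        if "event_increments" in d:
            d["event_increments"] = {k: tuple(v) for k, v in
                                     d["event_increments"].items()}
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: Named horizon presets.  "full" is the complete 2-year recording horizon
#: with the LHW-dependent stabilization rule; "desk" (2 months) and
#: "smoke" (1 week) are scaled tiers for interactive work and testing.
PRESETS: dict[str, dict[str, Any]] = {
    "full": {"record_minutes": 504_000.0, "stab_multiplier": 10.0},
    "desk": {"record_minutes": 2 * MONTH_MINUTES, "stab_multiplier": 10.0},
    "smoke": {"record_minutes": WEEK_MINUTES, "stab_multiplier": 0.0},
}


def preset_params(name: str, **overrides: Any) -> ModelParams:
    """Build :class:`ModelParams` from a named preset plus overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    merged = dict(PRESETS[name])
    merged.update(overrides)
    return ModelParams(**merged)
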