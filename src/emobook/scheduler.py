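"""Continuous-time, event-driven main loop.

Agents carry individual activation times on a shared priority queue; the
agent with the lowest scheduled time acts next (ties broken by lowest
agent id for reproducibility).  On activation an agent's time-dependent
state is relaxed lazily over the interval since its own last update
(mathematically equivalent to relaxing everyone at every event, since
relaxation is a deterministic function of elapsed time and the lasting
context, and contexts only change at events that touch the agents
involved).  The agent then executes a pending movement step, or checks
grouping and selects an action.

Re-activation delays depend on the behavior performed: grooming and
resting bouts are re-scheduled after Normal(7.5, 0.375) minutes,
movement steps every 3 s, reactions to signals and observed fights after
Normal(0.1, 0.005) s, an attack triggers an immediate response of the
victim, and discrete one-shot acts are followed after Normal(1, 0.05)
minutes.  All delays are resampled until strictly positive.

A run consists of a stabilization period (at least 100 hours, longer for
slow LIKE dynamics) followed by the recording window; only the recording
window enters the :class:`~emobook.recording.RunRecord`.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .behavior import (check_grouping, counter_attack_probability,
                       execute_movement_step, maybe_scan, perceive_candidates,
                       select_action, win_probability)
from .core import NONE, Activity, MoveKind, Population, init_population
from .emotions import apply_event_deltas, context_arousal_limit, like_value, \
    relax_agent, update_like
from .params import ModelParams
from .recording import RunRecord

#: external taxonomy used in event logs
LOG_NAMES = {
    "groom": "groom", "affil_signal": "affiliative_signal",
    "approach": "approach", "leave": "leave",
    "submissive_signal": "submissive_signal", "avoid": "avoid",
    "attack": "attack", "aggr_signal": "aggressive_signal",
    "rest": "rest", "random_walk": "random_walk", "grouping": "grouping",
    "flee": "flee", "scan": "scan", "fight": "escalated_fight",
}


def stabilization_duration(lhw: float, params: ModelParams) -> float:
    """Stabilization period before recording: at least 100 hours, and
    proportionally longer for slower LIKE dynamics (higher lhw)."""
    if lhw < 0:
        raise ValueError("lhw must be non-negative")
    return max(params.stab_min_minutes, params.stab_multiplier * lhw)


@dataclass(frozen=True)
class ScheduleEntry:
    time: float
    agent_id: int
    reason: str  # "act" or "step"


class EventQueue:
    """Per-agent activation schedule with lazy invalidation.

    Each agent has exactly one live entry; re-scheduling bumps the
    agent's generation counter so stale heap entries are skipped on pop.
    Ties in time are broken by the lowest agent id.
    """

    def __init__(self, n: int):
        self._heap: list[tuple[float, int, int, str]] = []
        self._gen = [0] * n

    def schedule(self, agent_id: int, time: float, reason: str = "act") -> None:
        self._gen[agent_id] += 1
        heapq.heappush(self._heap, (time, agent_id,
                                    self._gen[agent_id], reason))

    def pop_next(self) -> ScheduleEntry | None:
        """Entry with the minimal time, or None when the queue is empty."""
        while self._heap:
            time, agent_id, gen, reason = heapq.heappop(self._heap)
            if gen == self._gen[agent_id]:
                return ScheduleEntry(time, agent_id, reason)
        return None

    def __len__(self) -> int:
        return sum(1 for t, a, g, r in self._heap if g == self._gen[a])


def truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw resampled until strictly positive (time moves forward)."""
    x = rng.normal(mean, sd)
    while x <= 0.0:
        x = rng.normal(mean, sd)
    return float(x)


def reschedule_delay(behavior: str, params: ModelParams,
                     rng: np.random.Generator) -> float:
    """Delay (minutes) until the next activation after `behavior`."""
    if behavior in ("groom", "rest"):
        return truncated_normal(rng, params.groom_schedule_mean,
                                params.groom_schedule_sd)
    if behavior == "move":
        return params.move_step_minutes
    if behavior == "reaction":
        return truncated_normal(rng, params.react_mean_s,
                                params.react_sd_s) / 60.0
    if behavior == "attack_response":
        return 0.0
    if behavior == "act":
        return truncated_normal(rng, params.act_delay_mean,
                                params.act_delay_sd)
    raise ValueError(f"unknown behavior kind {behavior!r}")


class Simulation:
    """One seeded run of the model."""

    def __init__(self, params: ModelParams, seed: int):
        params.validate()
        self.params = params
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.pop = init_population(params, self.rng)
        n = self.pop.n

        self.stab = stabilization_duration(params.lhw, params)
        self.record_start = self.stab
        self.record_end = self.stab + params.record_minutes
        self.now = 0.0

        self.queue = EventQueue(n)
        for i in range(n):
            self.queue.schedule(i, float(self.pop.my_time[i]), "act")

        # per-groomer bout start times, random-walk end times
        self.bout_start = np.full(n, -1.0)
        self.walk_end = np.full(n, np.inf)

        # recording buffers
        n_samples = int(params.record_minutes // params.sample_interval)
        self.sample_times = self.record_start + params.sample_interval * \
            np.arange(1, n_samples + 1)
        self._next_sample = 0
        self.like_samples = np.zeros((n_samples, n, n))
        n_intervals = int(math.ceil(params.record_minutes
                                    / params.sample_interval))
        self.groom_interval_minutes = np.zeros((max(n_intervals, 1), n, n))
        n_months = int(params.record_minutes // params.month_minutes)
        self.groom_month_minutes = np.zeros((max(n_months, 1), n, n))
        self._has_months = n_months >= 1
        self.bout_durations: list[float] = []
        self.behavior_counts: dict[str, int] = {}
        self.events: list[tuple[float, int, str, int]] | None = \
            [] if params.log_events else None

    # ------------------------------------------------------------------
    # bookkeeping helpers
    # ------------------------------------------------------------------
    def _recording(self) -> bool:
        return self.now >= self.record_start

    def _log(self, actor: int, behavior: str, target: int = NONE) -> None:
        if not self._recording():
            return
        name = LOG_NAMES[behavior]
        self.behavior_counts[name] = self.behavior_counts.get(name, 0) + 1
        if self.events is not None:
            self.events.append((self.now, actor, name, int(target)))

    def _update_limit(self, i: int) -> None:
        """Refresh agent i's dominant-proximity flag and arousal target.

        Caller must have relaxed agent i to the current time first.
        """
        pop = self.pop
        d = pop.distances_from(i)
        d[i] = np.inf
        pop.dominant_near[i] = bool(
            np.any((d <= self.params.pers_dist) & (pop.dom > pop.dom[i])))
        pop.arousal_limit[i] = context_arousal_limit(pop, i, self.params)

    def _add_groom_minutes(self, actor: int, receiver: int,
                           t0: float, t1: float) -> None:
        """Credit a grooming span [t0, t1] to the recording bins."""
        lo = max(t0, self.record_start)
        hi = min(t1, self.record_end)
        if hi <= lo:
            return
        for bins, width in ((self.groom_interval_minutes,
                             self.params.sample_interval),
                            (self.groom_month_minutes
                             if self._has_months else None,
                             self.params.month_minutes)):
            if bins is None:
                continue
            b0 = int((lo - self.record_start) // width)
            b1 = int((hi - self.record_start) // width)
            nbins = bins.shape[0]
            for b in range(b0, b1 + 1):
                if b >= nbins:
                    break
                seg_lo = max(lo, self.record_start + b * width)
                seg_hi = min(hi, self.record_start + (b + 1) * width)
                if seg_hi > seg_lo:
                    bins[b, actor, receiver] += seg_hi - seg_lo

    # ------------------------------------------------------------------
    # LIKE anchoring (lazy per-dyad policy)
    # ------------------------------------------------------------------
    def _anchor_like(self, i: int, j: int) -> None:
        """Re-anchor LIKE[i, j] at the current time.

        Caller must have relaxed agent i (so PARTNER_SAT[i, j] is current).
        """
        pop = self.pop
        dt = self.now - pop.like_time[i, j]
        if dt > 0:
            pop.like[i, j] = update_like(pop.like[i, j],
                                         pop.partner_sat[i, j],
                                         dt, self.params.lhw)
            pop.like_time[i, j] = self.now
        else:
            pop.like[i, j] = max(pop.like[i, j], pop.partner_sat[i, j])

    def _anchor_like_row(self, i: int) -> None:
        """Eager policy: re-anchor agent i's whole LIKE row."""
        pop = self.pop
        dt = self.now - pop.like_time[i]
        pop.like[i] = like_value(pop.like[i], pop.partner_sat[i], dt,
                                 self.params.lhw)
        pop.like_time[i] = self.now

    # ------------------------------------------------------------------
    # bout management
    # ------------------------------------------------------------------
    def _end_groom_bout(self, groomer: int, truncated: bool = False) -> None:
        pop = self.pop
        j = int(pop.groom_target[groomer])
        if j == NONE:
            return
        relax_agent(pop, j, self.now, self.params)
        t0 = self.bout_start[groomer]
        elapsed = self.now - t0
        if self._recording():
            if not truncated:
                self.bout_durations.append(elapsed)
            self._add_groom_minutes(groomer, j, t0, self.now)
        self._anchor_like(j, groomer)
        pop.groom_target[groomer] = NONE
        pop.groomed_by[j] = NONE
        pop.activity[groomer] = Activity.REST
        self._update_limit(groomer)
        self._update_limit(j)

    def _interrupt_incoming(self, i: int) -> None:
        """End a grooming bout currently received by agent i, if any; the
        disturbed groomer reacts shortly after."""
        g = int(self.pop.groomed_by[i])
        if g != NONE:
            relax_agent(self.pop, g, self.now, self.params)
            self._end_groom_bout(g)
            self.queue.schedule(
                g, self.now + reschedule_delay("reaction", self.params,
                                               self.rng), "act")

    def _end_move(self, i: int) -> None:
        """Terminate agent i's movement bout and run the proximity update."""
        pop = self.pop
        pop.activity[i] = Activity.REST
        pop.move_kind[i] = MoveKind.NONE
        pop.move_target[i] = NONE
        self._update_limit(i)
        # lower-ranking group members near i's new position (or who had a
        # dominant neighbor before i left) refresh their arousal targets
        d = pop.distances_from(i)
        for k in range(pop.n):
            if k == i or pop.dom[k] >= pop.dom[i]:
                continue
            if d[k] <= self.params.pers_dist or pop.dominant_near[k]:
                relax_agent(pop, k, self.now, self.params)
                self._update_limit(k)

    def _end_bouts(self, i: int) -> None:
        pop = self.pop
        if pop.activity[i] == Activity.GROOM:
            self._end_groom_bout(i)
        elif pop.activity[i] == Activity.MOVE:
            self._end_move(i)
        self.walk_end[i] = np.inf

    def _start_move(self, i: int, kind: MoveKind, target: int) -> None:
        pop = self.pop
        self._interrupt_incoming(i)  # starting to move ends being groomed
        pop.view[i] = self.params.view_angle
        pop.activity[i] = Activity.MOVE
        pop.move_kind[i] = int(kind)
        pop.move_target[i] = int(target)
        self.queue.schedule(i, self.now + self.params.move_step_minutes,
                            "step")

    def _start_groom(self, i: int, j: int) -> None:
        pop = self.pop
        relax_agent(pop, j, self.now, self.params)
        pop.view[i] = self.params.view_angle
        self._anchor_like(j, i)  # anchor before PARTNER_SAT starts rising
        pop.groom_target[i] = j
        pop.groomed_by[j] = i
        pop.activity[i] = Activity.GROOM
        self.bout_start[i] = self.now
        self._update_limit(i)
        self._update_limit(j)
        self._log(i, "groom", j)
        self.queue.schedule(i, self.now + reschedule_delay("groom",
                                                           self.params,
                                                           self.rng), "act")

    # ------------------------------------------------------------------
    # aggression
    # ------------------------------------------------------------------
    def _handle_attack(self, i: int, j: int) -> None:
        pop = self.pop
        params = self.params
        relax_agent(pop, j, self.now, params)
        self._interrupt_incoming(i)
        self._end_bouts(j)
        self._interrupt_incoming(j)
        apply_event_deltas(pop, i, "give_attack", params)
        apply_event_deltas(pop, j, "receive_attack", params)
        self._log(i, "attack", j)

        p_counter = counter_attack_probability(pop.dom[j], pop.dom[i],
                                               params.eta_counter)
        if self.rng.uniform() < p_counter:
            self._log(j, "fight", i)
            if self.rng.uniform() < win_probability(pop.dom[i], pop.dom[j],
                                                    params.eta):
                winner, loser = i, j
            else:
                winner, loser = j, i
            apply_event_deltas(pop, winner, "win_fight", params)
            apply_event_deltas(pop, loser, "lose_fight", params)
            # bystanders near either combatant observe the fight
            d_i = pop.distances_from(i)
            d_j = pop.distances_from(j)
            for k in range(pop.n):
                if k in (i, j):
                    continue
                if d_i[k] <= params.pers_dist or d_j[k] <= params.pers_dist:
                    relax_agent(pop, k, self.now, params)
                    apply_event_deltas(pop, k, "observe_fight", params)
                    self.queue.schedule(
                        k, self.now + reschedule_delay("reaction", params,
                                                       self.rng), "act")
        else:
            winner, loser = i, j

        self._log(loser, "flee", winner)
        self._start_move(loser, MoveKind.FLEE, winner)
        if pop.activity[winner] != Activity.MOVE:
            pop.activity[winner] = Activity.REST
            self._update_limit(winner)
            self.queue.schedule(
                winner, self.now + reschedule_delay("act", params, self.rng),
                "act")

    # ------------------------------------------------------------------
    # activation
    # ------------------------------------------------------------------
    def _activate(self, i: int, reason: str) -> None:
        pop = self.pop
        params = self.params
        relax_agent(pop, i, self.now, params)

        if reason == "step" and pop.activity[i] == Activity.MOVE:
            if (pop.move_kind[i] == MoveKind.RANDOM_WALK
                    and self.now >= self.walk_end[i]):
                self._end_bouts(i)
                self._act(i)
                return
            arrived = execute_movement_step(pop, i, params.move_step_seconds,
                                            self.rng)
            if arrived:
                self._end_bouts(i)
                self._act(i)
            else:
                self.queue.schedule(i, self.now + params.move_step_minutes,
                                    "step")
            return

        self._end_bouts(i)
        self._act(i)

    def _act(self, i: int) -> None:
        pop = self.pop
        params = self.params
        if params.like_policy == "eager":
            self._anchor_like_row(i)

        target = check_grouping(pop, i, self.rng)
        if target is not None:
            self._log(i, "grouping", target)
            self._start_move(i, MoveKind.GROUPING, target)
            return

        cands = perceive_candidates(pop, i)
        behavior, j = select_action(pop, i, cands, params, self.rng, self.now)

        if behavior == "rest":
            pop.activity[i] = Activity.REST
            self._update_limit(i)
            if maybe_scan(pop, i, self.rng):
                self._log(i, "scan")
            else:
                self._log(i, "rest")
            self.queue.schedule(i, self.now + reschedule_delay("rest", params,
                                                               self.rng),
                                "act")
        elif behavior == "random_walk":
            self._log(i, "random_walk")
            self._start_move(i, MoveKind.RANDOM_WALK, NONE)
            self.walk_end[i] = self.now + reschedule_delay("act", params,
                                                           self.rng)
        elif behavior == "approach":
            self._log(i, "approach", j)
            self._start_move(i, MoveKind.APPROACH, j)
        elif behavior == "leave":
            self._log(i, "leave", j)
            self._start_move(i, MoveKind.LEAVE, j)
        elif behavior == "avoid":
            self._log(i, "avoid", j)
            self._start_move(i, MoveKind.AVOID, j)
        elif behavior == "groom":
            self._start_groom(i, j)
        elif behavior in ("affil_signal", "aggr_signal", "submissive_signal"):
            pop.view[i] = params.view_angle
            relax_agent(pop, j, self.now, params)
            receive_kind = {"affil_signal": "receive_affil_signal",
                            "aggr_signal": "receive_aggr_signal",
                            "submissive_signal": "receive_submission"}[behavior]
            apply_event_deltas(pop, j, receive_kind, params)
            if behavior == "affil_signal":
                apply_event_deltas(pop, i, "give_affil", params)
            self._log(i, behavior, j)
            self.queue.schedule(
                j, self.now + reschedule_delay("reaction", params, self.rng),
                "act")
            pop.activity[i] = Activity.REST
            self._update_limit(i)
            self.queue.schedule(
                i, self.now + reschedule_delay("act", params, self.rng),
                "act")
        elif behavior == "attack":
            pop.view[i] = params.view_angle
            self._handle_attack(i, j)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unhandled behavior {behavior!r}")

    # ------------------------------------------------------------------
    # sampling and the main loop
    # ------------------------------------------------------------------
    def _process_samples_until(self, t: float) -> None:
        pop = self.pop
        while (self._next_sample < len(self.sample_times)
               and self.sample_times[self._next_sample] <= t):
            ts = self.sample_times[self._next_sample]
            for i in range(pop.n):
                relax_agent(pop, i, ts, self.params)
            self.like_samples[self._next_sample] = like_value(
                pop.like, pop.partner_sat, ts - pop.like_time,
                self.params.lhw)
            self._next_sample += 1

    def run(self) -> RunRecord:
        while True:
            entry = self.queue.pop_next()
            if entry is None or entry.time > self.record_end:
                break
            self._process_samples_until(entry.time)
            self.now = entry.time
            self._activate(entry.agent_id, entry.reason)
        # close the window: take remaining samples, credit ongoing bouts
        self._process_samples_until(self.record_end)
        self.now = self.record_end
        for i in range(self.pop.n):
            relax_agent(self.pop, i, self.now, self.params)
        for i in range(self.pop.n):
            if self.pop.activity[i] == Activity.GROOM:
                self._end_groom_bout(i, truncated=True)
        return RunRecord(
            params=self.params.to_dict(),
            seed=self.seed,
            stab_minutes=self.stab,
            record_minutes=self.params.record_minutes,
            sample_times=self.sample_times - self.record_start,
            like_samples=self.like_samples,
            groom_interval_minutes=self.groom_interval_minutes,
            groom_month_minutes=self.groom_month_minutes,
            bout_durations=np.asarray(self.bout_durations),
            behavior_counts=self.behavior_counts,
            events=self.events,
            like_reads=self.pop.like_reads,
        )


def run(params: ModelParams, seed: int) -> RunRecord:
    """Execute one seeded simulation run and return its recording."""
    return Simulation(params, seed).run()
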