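# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of `emobook`, an event-driven, spatially
explicit agent-based model of grooming relationships maintained by
*emotional bookkeeping* in a macaque-like group.

## Model overview

Twenty agents live on a 300 m × 300 m torus. Each agent has a fixed
dominance strength (`myDOM`, evenly spaced on [0.05, 1.0]) and carries:

- three general emotional-state dimensions in [0, 1] — **arousal**
  (activity readiness), **anxiety** (fearfulness) and **satisfaction**
  (contentedness);
- a fixed, directed dyadic **FEAR** attitude,
  `FEAR_ij = myDOM_j − myDOM_i`;
- a dynamic, directed dyadic **LIKE** attitude in [0, 1], the emotional
  bookkeeping device, driven only by grooming received from the
  specific partner.

Two parameters are the study's axes:

- **LHW** (LIKE-history weight, minutes): the single-interval half-life
  of LIKE decay;
- **LPS** (LIKE partner selectivity, in [0, 1]): how strongly LIKE
  biases affiliation-partner choice. `LPS = 0` is the null model: LIKE
  is never read (the implementation counts LIKE reads to prove it).

## Emotional dynamics

### Continuous relaxation

Between events, each state dimension moves linearly at a constant
per-minute rate toward a context-dependent limit:

- arousal: rate 0.02/min toward a limit set by the lasting context
  (being groomed 0.0 < grooming 0.04 < default 0.09 < dominant group
  member within 5 m, 0.3);
- anxiety: decays at 0.002/min by default, 0.01/min while grooming,
  0.02/min while being groomed;
- satisfaction: +0.1/min while being groomed, +0.05/min while grooming,
  −0.02/min otherwise;
- partner-specific satisfaction `PARTNER_SAT_ij`: +0.1/min while being
  groomed by j, −0.02/min otherwise.

All levels are clipped to [0, 1]. Relaxation is applied *lazily*: an
agent's state is brought up to date whenever the agent is touched by an
event. Because relaxation is a deterministic function of elapsed time
and the lasting context, and contexts change only at events involving
the agent, this is mathematically identical to relaxing every agent at
every event, at a fraction of the cost.

### Event increments

Discrete social events add instantaneous increments (arousal Δ, anxiety
Δ): receiving an attack (0.4, 0.3) > giving one (0.3, 0.15) > observing
a fight or receiving an aggressive signal (0.2, 0.2); losing a fight
adds anxiety; winning a fight, receiving submission or receiving an
affiliative signal reduce anxiety by 0.1. The model design fixes the
orderings of these increments but not every magnitude; unspecified
magnitudes are config defaults chosen to honor every ordering (see
`emobook.params.DEFAULT_EVENT_INCREMENTS`).

### LIKE update

```
LIKE(t_n) = max( (LHW·LIKE(t_{n−1}) + Δt·PARTNER_SAT(t_n)) / (LHW + Δt),
                 PARTNER_SAT(t_n) )
```

With `PARTNER_SAT = 0`, decaying over `Δt = LHW` from 1.0 leaves exactly
0.5 — LHW is the single-interval half-life. At `LHW = 0`, LIKE tracks
`PARTNER_SAT` exactly.

The equation is **not composition-invariant**: chaining k updates over
Δt/k each decays faster than one update over Δt. The choice of update
times is therefore part of the model definition. `emobook` anchors each
dyad's LIKE only at grooming-relevant moments (bout start and end) and
evaluates it *read-only* everywhere else (partner choice, sampling), so
the half-life semantics of a quiet dyad are preserved exactly. An
"eager" policy that re-anchors an agent's whole LIKE row at every
activation is available via `ModelParams.like_policy = "eager"` for
sensitivity analysis.

## Behavior

An activated agent first checks **grouping**: if fewer than 3 group
members are within 20 m (judged omnidirectionally) or any member is
farther than 100 m, it approaches a random group member. Otherwise it
perceives its candidates — the ≤ 10 nearest members within 50 m and its
view angle (120°, widened to 360° by scanning; members within 1 m are
always perceived) — and samples one (behavior, partner) pair:

- it rests with probability `1 − arousal`;
- **affiliation** (groom ≤ 1 m, affiliative signal ≤ 5 m, approach
  ≤ 50 m) is weighted by
  `base · (1 + anxiety)(1 − 0.5·satisfaction) · s_ij`, where the
  selectivity factor `s_ij = (1−LPS) + LPS·LIKE_ij`, normalized to a
  mean of 1 over the candidate set;
- **aggression** (attack ≤ 1 m, aggressive signal ≤ 5 m) by
  `base · max(0, 1 − FEAR_ij) · max(0, 1 − anxiety)`;
- **submission** (leave ≤ 1 m, submissive signal and avoid ≤ 5 m) by
  `base · max(0, 1 + FEAR_ij) · (1 + anxiety)`;
- a random walk is always available.

Two design decisions about the selectivity factor deserve record:

1. **Linear mixture.** A sharpened variant (`s_ij` raised to a power
   γ = 3) was rejected: with LIKE starting at 0, a high-selectivity
   agent's affiliation weight becomes `(0.01)³ ≈ 1e−6` and grooming
   never bootstraps (a 2-month run at LPS = 0.99 produced zero bouts).
   The exponent remains available as `selectivity_gamma` (default 1).
2. **Mean-1 normalization.** Without normalization, high LPS suppresses
   the *absolute* affiliation propensity (including approaches) before
   any LIKE has developed, which again prevents bootstrapping.
   Normalizing `s_ij` to mean 1 across the perceived candidates makes
   selectivity purely *distributive*: LPS redistributes a fixed
   affiliation propensity among partners in proportion to LIKE, which
   is the intended meaning of partner selectivity. At LPS = 0 (or when
   all candidates share the same LIKE) the factor is exactly 1.

An attack provokes a counter-attack with probability
`1/(1 + exp(−4·(dom_victim − dom_attacker)))`; an escalated fight is won
by i with probability `1/(1 + exp(−4·(dom_i − dom_j)))`; the loser
flees; bystanders within 5 m of either combatant observe the fight.

## Scheduling

Time is continuous (minutes). Each agent holds one live entry on a
shared priority queue (binary heap with per-agent generation counters
for O(1) invalidation; ties broken by lowest agent id). Delays:
grooming and resting bouts Normal(7.5, 0.375) min; movement steps every
3 s at 0.6 m/s; reactions to signals and observed fights
Normal(0.1, 0.005) s; one-shot acts Normal(1, 0.05) min; all delays
resampled until strictly positive. A grooming bout ends at the
groomer's next scheduled activation or earlier if either party is
interrupted (reaction to a signal, an attack, the receiver starting to
move).

Runs begin with a stabilization period of
`max(6000 min, 10·LHW)` — at least 100 hours, longer for slow LIKE
dynamics — followed by the recording window. Only the window is
recorded. The rule implements a fixed floor, scaled up when LIKE needs
longer to equilibrate.

Horizon presets: `full` (504 000 min = 2 years recorded), `desk`
(42 000 min = 2 months), `smoke` (5 040 min = 1 week, no LHW-scaled
stabilization). LIKE matrices are sampled every 2 520 min (3.5 days);
grooming minutes are binned per sampling interval and per month
(21 000 min).

## Observation and statistics

- **Rates**: dyadic grooming minutes per 3.5-day interval ÷ 42 h;
  individual rate = row sum; group rate = mean of individual rates.
- **Preferred partner**: strictly more than 10% of an actor's total
  grooming given within a month. An actor that gave no grooming has no
  preferred partners.
- **Preference bouts**: maximal runs of consecutive preferred months;
  total preference duration = sum of a dyad's bout lengths.
  Group means of bout statistics are taken over dyads with at least one
  bout (the scale on which durations are meaningfully reported); the
  all-dyad convention (never-preferred dyads contributing zero) is
  available via `summarize_run(..., include_empty_dyads=True)`.
- **Grooming–LIKE correspondence**: row-wise Pearson correlation
  between the grooming-rate and time-averaged LIKE matrices (diagonal
  excluded, zero-variance rows skipped), pooled across rows by Fisher-z
  averaging (|r| clipped at 1 − 1e−12 before `arctanh`).
- **Reciprocity** `tau_rw`: per actor row, Kendall's tau-b between the
  total-preference-duration matrix and its transpose, averaged across
  rows with variation on both sides.
- **Null-model check**: at LPS = 0 the grooming-rate distribution must
  be independent of LHW (Kruskal–Wallis, α = 0.01).

## Calibration

The behavior base weights are study conditions, calibrated so that a
default desk run (LPS = 0.5, LHW = 720) lands its mean grooming-bout
duration inside the empirically plausible 5.7–6.3 min band. A bout's
duration is `min(T, E)` with `T ~ Normal(7.5, 0.375)` min (the
groomer's own schedule) and `E` an approximately exponential
interruption time; the band requires an interruption hazard near
0.06/min. The dominant interruption channel is signals received by an
active groomer (every reaction activation ends the bout). Raising the
*aggressive* weights far enough to hit the band destabilized the null
model (fights → fleeing → progressive group dispersal at LPS = 0), so
the calibration leans on affiliative signals instead; the final
defaults are groom 2.0, approach 1.0, affiliative signal 2.0,
submissive signal 1.0, aggressive signal 0.6, attack 0.16, leave 0.2,
avoid 0.2, random walk 0.5, giving one-week calibration means of
5.99–6.18 min (seeds 21–22, disjoint from all test seeds) and healthy
grooming rates (~2–3 min/h) at every LPS. The calibration was frozen
before the acceptance tests were first executed.

## Reproducibility

All randomness flows from one `numpy.random.Generator` seeded per run.
Sweep seeds derive from
`SeedSequence([base_seed, round(LHW), round(LPS·10⁴), replicate])`, so
every cell/replicate is reproducible independently and in any order.
Identical seeds give bit-identical event logs and summaries (asserted in
the test suite).

## Limitations

- Full-scale headline quantities (2-year recording × 250-run grid:
  preference-bout duration ≈ 2.25 months at LHW = 720/LPS = 0.99, total
  duration ≈ 7 months, tau_rw > 0.875, grooming–LIKE r up to ≈ 0.95)
  are not verified here; at desk scale only the directional effects of
  LPS are asserted. A full sweep (`emobook sweep --preset full`) runs
  overnight on one CPU.
- Magnitudes of some event increments, arousal limits and the
  action-selection base weights are config defaults constrained only by
  the designed orderings and by the bout-duration band; other
  calibrations reproducing the same orderings are possible.
- The lazy LIKE-anchoring policy makes the exact LIKE trajectory depend
  on the (behavior-driven) sequence of anchor points; the eager policy
  bounds the sensitivity of results to this choice.
- Movement is a straight-line/random-walk scheme with instantaneous
  turning; no terrain, no inertia, no collision handling.
- The group is closed and the hierarchy fixed: no rank dynamics,
  migration, kinship or demography.
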