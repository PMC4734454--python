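# emobook

An event-driven, spatially explicit agent-based model of how **emotional
bookkeeping** can maintain grooming relationships in a group of
macaque-like primates — together with the analysis layer (partner
preferences, preference bouts, row-wise matrix correlations,
reciprocity) and a sweep driver for the two model axes.

## The scientific problem

Primates groom a few preferred partners over long periods, yet there is
little evidence that they keep an episodic ledger of who did what for
whom. The *emotional bookkeeping* hypothesis holds that a simple
affective summary suffices: grooming received from a partner leaves a
partner-specific emotional trace (a **LIKE** attitude) that decays over
time, and partner choice biased by LIKE is enough to produce stable,
reciprocated grooming relationships.

`emobook` implements that hypothesis as a mechanistic model and asks:
across which timescales of emotional memory (**LHW**, the LIKE
half-life, 0–21 600 minutes) and which degrees of partner selectivity
(**LPS**, 0–0.99) do stable preferred-partner relationships emerge? The
LPS = 0 column is a built-in null model: LIKE attitudes are maintained
but never read, so any relationship structure there arises without
emotional bookkeeping.

## The model in brief

- 20 agents on a 300 m torus, fixed dominance hierarchy; antisymmetric
  FEAR attitudes equal the dominance differences.
- Continuous time, event-driven: each agent holds one entry on a shared
  priority queue; grooming/resting bouts are rescheduled after
  Normal(7.5, 0.375) min, movement steps every 3 s, reactions to
  signals after ~0.1 s.
- Emotions (arousal, anxiety, satisfaction) relax linearly toward
  context-dependent limits and jump at social events (attacks, fights,
  signals); satisfaction from being groomed is also booked per partner
  (PARTNER_SAT) and aggregated into LIKE with half-life LHW.
- Action selection weighs grooming, signals, approach/leave/avoid,
  attack and random walking by emotional state, FEAR, and — scaled by
  LPS — the LIKE attitudes toward the perceived candidates.
- Recording tracks dyadic grooming minutes, bout durations, periodic
  LIKE matrix samples, and (optionally) the full event log.

See [docs/methods.md](docs/methods.md) for assumptions, parameter
tables, numerical decisions and limitations.

## Worked example

A one-week "smoke" run at the default axes (LHW = 720 min, LPS = 0.5):

```sh
emobook run --preset smoke --seed 7 --out results/demo
```

which prints (exact output of this command):

```json
{
  "seed": 7,
  "lhw": 720.0,
  "lps": 0.5,
  "group_groom_rate": 2.892376200557137,
  "mean_bout_minutes": 6.180761621173229,
  "n_bouts": 786,
  "up_hierarchy_minutes": 2413.5484384350075,
  "down_hierarchy_minutes": 2445.6435785009835,
  "mean_n_preferred": 0.0,
  "mean_pref_bout_months": 0.0,
  "mean_pref_total_months": 0.0,
  "tau_rw": NaN,
  "groom_like_r": 0.24336815935629888,
  "mean_like": 0.2161768686777729
}
```

Reading the summary: each agent grooms ~2.9 minutes per hour on average
(`group_groom_rate`), in bouts of ~6.2 minutes (`mean_bout_minutes`,
786 bouts in the recorded week); grooming minutes split nearly evenly
between up- and down-hierarchy partners; `groom_like_r` is the row-wise
Pearson correlation between grooming given and LIKE attitudes and
`tau_rw` the row-wise Kendall reciprocity of total preference
durations. A one-week window is shorter than the one-month horizon on
which partner preferences are scored, so the preference statistics are
zero (and `tau_rw` undefined) here — those become informative on the
multi-month `desk` and `full` presets.

The same from Python:

```python
from emobook import preset_params, run, summarize_run

params = preset_params("desk", lhw=720.0, lps=0.9)
record = run(params, seed=7)
print(summarize_run(record))
```

A scaled sweep over both axes with the null-model check:

```sh
emobook sweep --preset desk --replicates 5 --base-seed 1 --out results/sweep
emobook check --runs results/sweep/runs.csv   # exits 1 on a violation
emobook analyze --runs results/sweep/runs.csv
```

## Reproduction

- **Tests** (unit, property-based, and one test per acceptance
  criterion; ~7 min on one CPU, dominated by the desk-scale acceptance
  runs):

  ```sh
  python -m pytest -q tests/
  ```

- **Acceptance targets** (recomputed from scratch; one 2-month desk run,
  a few minutes):

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

  writes `t1` (analytic LIKE half-life value, exactly 0.5), and `t2`/`t3`
  (mean grooming-bout duration of the desk run, compared against the
  5.7–6.3 min band).

- **Full study grid** (5 LHW × 5 LPS × 10 replicates at the 2-year
  horizon; overnight on one CPU):

  ```sh
  emobook sweep --preset full --replicates 10 --base-seed 1 --out results/full
  ```

Determinism: every run is a pure function of its parameters and seed;
sweep seeds are derived per cell/replicate, so any subset of the grid
can be reproduced independently.

## Package layout

| module                | contents                                            |
|-----------------------|-----------------------------------------------------|
| `emobook.params`      | all model constants, presets, YAML round-trip       |
| `emobook.core`        | torus geometry, population state, FEAR, initializer |
| `emobook.emotions`    | relaxation, event increments, the LIKE update       |
| `emobook.behavior`    | perception, action selection, movement, aggression  |
| `emobook.scheduler`   | event queue, bout management, the main loop         |
| `emobook.recording`   | run records and their on-disk format                |
| `emobook.metrics`     | rates, preferences, bouts, matrix correlations      |
| `emobook.experiments` | sweep driver, aggregation, null-model check         |
| `emobook.cli`         | `emobook run / sweep / analyze / check`             |
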