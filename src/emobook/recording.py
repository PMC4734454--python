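"""Run output container and its on-disk serialization.

A :class:`RunRecord` holds everything observed during the recording
window of one simulation run:

* dyadic LIKE matrices sampled every 3.5 days (2 520 min),
* dyadic grooming minutes binned per 3.5-day recording interval and per
  month (21 000 min),
* the durations of all grooming bouts that ended in the window,
* optionally the full behavior event log,
* LIKE snapshots at the end of each recorded year (for full runs).

Matrices are actor-by-receiver with an undefined diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RunRecord:
    params: dict
    seed: int
    stab_minutes: float
    record_minutes: float
    sample_times: np.ndarray            # (k,) minutes since recording start
    like_samples: np.ndarray            # (k, n, n)
    groom_interval_minutes: np.ndarray  # (n_intervals, n, n)
    groom_month_minutes: np.ndarray     # (n_months, n, n)
    bout_durations: np.ndarray          # (n_bouts,)
    behavior_counts: dict[str, int] = field(default_factory=dict)
    events: list[tuple[float, int, str, int]] | None = None
    like_reads: int = 0

    @property
    def n(self) -> int:
        return self.like_samples.shape[1]

    @property
    def n_months(self) -> int:
        return self.groom_month_minutes.shape[0]

    def groom_total_minutes(self) -> np.ndarray:
        """Total dyadic grooming minutes over the recording window."""
        return self.groom_interval_minutes.sum(axis=0)

    def events_frame(self) -> pd.DataFrame:
        if self.events is None:
            raise ValueError("run was executed without event logging")
        return pd.DataFrame(self.events,
                            columns=["time", "actor", "behavior", "target"])

    # --- serialization ------------------------------------------------------
    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = self.n
        idx = [f"a{i}" for i in range(n)]

        manifest = {
            "seed": self.seed,
            "stab_minutes": self.stab_minutes,
            "record_minutes": self.record_minutes,
            "n_agents": n,
            "n_samples": len(self.sample_times),
            "like_reads": self.like_reads,
            "behavior_counts": self.behavior_counts,
            "params": self.params,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

        rows = []
        for k, t in enumerate(self.sample_times):
            mat = self.like_samples[k]
            for i in range(n):
                for j in range(n):
                    if i != j:
                        rows.append((float(t), i, j, float(mat[i, j])))
        pd.DataFrame(rows, columns=["time", "i", "j", "value"]).to_csv(
            outdir / "like_samples.csv", index=False)

        rows = []
        for b in range(self.groom_interval_minutes.shape[0]):
            mat = self.groom_interval_minutes[b]
            for i in range(n):
                for j in range(n):
                    if i != j and mat[i, j] > 0:
                        rows.append((b, i, j, float(mat[i, j])))
        pd.DataFrame(rows, columns=["interval_index", "i", "j", "minutes"]
                     ).to_csv(outdir / "groom_minutes.csv", index=False)

        total = pd.DataFrame(self.groom_total_minutes(), index=idx, columns=idx)
        np.fill_diagonal(total.values, np.nan)
        total.to_csv(outdir / "groom_total_minutes.csv")

        if self.events is not None:
            self.events_frame().to_csv(outdir / "events.csv", index=False)
        return outdir
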