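"""Parameter sweeps over the LHW x LPS grid and cross-run aggregation.

The study design crosses five LIKE-history weights (0, 180, 720, 5 400,
21 600 min) with five partner selectivities (0, 0.5, 0.9, 0.95, 0.99) and
runs 10 independent replicates per cell (250 runs at full scale).  Seeds
are derived deterministically from the base seed and the cell
coordinates, so a sweep is reproducible and permutation-invariant in
replicate order.

The LPS = 0 column is the null model: partner choice never reads LIKE
attitudes, so behavioral rates there must be statistically independent of
LHW -- :func:`null_model_check` verifies that invariance.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import fisher_pool, summarize_run
from .params import ModelParams, preset_params
from .scheduler import run as run_simulation

DEFAULT_LHW = (0.0, 180.0, 720.0, 5_400.0, 21_600.0)
DEFAULT_LPS = (0.0, 0.50, 0.90, 0.95, 0.99)


@dataclass
class SweepSpec:
    lhw_values: tuple[float, ...] = DEFAULT_LHW
    lps_values: tuple[float, ...] = DEFAULT_LPS
    replicates: int = 10
    base_seed: int = 1
    preset: str = "full"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0.0 <= v <= 1.0 for v in self.lps_values):
            raise ValueError("all lps values must lie in [0, 1]")

    def cells(self):
        for lhw in self.lhw_values:
            for lps in self.lps_values:
                yield lhw, lps

    def params_for(self, lhw: float, lps: float) -> ModelParams:
        return preset_params(self.preset, lhw=lhw, lps=lps, **self.overrides)


def derive_seed(base_seed: int, lhw: float, lps: float,
                replicate: int) -> int:
    """Deterministic per-run seed: a pure function of the cell coordinates."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(lhw)), int(round(lps * 10_000)),
         int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _run_cell(args) -> dict:
    params, seed, lhw, lps, replicate = args
    rec = run_simulation(params, seed)
    row = summarize_run(rec).to_dict()
    row["replicate"] = replicate
    return row


def run_sweep(spec: SweepSpec, n_jobs: int = 1) -> pd.DataFrame:
    """One RunSummary row per (lhw, lps, replicate).

    Per-run failures are isolated: a failing run is reported as a row with
    ``failed = True`` and NaN statistics rather than aborting the sweep.
    """
    jobs = []
    for lhw, lps in spec.cells():
        params = spec.params_for(lhw, lps)
        for rep in range(spec.replicates):
            seed = derive_seed(spec.base_seed, lhw, lps, rep)
            jobs.append((params, seed, lhw, lps, rep))

    rows: list[dict] = []

    def handle(job, runner):
        params, seed, lhw, lps, rep = job
        try:
            row = runner(job)
            row["failed"] = False
        except Exception as exc:  # noqa: BLE001 - isolate per-run failures
            row = {"seed": seed, "lhw": lhw, "lps": lps, "replicate": rep,
                   "failed": True, "error": str(exc)}
        rows.append(row)

    if n_jobs > 1:
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_run_cell, jobs))
        for job, row in zip(jobs, results):
            row["failed"] = False
            rows.append(row)
    else:
        for job in jobs:
            handle(job, _run_cell)

    df = pd.DataFrame(rows)
    return df.sort_values(["lhw", "lps", "replicate"]).reset_index(drop=True)


def _successful(table: pd.DataFrame) -> pd.DataFrame:
    if "failed" in table.columns:
        return table[~table["failed"].astype(bool)]
    return table


def aggregate_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means over replicates; correlations pooled via Fisher-z."""
    ok = _successful(table)
    records = []
    for (lhw, lps), grp in ok.groupby(["lhw", "lps"]):
        rec = {"lhw": lhw, "lps": lps, "n_runs": len(grp)}
        for col in ("group_groom_rate", "mean_bout_minutes",
                    "mean_n_preferred", "mean_pref_bout_months",
                    "mean_pref_total_months", "tau_rw", "mean_like"):
            if col in grp:
                rec[col] = float(grp[col].mean())
        if "groom_like_r" in grp:
            rec["groom_like_r"] = fisher_pool(grp["groom_like_r"])
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class NullModelReport:
    lhw_values: tuple[float, ...]
    statistic: float
    p_value: float
    violation: bool
    alpha: float = 0.01


def null_model_check(table: pd.DataFrame, alpha: float = 0.01
                     ) -> NullModelReport:
    """Test the null-model invariance: at LPS = 0, grooming rates must not
    differ across LHW settings (Kruskal-Wallis at ``alpha``)."""
    ok = _successful(table)
    null = ok[ok["lps"] == 0.0]
    lhw_values = tuple(sorted(null["lhw"].unique()))
    if len(lhw_values) < 2:
        raise ValueError("null-model check needs LPS = 0 cells for at "
                         "least two LHW values")
    groups = [null.loc[null["lhw"] == v, "group_groom_rate"].to_numpy()
              for v in lhw_values]
    stat, p = stats.kruskal(*groups)
    return NullModelReport(lhw_values=lhw_values, statistic=float(stat),
                           p_value=float(p), violation=bool(p < alpha),
                           alpha=alpha)
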