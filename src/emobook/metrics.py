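"""Observation and statistical analysis of run recordings.

Measures
--------
hourly rates
    Dyadic grooming minutes per 3.5-day recording interval divided by the
    interval's 42 hours; an individual's rate is its row sum; the group
    mean is the mean of the individual rates.
preferred partners
    Partners receiving strictly more than 10% of an actor's total
    grooming given within one month (21 000 min).  An actor that gave no
    grooming in a month has no preferred partners.
preference bouts
    Maximal runs of consecutive months during which a partner stays
    preferred; the total preference duration is the sum of a dyad's bout
    lengths over the recording.
row-wise matrix correlations
    The grooming-LIKE correspondence is the row-wise Pearson correlation
    between two actor-by-receiver matrices (diagonal excluded), combined
    across rows by Fisher-z averaging; reciprocity of total preference
    durations is the row-wise Kendall tau (tau-b) between the duration
    matrix and its transpose, averaged across rows.  Rows without
    variation are skipped in both statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .recording import RunRecord

_Z_CLIP = 1.0 - 1e-12  # |r| clip before the Fisher-z transform


# --------------------------------------------------------------------------
# rates
# --------------------------------------------------------------------------

def hourly_rates(minutes: np.ndarray, interval_minutes: float) -> np.ndarray:
    """Convert dyadic grooming minutes per interval into minutes per hour."""
    minutes = np.asarray(minutes, dtype=float)
    if np.any(minutes < 0):
        raise ValueError("grooming minutes must be non-negative")
    if interval_minutes <= 0:
        raise ValueError("interval must be positive")
    return minutes / (interval_minutes / 60.0)


def individual_rates(rate_matrix: np.ndarray) -> np.ndarray:
    """Per-actor behavioral rate: the row sum over all partners."""
    m = np.asarray(rate_matrix, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    return m.sum(axis=1)


def group_mean_rate(rate_matrix: np.ndarray) -> float:
    """Group mean: the mean of the individual behavioral rates."""
    return float(individual_rates(rate_matrix).mean())


# --------------------------------------------------------------------------
# partner preferences
# --------------------------------------------------------------------------

def preferred_partners(monthly_given: np.ndarray,
                       threshold: float = 0.10) -> np.ndarray:
    """Boolean preferred-partner vector for one actor-month.

    A partner is preferred iff its share of the actor's total grooming
    given that month strictly exceeds ``threshold``.
    """
    given = np.asarray(monthly_given, dtype=float)
    if np.any(given < 0):
        raise ValueError("grooming minutes must be non-negative")
    total = given.sum()
    if total <= 0:
        return np.zeros(given.shape, dtype=bool)
    return given / total > threshold


def preference_series(month_minutes: np.ndarray,
                      threshold: float = 0.10) -> np.ndarray:
    """Monthly preferred-partner booleans, shape (months, n, n)."""
    month_minutes = np.asarray(month_minutes, dtype=float)
    out = np.zeros(month_minutes.shape, dtype=bool)
    for m in range(month_minutes.shape[0]):
        mat = month_minutes[m].copy()
        np.fill_diagonal(mat, 0.0)
        for i in range(mat.shape[0]):
            out[m, i] = preferred_partners(mat[i], threshold)
            out[m, i, i] = False
    return out


def preference_bouts(series: np.ndarray) -> tuple[list[int], float, int]:
    """Bout durations for one dyad's monthly preference series.

    Returns (bout durations in months, mean bout duration, total
    duration).  A dyad with no bouts has mean 0 and total 0.
    """
    series = np.asarray(series, dtype=bool)
    bouts: list[int] = []
    run = 0
    for v in series:
        if v:
            run += 1
        elif run:
            bouts.append(run)
            run = 0
    if run:
        bouts.append(run)
    mean = float(np.mean(bouts)) if bouts else 0.0
    return bouts, mean, int(sum(bouts))


def bout_matrices(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dyad mean bout duration and total duration matrices."""
    _, n, _ = series.shape
    mean_mat = np.zeros((n, n))
    total_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            _, mean, total = preference_bouts(series[:, i, j])
            mean_mat[i, j] = mean
            total_mat[i, j] = total
    return mean_mat, total_mat


# --------------------------------------------------------------------------
# row-wise matrix correlations
# --------------------------------------------------------------------------

def _offdiag_rows(A: np.ndarray):
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        yield A[i][mask[i]]


def fisher_pool(rs) -> float:
    """Average correlation coefficients via the Fisher-z transform."""
    rs = np.asarray(list(rs), dtype=float)
    rs = rs[~np.isnan(rs)]
    if rs.size == 0:
        return float("nan")
    z = np.arctanh(np.clip(rs, -_Z_CLIP, _Z_CLIP))
    return float(np.tanh(z.mean()))


def rowwise_pearson(A: np.ndarray, B: np.ndarray) -> float:
    """Row-wise Pearson correlation of two dyadic matrices.

    Per actor row, Pearson's r over the off-diagonal entries of A's row
    against B's row; rows where either side has zero variance are
    skipped; row coefficients are combined by Fisher-z averaging.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    rs = []
    for a, b in zip(_offdiag_rows(A), _offdiag_rows(B)):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        rs.append(stats.pearsonr(a, b).statistic)
    if not rs:
        warnings.warn("all rows degenerate; row-wise Pearson undefined")
        return float("nan")
    return fisher_pool(rs)


def tau_rw_reciprocity(D: np.ndarray) -> float:
    """Row-wise Kendall tau between a dyadic matrix and its transpose.

    Measures group-level reciprocity: per actor row, Kendall's tau-b over
    the matched off-diagonal entries of D and D-transposed, averaged
    (plain mean) across rows with variation on both sides.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("matrix must be square")
    taus = []
    for x, y in zip(_offdiag_rows(D), _offdiag_rows(D.T)):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        taus.append(stats.kendalltau(x, y).statistic)
    if not taus:
        warnings.warn("all rows degenerate; tau_rw undefined")
        return float("nan")
    return float(np.mean(taus))


# --------------------------------------------------------------------------
# run summary
# --------------------------------------------------------------------------

@dataclass
class RunSummary:
    """Headline statistics of one simulation run."""
    seed: int
    lhw: float
    lps: float
    group_groom_rate: float        # min/h, mean of individual rates
    mean_bout_minutes: float       # grooming bout duration
    n_bouts: int
    up_hierarchy_minutes: float    # grooming toward higher-ranking
    down_hierarchy_minutes: float
    mean_n_preferred: float        # preferred partners per actor-month
    mean_pref_bout_months: float   # over dyads with at least one bout
    mean_pref_total_months: float
    tau_rw: float                  # reciprocity of total pref durations
    groom_like_r: float            # row-wise Pearson, grooming vs LIKE
    mean_like: float

    def to_dict(self) -> dict:
        return asdict(self)


def _last_year_slices(rec: RunRecord, year_minutes: float = 252_000.0):
    """Sample and interval indices falling in the last recorded year
    (or the whole recording when shorter than a year)."""
    start = max(rec.record_minutes - year_minutes, 0.0)
    sample_sel = rec.sample_times > start
    if not sample_sel.any():
        sample_sel[:] = True
    interval = rec.params["sample_interval"]
    n_int = rec.groom_interval_minutes.shape[0]
    t_hi = np.minimum((np.arange(n_int) + 1) * interval, rec.record_minutes)
    int_sel = t_hi > start
    if not int_sel.any():
        int_sel[:] = True
    return sample_sel, int_sel


def summarize_run(rec: RunRecord,
                  include_empty_dyads: bool = False) -> RunSummary:
    """Compute the headline statistics of one recording.

    LIKE and grooming-rate matrices are averaged over the last recorded
    year (or the whole recording when shorter).  Preference statistics
    use the whole recording.  ``include_empty_dyads`` switches the group
    means of the preference-bout statistics from dyads with at least one
    bout (default, the scale on which bout durations are reported) to all
    dyads (never-preferred dyads contributing zero).
    """
    sample_sel, int_sel = _last_year_slices(rec)
    n = rec.n
    if sample_sel.any() and rec.like_samples.shape[0]:
        like_year = rec.like_samples[sample_sel].mean(axis=0)
    else:  # recording shorter than one sampling interval
        like_year = np.full((n, n), np.nan)

    minutes = rec.groom_interval_minutes[int_sel].sum(axis=0)
    interval = rec.params["sample_interval"]
    n_int = int(int_sel.sum())
    span = min(n_int * interval, rec.record_minutes)
    groom_rate = hourly_rates(minutes, span)

    total_minutes = rec.groom_total_minutes()
    up = float(np.triu(total_minutes, 1).sum())    # receiver ranks higher
    down = float(np.tril(total_minutes, -1).sum())

    series = preference_series(rec.groom_month_minutes,
                               rec.params["pref_threshold"])
    mean_mat, total_mat = bout_matrices(series)
    n_pref = series.sum(axis=2).mean() if series.size else 0.0
    has_bout = total_mat > 0
    if include_empty_dyads:
        n = mean_mat.shape[0]
        offdiag = n * (n - 1)
        mean_bout = mean_mat.sum() / offdiag if offdiag else 0.0
        mean_total = total_mat.sum() / offdiag if offdiag else 0.0
    else:
        mean_bout = float(mean_mat[has_bout].mean()) if has_bout.any() else 0.0
        mean_total = (float(total_mat[has_bout].mean())
                      if has_bout.any() else 0.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = tau_rw_reciprocity(total_mat)
        r = (rowwise_pearson(groom_rate, like_year)
             if np.isfinite(like_year).any() else float("nan"))
    off = ~np.eye(n, dtype=bool)
    mean_like = (float(like_year[off].mean())
                 if np.isfinite(like_year).any() else float("nan"))

    bouts = rec.bout_durations
    return RunSummary(
        seed=rec.seed,
        lhw=rec.params["lhw"],
        lps=rec.params["lps"],
        group_groom_rate=group_mean_rate(groom_rate),
        mean_bout_minutes=float(bouts.mean()) if bouts.size else 0.0,
        n_bouts=int(bouts.size),
        up_hierarchy_minutes=up,
        down_hierarchy_minutes=down,
        mean_n_preferred=float(n_pref),
        mean_pref_bout_months=float(mean_bout),
        mean_pref_total_months=float(mean_total),
        tau_rw=float(tau),
        groom_like_r=float(r),
        mean_like=mean_like,
    )
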