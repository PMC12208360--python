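"""From day-level records to one analysis row per worker.

Stages, in order: keep only valid workdays (at least 4 h of work-time
measurement, closed bound), replace structural zeros in the daily behaviour
durations multiplicatively, close each day to a composition, aggregate a
worker's days with the compositional (geometric-mean) centre, and finally
drop workers with missing determinants (complete-case) before modelling.
Every stage reports what it removed so attrition is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from codawork.composition import PARTS, close, ilr_transform

DURATION_COLUMNS = ["sb_hours", "lpa_hours", "mvpa_hours"]


class ExcludedWorkersError(ValueError):
    """Raised when a requested aggregation has no valid days to work with."""


class CompleteCaseError(ValueError):
    """Raised when complete-case filtering empties the dataset."""


@dataclass(frozen=True)
class ValidityRule:
    """A workday counts only with at least this much measured work time."""

    min_work_hours: float = 4.0

    def __post_init__(self) -> None:
        if self.min_work_hours <= 0:
            raise ValueError("min_work_hours must be positive")


def filter_valid_days(
    days: pd.DataFrame, rule: ValidityRule = ValidityRule()
) -> tuple[pd.DataFrame, list]:
    """Keep days with work duration >= the threshold (closed bound).

    Returns the retained days and the ids of workers left with zero valid
    days (flagged, never silently dropped by downstream joins).
    """
    keep = days["work_hours"].to_numpy(dtype=float) >= rule.min_work_hours
    valid = days.loc[keep].reset_index(drop=True)
    excluded = sorted(set(days["worker_id"]) - set(valid["worker_id"]))
    return valid, excluded


def replace_zero_durations(days: pd.DataFrame) -> pd.DataFrame:
    """Multiplicative replacement of exact-zero daily behaviour durations.

    Works on the daily *fractions*: a zero in part j becomes delta_j = half
    the smallest nonzero fraction observed for that part across the dataset,
    and the day's nonzero parts are shrunk by the total mass inserted, so
    each day still sums to its work duration.  Days without zeros are
    untouched.
    """
    durs = days[DURATION_COLUMNS].to_numpy(dtype=float)
    if np.any(durs < 0):
        raise ValueError("negative behaviour duration")
    totals = durs.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("day with zero total behaviour time cannot be closed")
    frac = durs / totals[:, None]
    zero = frac == 0.0
    if not zero.any():
        return days.copy()
    delta = np.empty(frac.shape[1])
    for j in range(frac.shape[1]):
        nz = frac[:, j][frac[:, j] > 0]
        if nz.size == 0:
            raise ValueError(
                f"part {PARTS[j]!r} is zero on every day; nothing to impute from"
            )
        delta[j] = 0.5 * nz.min()
    inserted = (zero * delta).sum(axis=1)
    adj = np.where(zero, np.broadcast_to(delta, frac.shape), frac * (1.0 - inserted)[:, None])
    out = days.copy()
    out[DURATION_COLUMNS] = adj * totals[:, None]
    return out


def aggregate_worker(days: pd.DataFrame, method: str = "geometric") -> pd.DataFrame:
    """Aggregate each worker's valid days into one behaviour composition.

    ``method="geometric"`` (default) takes the compositional centre of the
    daily compositions; ``"arithmetic"`` averages the daily fraction vectors,
    kept as a sensitivity switch.  Input days must already be valid and free
    of zero durations.  Also carries the per-worker geometric-mean behaviour
    hours and day counts used by the descriptive summaries.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if len(days) == 0:
        raise ExcludedWorkersError("no valid days to aggregate")
    durs = days[DURATION_COLUMNS].to_numpy(dtype=float)
    if np.any(durs <= 0):
        raise ValueError("zero or negative duration; run replace_zero_durations first")
    comps = close(durs)

    per_day = pd.DataFrame(
        np.log(comps) if method == "geometric" else comps, columns=list(PARTS)
    )
    per_day[[f"{p}_hours_gm" for p in PARTS]] = np.log(durs)
    per_day["worker_id"] = days["worker_id"].to_numpy()
    grouped = per_day.groupby("worker_id", sort=True)
    agg = grouped.mean()
    agg[[f"{p}_hours_gm" for p in PARTS]] = np.exp(agg[[f"{p}_hours_gm" for p in PARTS]])
    parts = agg[list(PARTS)].to_numpy()
    agg[list(PARTS)] = close(np.exp(parts) if method == "geometric" else parts)
    agg["n_valid_days"] = grouped.size()
    return agg.reset_index()


def complete_case_filter(
    workers: pd.DataFrame, required: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with every required determinant present.

    Returns the retained rows and, for the audit log, the number of missing
    values per required determinant among dropped rows.
    """
    missing_cols = [c for c in required if c not in workers.columns]
    if missing_cols:
        raise KeyError(f"required determinants not in dataset: {missing_cols}")
    isna = workers[list(required)].isna()
    dropped_counts = {c: int(isna[c].sum()) for c in required if isna[c].any()}
    kept = workers.loc[~isna.any(axis=1)].reset_index(drop=True)
    if len(kept) == 0:
        raise CompleteCaseError(
            "complete-case filtering removed every worker; relax the required "
            f"determinant list (missing counts: {dropped_counts})"
        )
    return kept, dropped_counts


def preprocess(
    workers: pd.DataFrame,
    days: pd.DataFrame,
    rule: ValidityRule = ValidityRule(),
    aggregation: str = "geometric",
) -> tuple[pd.DataFrame, dict]:
    """Full chain: validity filter, zero replacement, aggregation, ilr.

    Returns the analysis table (workers with >= 1 valid day, their measured
    composition ``sb/lpa/mvpa`` and ilr coordinates) and an attrition log.
    """
    valid, excluded = filter_valid_days(days, rule)
    if len(valid) == 0:
        raise ExcludedWorkersError("no day passes the validity rule")
    clean = replace_zero_durations(valid)
    agg = aggregate_worker(clean, method=aggregation)
    merged = workers.merge(agg, on="worker_id", how="inner", validate="one_to_one")
    merged[["ilr1", "ilr2"]] = ilr_transform(merged[list(PARTS)].to_numpy())
    log = {
        "n_days_in": int(len(days)),
        "n_days_valid": int(len(valid)),
        "n_workers_in": int(len(workers)),
        "n_workers_valid": int(len(merged)),
        "workers_excluded_no_valid_days": excluded,
    }
    return merged, log
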