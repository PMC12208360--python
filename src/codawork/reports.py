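"""Tabular report builders: descriptives, composition summary, model tables.

All outputs are plain DataFrames destined for CSV, mirroring the study's
reporting conventions: mean (SD) or n (%) per determinant by organisational
level, geometric-mean behaviour hours with closed percentages, per-level
variance estimates with % contributions, and the association tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from codawork.composition import PARTS, close
from codawork.models import CompositionModelFit, PivotModelFit, VarianceDecomposition
from codawork.simulate import (
    INSTITUTION_BINARY,
    INSTITUTION_CONTINUOUS,
    TEAM_CONTINUOUS,
    WORKER_BINARY,
    WORKER_CONTINUOUS,
)

BEHAVIOUR_LABELS = {
    "sb": "sedentary_behaviour",
    "lpa": "light_physical_activity",
    "mvpa": "moderate_to_vigorous_physical_activity",
}


def _mean_sd_rows(df: pd.DataFrame, names, level: str) -> list[dict]:
    rows = []
    for name in names:
        if name not in df.columns:
            continue
        vals = pd.to_numeric(df[name], errors="coerce")
        n = int(vals.notna().sum())
        # SD is undefined (reported absent) for a single observation.
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "level": level,
                "determinant": name,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "sd": sd,
                "category": "",
                "count": np.nan,
                "pct": np.nan,
            }
        )
    return rows


def _binary_rows(df: pd.DataFrame, spec: dict, level: str) -> list[dict]:
    rows = []
    for name, (_, lab1, lab0) in spec.items():
        if name not in df.columns:
            continue
        vals = df[name].dropna()
        for lab in (lab1, lab0):
            count = int((vals == lab).sum())
            rows.append(
                {
                    "level": level,
                    "determinant": name,
                    "n": int(len(vals)),
                    "mean": np.nan,
                    "sd": np.nan,
                    "category": lab,
                    "count": count,
                    "pct": 100.0 * count / len(vals) if len(vals) else np.nan,
                }
            )
    return rows


def summarise_determinants(workers: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: mean (SD) or n (%) per determinant at each level.

    Team- and institution-level determinants are summarised over unique
    teams/institutions, not over workers.
    """
    rows = _mean_sd_rows(workers, WORKER_CONTINUOUS, "worker")
    rows += _binary_rows(workers, WORKER_BINARY, "worker")
    teams = workers.drop_duplicates("team_id")
    rows += _mean_sd_rows(teams, TEAM_CONTINUOUS, "team")
    insts = workers.drop_duplicates("institution_id")
    rows += _mean_sd_rows(insts, INSTITUTION_CONTINUOUS, "institution")
    rows += _binary_rows(insts, INSTITUTION_BINARY, "institution")
    return pd.DataFrame(rows)


def summarise_composition(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Average behaviour distribution: geometric-mean hours and closed %.

    Expects the per-worker aggregate from :func:`codawork.preprocess.
    aggregate_worker` (columns ``{part}_hours_gm``).  Hours are the
    geometric mean over workers of each worker's geometric-mean daily hours;
    percentages are their closure.
    """
    hours = np.array(
        [np.exp(np.log(aggregated[f"{p}_hours_gm"]).mean()) for p in PARTS]
    )
    pct = 100.0 * close(hours)
    return pd.DataFrame(
        {
            "behaviour": [BEHAVIOUR_LABELS[p] for p in PARTS],
            "geometric_mean_hours": hours,
            "pct_of_work_time": pct,
        }
    )


def vca_table(vd: VarianceDecomposition) -> pd.DataFrame:
    tab = vd.as_table()
    for coord, comps in vd.per_coordinate.items():
        tab[f"estimate_{coord}"] = tab["level"].map(comps)
    return tab


def model1_table(fit: CompositionModelFit) -> pd.DataFrame:
    return fit.table.reset_index()


def pivot_table(fits: dict[str, PivotModelFit]) -> pd.DataFrame:
    frames = []
    for part, fit in fits.items():
        t = fit.table.reset_index()
        t.insert(0, "pivot", BEHAVIOUR_LABELS[part])
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
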