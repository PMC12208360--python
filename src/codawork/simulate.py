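"""Hierarchical synthetic data for the childcare time-use study design.

The generator emulates the observed study structure: 16 day-nursery
institutions, ~73 teams, ~178 workers, each worker measured on 1-5 workdays
(mean ~3.3) with a lognormal work duration (geometric mean 6.61 h).  The
behaviour composition is generated on the ilr scale as

    ilr_c = grand_mean_c + sum_d beta_dc (x_d - centre_d)
            + u_institution,c + u_team,c + e_worker,c

with mean-zero Gaussian random intercepts at per-coordinate variances
defaulting to the study's estimated components (worker 0.079, team 0.0017,
institution 0.0021), and an optional day-level Gaussian wobble around the
worker value so that the validity filter and aggregation are exercised.
Day durations are the inverse-ilr composition scaled by that day's work
hours.

Determinants are drawn independently: continuous ones from truncated
normals whose *truncated* mean matches the published sample mean exactly
(underlying parameters are moment-matched, since naive truncation shifts
the mean), binaries from Bernoulli at the published proportions.
Missingness is masked MCAR per cell, after outcomes are generated, at a
rate calibrated so that complete-case filtering reproduces the observed
attrition (178 -> ~155 workers).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from codawork.composition import PARTS, ilr_transform, inverse_ilr

# --------------------------------------------------------------------------
# Determinant catalogue: published sample moments and instrument ranges.
# Continuous: (mean, sd, lower, upper).  Binary: probability of the coded-1
# level, with labels (level1, level0).

WORKER_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "age": (36.5, 11.7, 18.0, 70.0),
    "work_hours": (35.0, 2.6, 8.0, 60.0),
    "bmi": (25.3, 5.3, 15.0, 60.0),
    "physical_exertion": (5.9, 1.8, 0.0, 10.0),
    "pain_regions": (2.5, 1.8, 0.0, 8.0),
    "max_pain_intensity": (5.6, 2.5, 0.0, 10.0),
    "pain_interference": (3.5, 6.6, 0.0, 28.0),
    "influence": (69.8, 14.9, 0.0, 100.0),
    "support": (70.8, 14.3, 0.0, 100.0),
}
WORKER_BINARY: dict[str, tuple[float, str, str]] = {
    "sex": (0.843, "female", "male"),
    "job_type": (0.567, "pedagogue", "non_pedagogue"),
}
TEAM_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "n_children": (12.0, 0.9, 6.0, 20.0),
    "worker_child_ratio": (0.3, 0.09, 0.05, 1.0),
}
INSTITUTION_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "staff_ratio": (0.3, 0.2, 0.0, 1.5),
}
INSTITUTION_BINARY: dict[str, tuple[float, str, str]] = {
    "institution_type": (0.625, "public", "private"),
}

#: The 15 determinants entering the association models, in reporting order.
DETERMINANTS: tuple[str, ...] = (
    "age",
    "sex",
    "work_hours",
    "job_type",
    "bmi",
    "physical_exertion",
    "pain_regions",
    "max_pain_intensity",
    "pain_interference",
    "influence",
    "support",
    "n_children",
    "worker_child_ratio",
    "institution_type",
    "staff_ratio",
)

#: Worker-level questionnaire/health determinants eligible for missingness.
MISSINGNESS_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "work_hours",
    "job_type",
    "bmi",
    "physical_exertion",
    "pain_regions",
    "max_pain_intensity",
    "pain_interference",
    "influence",
    "support",
)

WORKERS_SCHEMA_NUMERIC = [
    "age",
    "work_hours",
    "bmi",
    "physical_exertion",
    "pain_regions",
    "max_pain_intensity",
    "pain_interference",
    "influence",
    "support",
    "n_children",
    "worker_child_ratio",
    "staff_ratio",
    "sb_true",
    "lpa_true",
    "mvpa_true",
]
DAYS_SCHEMA_NUMERIC = ["day", "work_hours", "sb_hours", "lpa_hours", "mvpa_hours"]


class DatasetFormatError(ValueError):
    """Raised when a stored dataset violates the documented CSV schema."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_institutions: int = 16
    #: teams per institution: int, or {count: probability}
    teams_per_institution: Any = field(default_factory=lambda: {4: 0.5, 5: 0.5})
    #: workers per team: int, or {count: probability}
    workers_per_team: Any = field(default_factory=lambda: {2: 0.60, 3: 0.35, 4: 0.05})
    var_worker: float = 0.079
    var_team: float = 0.0017
    var_institution: float = 0.0021
    #: determinant -> (effect on ilr1, effect on ilr2), per raw unit
    betas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "physical_exertion": (-0.03, 0.0),
            "max_pain_intensity": (0.03, 0.0),
        }
    )
    grand_mean_composition: tuple[float, float, float] = (0.4767, 0.4000, 0.1233)
    #: measurement days per worker: int, or {count: probability}
    days_per_worker: Any = field(
        default_factory=lambda: {1: 0.05, 2: 0.15, 3: 0.35, 4: 0.35, 5: 0.10}
    )
    work_hours_geometric_mean: float = 6.61
    work_hours_log_sd: float = 0.25
    day_noise_sd: float = 0.1
    p_missing_determinant: float = 0.0125
    #: override published moments, e.g. {"age": (40, 0, 18, 70)}
    determinant_overrides: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_institutions < 1:
            raise ValueError("need at least one institution")
        for name in ("var_worker", "var_team", "var_institution"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.day_noise_sd < 0 or self.work_hours_log_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.p_missing_determinant <= 1.0:
            raise ValueError("missingness probability must lie in [0, 1]")
        for dist_name in ("teams_per_institution", "workers_per_team", "days_per_worker"):
            _validate_count_dist(getattr(self, dist_name), dist_name)
        g = np.asarray(self.grand_mean_composition, dtype=float)
        if g.shape != (3,) or np.any(g <= 0):
            raise ValueError("grand_mean_composition must be 3 strictly positive parts")
        for name, b in self.betas.items():
            if len(tuple(b)) != 2:
                raise ValueError(f"beta for {name!r} must give (ilr1, ilr2) effects")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grand_mean_composition"] = list(self.grand_mean_composition)
        d["betas"] = {k: list(v) for k, v in self.betas.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "betas" in d:
            d["betas"] = {k: tuple(v) for k, v in d["betas"].items()}
        if "grand_mean_composition" in d:
            d["grand_mean_composition"] = tuple(d["grand_mean_composition"])
        if "determinant_overrides" in d:
            d["determinant_overrides"] = {
                k: tuple(v) for k, v in d["determinant_overrides"].items()
            }
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _validate_count_dist(dist: Any, name: str) -> None:
    if isinstance(dist, (int, np.integer)):
        if dist < 1:
            raise ValueError(f"{name} must be >= 1")
        return
    if isinstance(dist, Mapping):
        probs = np.array(list(dist.values()), dtype=float)
        counts = np.array(list(dist.keys()))
        if np.any(counts < 1):
            raise ValueError(f"{name} counts must be >= 1")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} probabilities must be non-negative and sum to 1")
        return
    raise ValueError(f"{name} must be an int or a {{count: prob}} mapping")


def _draw_counts(dist: Any, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(dist, (int, np.integer)):
        return np.full(n, int(dist), dtype=int)
    counts = np.array(sorted(dist.keys()), dtype=int)
    probs = np.array([dist[int(c)] for c in counts], dtype=float)
    return rng.choice(counts, size=n, p=probs / probs.sum())


# --------------------------------------------------------------------------
# Truncated-normal moment matching


@functools.lru_cache(maxsize=None)
def matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal hits ``mean``.

    The truncated mean is matched exactly (it is monotone in mu, solved by
    bisection); sigma is then chosen to bring the truncated SD as close as
    possible to ``sd``.  For strongly skewed targets (mean near a bound, SD
    larger than the mean) the SD is not attainable by any truncated normal
    and the closest achievable value is used.
    """
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} outside bracket ({lo}, {hi})")
    if sd == 0:
        return float(mean), 0.0

    def trunc_stats(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with np.errstate(all="ignore"):
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        m = float(m)
        v = float(v)
        return m, np.sqrt(v) if np.isfinite(v) and v >= 0 else np.nan

    def solve_mu(sigma: float) -> float:
        span = 60.0 * max(sigma, 1.0) + (hi - lo)
        return float(
            optimize.brentq(
                lambda mu: trunc_stats(mu, sigma)[0] - mean,
                lo - span,
                hi + span,
                xtol=1e-12,
            )
        )

    def sd_gap(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = solve_mu(sigma)
        got = trunc_stats(mu, sigma)[1]
        # Extreme-tail truncations can defeat the moment formulas; treat as
        # unusable rather than letting NaN leak into the line search.
        return (got - sd) ** 2 if np.isfinite(got) else 1e9 + log_sigma**2

    res = optimize.minimize_scalar(
        sd_gap,
        bounds=(np.log(sd / 10.0), np.log(sd * 10.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma = float(np.exp(res.x))
    return solve_mu(sigma), sigma


def _sample_truncnorm(
    spec: tuple[float, float, float, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    mean, sd, lo, hi = spec
    if sd == 0:
        return np.full(size, float(mean))
    mu, sigma = matched_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


# --------------------------------------------------------------------------
# Generation stages


def sample_hierarchy(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the institution/team/worker skeleton as one row per worker."""
    n_teams = _draw_counts(config.teams_per_institution, config.n_institutions, rng)
    rows = []
    for i in range(config.n_institutions):
        inst = f"I{i + 1:03d}"
        sizes = _draw_counts(config.workers_per_team, int(n_teams[i]), rng)
        for t in range(int(n_teams[i])):
            team = f"{inst}-T{t + 1:02d}"
            for w in range(int(sizes[t])):
                rows.append((inst, team, f"{team}-W{w + 1:02d}"))
    return pd.DataFrame(rows, columns=["institution_id", "team_id", "worker_id"])


def _spec_for(config: SimulationConfig, name: str, table: Mapping[str, tuple]) -> tuple:
    return tuple(config.determinant_overrides.get(name, table[name]))


def sample_determinants(
    skeleton: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach worker-, team- and institution-level determinants to a skeleton.

    Level-specific values are drawn once per unit (e.g. one staff ratio per
    institution) and broadcast to the workers beneath it.
    """
    out = skeleton.copy()
    n = len(out)
    for name in WORKER_CONTINUOUS:
        out[name] = _sample_truncnorm(_spec_for(config, name, WORKER_CONTINUOUS), n, rng)
    for name, (p1, lab1, lab0) in WORKER_BINARY.items():
        out[name] = np.where(rng.random(n) < p1, lab1, lab0)

    teams = out["team_id"].unique()
    for name in TEAM_CONTINUOUS:
        vals = _sample_truncnorm(_spec_for(config, name, TEAM_CONTINUOUS), len(teams), rng)
        out[name] = out["team_id"].map(dict(zip(teams, vals)))
    insts = out["institution_id"].unique()
    for name, (p1, lab1, lab0) in INSTITUTION_BINARY.items():
        vals = np.where(rng.random(len(insts)) < p1, lab1, lab0)
        out[name] = out["institution_id"].map(dict(zip(insts, vals)))
    for name in INSTITUTION_CONTINUOUS:
        vals = _sample_truncnorm(
            _spec_for(config, name, INSTITUTION_CONTINUOUS), len(insts), rng
        )
        out[name] = out["institution_id"].map(dict(zip(insts, vals)))
    return out


def _determinant_centre(config: SimulationConfig, name: str) -> float:
    """Centre used for fixed effects: published mean or level-1 proportion."""
    for table in (WORKER_CONTINUOUS, TEAM_CONTINUOUS, INSTITUTION_CONTINUOUS):
        if name in table:
            return _spec_for(config, name, table)[0]
    for table in (WORKER_BINARY, INSTITUTION_BINARY):
        if name in table:
            return table[name][0]
    raise KeyError(f"unknown determinant {name!r}")


def _numeric_determinant(workers: pd.DataFrame, name: str) -> np.ndarray:
    """Determinant as a numeric column (binary -> indicator of level 1)."""
    col = workers[name]
    for table in (WORKER_BINARY, INSTITUTION_BINARY):
        if name in table:
            return (col == table[name][1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def sample_outcomes(
    workers: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ilr outcomes, latent compositions and day records.

    Returns the worker table extended with ``ilr1_true``/``ilr2_true`` and the
    latent composition ``sb_true``/``lpa_true``/``mvpa_true``, plus a day table
    with per-day work hours and behaviour durations.  Missingness is masked
    last, so outcomes always reflect the complete determinant values.
    """
    workers = workers.copy()
    n = len(workers)
    grand = ilr_transform(np.asarray(config.grand_mean_composition, dtype=float))

    inst_codes = workers["institution_id"].astype("category").cat.codes.to_numpy()
    team_codes = workers["team_id"].astype("category").cat.codes.to_numpy()
    n_inst, n_team = inst_codes.max() + 1, team_codes.max() + 1

    ilr = np.tile(grand, (n, 1))
    for name, (b1, b2) in config.betas.items():
        x = _numeric_determinant(workers, name) - _determinant_centre(config, name)
        ilr += np.outer(x, [b1, b2])
    # Random intercepts, drawn independently per coordinate.
    u_inst = rng.normal(0.0, np.sqrt(config.var_institution), (n_inst, 2))
    u_team = rng.normal(0.0, np.sqrt(config.var_team), (n_team, 2))
    e_work = rng.normal(0.0, np.sqrt(config.var_worker), (n, 2))
    ilr += u_inst[inst_codes] + u_team[team_codes] + e_work

    workers[["ilr1_true", "ilr2_true"]] = ilr
    workers[["sb_true", "lpa_true", "mvpa_true"]] = inverse_ilr(ilr)

    n_days = _draw_counts(config.days_per_worker, n, rng)
    idx = np.repeat(np.arange(n), n_days)
    total_days = idx.size
    log_gm = np.log(config.work_hours_geometric_mean)
    hours = np.exp(rng.normal(log_gm, config.work_hours_log_sd, total_days))
    day_ilr = ilr[idx] + rng.normal(0.0, config.day_noise_sd, (total_days, 2))
    day_comp = np.atleast_2d(inverse_ilr(day_ilr))
    day_index = np.concatenate([np.arange(1, k + 1) for k in n_days]) if n else np.array([], int)
    days = pd.DataFrame(
        {
            "worker_id": workers["worker_id"].to_numpy()[idx],
            "day": day_index,
            "work_hours": hours,
            "sb_hours": day_comp[:, 0] * hours,
            "lpa_hours": day_comp[:, 1] * hours,
            "mvpa_hours": day_comp[:, 2] * hours,
        }
    )

    if config.p_missing_determinant > 0:
        for name in MISSINGNESS_COLUMNS:
            mask = rng.random(n) < config.p_missing_determinant
            workers.loc[mask, name] = np.nan if name in WORKER_CONTINUOUS else pd.NA
    return workers, days


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator: skeleton -> determinants -> outcomes/days."""
    rng = np.random.default_rng(config.seed)
    skeleton = sample_hierarchy(config, rng)
    workers = sample_determinants(skeleton, config, rng)
    return sample_outcomes(workers, config, rng)


# --------------------------------------------------------------------------
# Dataset I/O


def write_dataset(workers: pd.DataFrame, days: pd.DataFrame, directory: str | Path) -> None:
    """Write ``workers.csv`` and ``days.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    workers.to_csv(directory / "workers.csv", index=False)
    days.to_csv(directory / "days.csv", index=False)


def _check_numeric(df: pd.DataFrame, columns: list[str], filename: str) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetFormatError(
                f"{filename}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2}"
            )
        df[col] = converted
    return df


def read_dataset(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a dataset written by :func:`write_dataset`.

    Missing cells stay missing (NaN); duplicated worker ids, unknown headers
    or non-numeric cells in numeric columns raise :class:`DatasetFormatError`
    naming the offending row and column.
    """
    directory = Path(directory)
    workers = pd.read_csv(directory / "workers.csv", dtype=str)
    days = pd.read_csv(directory / "days.csv", dtype=str)
    for req in ("institution_id", "team_id", "worker_id"):
        if req not in workers.columns:
            raise DatasetFormatError(f"workers.csv: missing required column {req!r}")
    for req in ("worker_id", "day", "work_hours"):
        if req not in days.columns:
            raise DatasetFormatError(f"days.csv: missing required column {req!r}")
    dupes = workers["worker_id"][workers["worker_id"].duplicated()]
    if len(dupes):
        raise DatasetFormatError(f"workers.csv: duplicated worker id {dupes.iloc[0]!r}")
    workers = _check_numeric(workers, WORKERS_SCHEMA_NUMERIC + ["ilr1_true", "ilr2_true"], "workers.csv")
    days = _check_numeric(days, DAYS_SCHEMA_NUMERIC, "days.csv")
    unknown_workers = days.loc[~days["worker_id"].isin(workers["worker_id"]), "worker_id"]
    if len(unknown_workers):
        raise DatasetFormatError(
            f"days.csv: worker id {unknown_workers.iloc[0]!r} not present in workers.csv"
        )
    return workers, days
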