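"""Multilevel models for the behaviour composition.

Two analyses, both with nested random intercepts for institutions and for
teams within institutions, fitted by REML (:mod:`codawork.reml`):

* **Variance-components analysis** — the two ilr coordinates are stacked as
  a joint outcome sharing one variance parameter per organisational level
  (worker = residual, team, institution), yielding a single estimate and %
  contribution per level.  A per-coordinate decomposition is exposed as a
  diagnostic.

* **Association models** — Model 1 regresses both ilr coordinates on all 15
  determinants (one fit per coordinate, random structure as above) and
  combines the two per-coordinate Wald z statistics into a 2-df joint test
  per determinant.  The pivot models re-express the outcome with each
  behaviour rotated into the first ilr position and model that single
  coordinate, translating each slope into a % change of the pivot behaviour
  relative to the geometric mean of the other two.

Inference is large-sample Wald (normal reference); no small-sample df
correction and no multiplicity adjustment are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from codawork.composition import PARTS, inverse_ilr, percent_change, pivot_rotate
from codawork.reml import DesignError, MixedDataset, REMLResult, fit_reml
from codawork.simulate import DETERMINANTS

LEVELS = ("worker", "team", "institution")

#: Categorical determinants with (reference level, contrast level).
CATEGORICAL_REFERENCE = {
    "sex": ("male", "female"),
    "job_type": ("pedagogue", "non_pedagogue"),
    "institution_type": ("private", "public"),
}


# --------------------------------------------------------------------------
# Result containers


@dataclass
class VarianceDecomposition:
    """Per-level variance estimates and % contributions (joint over ilr1/ilr2)."""

    estimates: dict[str, float]
    contributions: dict[str, float]
    total: float
    per_coordinate: dict[str, dict[str, float]]
    n_workers: int
    n_teams: int
    n_institutions: int
    converged: bool
    reml_criterion: float

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "estimate": self.estimates[lvl], "pct_contribution": self.contributions[lvl]}
            for lvl in LEVELS
        ]
        rows.append({"level": "total", "estimate": self.total, "pct_contribution": 100.0})
        return pd.DataFrame(rows)


@dataclass
class CompositionModelFit:
    """Model 1: both ilr coordinates on all determinants."""

    table: pd.DataFrame  # one row per determinant
    variance_components: dict[str, dict[str, float]]  # per coordinate
    n_workers: int
    n_teams: int
    n_institutions: int
    converged: bool
    reml_criteria: dict[str, float]
    #: fitted fixed effects keyed by (coordinate, design column)
    betas: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)
    #: reference covariate values (sample means / modes) per design column
    reference_values: dict[str, float] = field(default_factory=dict, repr=False)
    design_columns: list[str] = field(default_factory=list, repr=False)
    observed_ranges: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)


@dataclass
class PivotModelFit:
    """One pivot model: first pivot coordinate of a behaviour on determinants."""

    pivot_part: str
    table: pd.DataFrame
    n_workers: int
    converged: bool
    reml_criterion: float


# --------------------------------------------------------------------------
# Design-matrix construction


def _design_column(workers: pd.DataFrame, name: str) -> tuple[str, np.ndarray]:
    if name in CATEGORICAL_REFERENCE:
        ref, contrast = CATEGORICAL_REFERENCE[name]
        values = workers[name]
        known = {ref, contrast}
        bad = set(values.dropna().unique()) - known
        if bad:
            raise ValueError(f"{name!r} has unexpected levels {sorted(bad)}; known {sorted(known)}")
        return f"{name}[{contrast}]", (values == contrast).to_numpy(dtype=float)
    return name, workers[name].to_numpy(dtype=float)


def build_design(
    workers: pd.DataFrame, determinants: tuple[str, ...] = DETERMINANTS
) -> pd.DataFrame:
    """Fixed-effects design: intercept plus one column per determinant.

    Categorical determinants enter as treatment contrasts against their
    reference level (sex: male, job type: pedagogue, institution type:
    private); continuous ones on their raw scales.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(workers))}
    for name in determinants:
        label, values = _design_column(workers, name)
        cols[label] = values
    X = pd.DataFrame(cols, index=workers.index)
    if X.isna().any().any():
        missing = X.columns[X.isna().any()].tolist()
        raise DesignError(
            f"missing determinant values in {missing}; apply complete_case_filter first"
        )
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) == X.shape[1]:
        return
    # Name the offenders: columns that do not increase the rank when added.
    culprits = []
    rank = 0
    acc = np.empty((mat.shape[0], 0))
    for j, col in enumerate(X.columns):
        trial = np.column_stack([acc, mat[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r == rank:
            culprits.append(col)
        else:
            acc, rank = trial, r
    raise DesignError(f"design matrix is rank deficient; collinear columns: {culprits}")


def _require_hierarchy(workers: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    inst = workers["institution_id"].to_numpy()
    team = workers["team_id"].to_numpy()
    if len(np.unique(inst)) < 2:
        raise DesignError("variance components need at least 2 institutions")
    team_sizes = pd.Series(team).value_counts()
    if team_sizes.max() == 1:
        raise DesignError(
            "every team has exactly one worker: team and institution variance "
            "is confounded with worker variance in this design"
        )
    teams_per_inst = pd.DataFrame({"i": inst, "t": team}).groupby("i")["t"].nunique()
    if teams_per_inst.max() < 2:
        raise DesignError("variance components need some institution with >= 2 teams")
    return inst, team


# --------------------------------------------------------------------------
# Variance-components analysis


def fit_vca(workers: pd.DataFrame, per_coordinate: bool = True) -> VarianceDecomposition:
    """Decompose ilr-scale variance across institution, team and worker.

    ``workers`` needs ``institution_id``, ``team_id`` and the ``ilr1``/``ilr2``
    outcome columns (one row per worker).  The two coordinates are fitted
    jointly with shared variance parameters but separate means; the worker
    level is the residual.  Negative components are truncated at zero by the
    optimiser's constraint.
    """
    inst, team = _require_hierarchy(workers)
    X = np.ones((len(workers), 1))
    datasets = [
        MixedDataset(workers[coord].to_numpy(dtype=float), X, [inst, team])
        for coord in ("ilr1", "ilr2")
    ]
    res = fit_reml(datasets, ["institution", "team"])
    per_coord = {}
    if per_coordinate:  # diagnostic: each coordinate decomposed on its own
        for coord in ("ilr1", "ilr2"):
            r = fit_reml(
                [MixedDataset(workers[coord].to_numpy(dtype=float), X, [inst, team])],
                ["institution", "team"],
            )
            vc = r.variance_components
            per_coord[coord] = {
                "worker": vc["residual"],
                "team": vc["team"],
                "institution": vc["institution"],
            }
    vc = res.variance_components
    estimates = {
        "worker": vc["residual"],
        "team": vc["team"],
        "institution": vc["institution"],
    }
    total = sum(estimates.values())
    contributions = {k: 100.0 * v / total for k, v in estimates.items()}
    return VarianceDecomposition(
        estimates=estimates,
        contributions=contributions,
        total=total,
        per_coordinate=per_coord,
        n_workers=len(workers),
        n_teams=int(len(np.unique(team))),
        n_institutions=int(len(np.unique(inst))),
        converged=res.converged,
        reml_criterion=res.criterion,
    )


# --------------------------------------------------------------------------
# Association models


def _wald_columns(res: REMLResult, names: list[str], which: int = 0) -> pd.DataFrame:
    beta = res.betas[which]
    se = np.sqrt(np.diag(res.cov_betas[which]))
    z = beta / se
    zcrit = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "ci_low": beta - zcrit * se,
            "ci_high": beta + zcrit * se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=names,
    )


def fit_model1(
    workers: pd.DataFrame, determinants: tuple[str, ...] = DETERMINANTS
) -> CompositionModelFit:
    """Whole-composition model: both ilr coordinates on all determinants.

    One REML fit per coordinate (nested random intercepts for institution
    and team), then a 2-df joint Wald test per determinant combining the two
    coordinate-wise z statistics (the coordinates are modelled as
    independent).  Requires complete cases.
    """
    inst, team = _require_hierarchy(workers)
    X = build_design(workers, determinants)
    names = [c for c in X.columns if c != "intercept"]
    fits = {}
    for coord in ("ilr1", "ilr2"):
        fits[coord] = fit_reml(
            [MixedDataset(workers[coord].to_numpy(dtype=float), X.to_numpy(), [inst, team])],
            ["institution", "team"],
        )
    col_names = list(X.columns)
    per_coord = {c: _wald_columns(fits[c], col_names) for c in fits}
    rows = []
    for det in determinants:
        label, _ = _design_column(workers, det)
        w1 = per_coord["ilr1"].loc[label]
        w2 = per_coord["ilr2"].loc[label]
        chi2 = (w1["coef"] / w1["se"]) ** 2 + (w2["coef"] / w2["se"]) ** 2
        rows.append(
            {
                "determinant": det,
                "design_column": label,
                "coef_ilr1": w1["coef"],
                "ci_low_ilr1": w1["ci_low"],
                "ci_high_ilr1": w1["ci_high"],
                "p_ilr1": w1["p"],
                "coef_ilr2": w2["coef"],
                "ci_low_ilr2": w2["ci_low"],
                "ci_high_ilr2": w2["ci_high"],
                "p_ilr2": w2["p"],
                "p_joint": float(stats.chi2.sf(chi2, df=2)),
            }
        )
    table = pd.DataFrame(rows).set_index("determinant")
    ranges = {
        det: (float(np.min(v)), float(np.max(v)))
        for det in determinants
        if det not in CATEGORICAL_REFERENCE
        for v in [workers[det].to_numpy(dtype=float)]
    }
    return CompositionModelFit(
        table=table,
        variance_components={
            c: {
                "worker": fits[c].variance_components["residual"],
                "team": fits[c].variance_components["team"],
                "institution": fits[c].variance_components["institution"],
            }
            for c in fits
        },
        n_workers=len(workers),
        n_teams=int(pd.Series(team).nunique()),
        n_institutions=int(pd.Series(inst).nunique()),
        converged=all(f.converged for f in fits.values()),
        reml_criteria={c: fits[c].criterion for c in fits},
        betas={
            c: dict(zip(col_names, map(float, fits[c].betas[0]))) for c in fits
        },
        reference_values=_reference_row(workers, determinants),
        design_columns=col_names,
        observed_ranges=ranges,
    )


def _reference_row(workers: pd.DataFrame, determinants: tuple[str, ...]) -> dict[str, float]:
    """Reference covariate values: sample mean (continuous) or mode (binary)."""
    ref = {}
    for det in determinants:
        label, values = _design_column(workers, det)
        if det in CATEGORICAL_REFERENCE:
            ref[label] = float(np.round(np.nanmean(values)))  # modal indicator
        else:
            ref[label] = float(np.nanmean(values))
    return ref


def fit_pivot_models(
    workers: pd.DataFrame, determinants: tuple[str, ...] = DETERMINANTS
) -> dict[str, PivotModelFit]:
    """One model per behaviour: its first pivot coordinate on determinants.

    Each slope is also reported as the % change of the pivot behaviour
    relative to the geometric mean of the other two per unit determinant.
    """
    inst, team = _require_hierarchy(workers)
    X = build_design(workers, determinants)
    comps = workers[list(PARTS)].to_numpy(dtype=float)
    out = {}
    for part in PARTS:
        z1 = pivot_rotate(comps, part)[:, 0]
        res = fit_reml(
            [MixedDataset(z1, X.to_numpy(), [inst, team])], ["institution", "team"]
        )
        wald = _wald_columns(res, list(X.columns))
        rows = []
        for det in determinants:
            label, _ = _design_column(workers, det)
            w = wald.loc[label]
            rows.append(
                {
                    "determinant": det,
                    "coef": w["coef"],
                    "ci_low": w["ci_low"],
                    "ci_high": w["ci_high"],
                    "p": w["p"],
                    "percent_change": percent_change(w["coef"]),
                }
            )
        out[part] = PivotModelFit(
            pivot_part=part,
            table=pd.DataFrame(rows).set_index("determinant"),
            n_workers=len(workers),
            converged=res.converged,
            reml_criterion=res.criterion,
        )
    return out


# --------------------------------------------------------------------------
# Prediction curves (ternary-plot input)


def predict_composition_curve(
    fit: CompositionModelFit,
    determinant: str,
    grid=None,
    n_points: int = 25,
) -> pd.DataFrame:
    """Predicted compositions along a determinant grid at reference covariates.

    Other covariates are held at sample means (continuous) or modes
    (binary); random effects at zero.  The predicted (ilr1, ilr2) pair is
    mapped back through the inverse ilr transform, yielding the long-format
    curve used for ternary plots.
    """
    if determinant in CATEGORICAL_REFERENCE:
        raise ValueError("prediction curves are defined for continuous determinants")
    if determinant not in fit.observed_ranges:
        raise KeyError(f"{determinant!r} was not a determinant of this fit")
    lo, hi = fit.observed_ranges[determinant]
    if grid is None:
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        warnings.warn(
            f"grid for {determinant!r} extends beyond the observed range "
            f"[{lo:.3g}, {hi:.3g}]; extrapolating",
            stacklevel=2,
        )
    ref = fit.reference_values
    zs = []
    for coord in ("ilr1", "ilr2"):
        betas = fit.betas[coord]
        base = betas["intercept"] + sum(betas[name] * val for name, val in ref.items())
        slope = betas[determinant]
        zs.append(base + slope * (grid - ref[determinant]))
    comps = inverse_ilr(np.column_stack(zs))
    out = pd.DataFrame(comps, columns=list(PARTS))
    out.insert(0, "value", grid)
    out.insert(0, "determinant", determinant)
    return out
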