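"""Replicated simulation studies validating the estimation pipeline.

Three studies, each simulating with the generator defaults (the study-sized
hierarchy and published variance components / effect sizes) unless noted:

* variance-component recovery at the study size (16 institutions, ~73
  teams, ~178 workers) — does the joint REML decomposition reproduce the
  dominant worker-level contribution?
* fixed-effect recovery at a larger size (~1000 workers, no missingness) —
  is the physical-exertion coefficient on ilr1 estimated without bias?
* type-I error of the 2-df joint determinant test under a null generator
  (all effects zero) at the study size.

Each replicate runs the full chain: generate -> validity filter -> zero
replacement -> compositional aggregation -> REML fit.  Replicate seeds are
spawned from one base seed, so every study is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from codawork.models import fit_model1, fit_vca
from codawork.reml import DesignError
from codawork.preprocess import complete_case_filter, preprocess
from codawork.simulate import DETERMINANTS, SimulationConfig, generate_dataset

_SEED_MOD = 2**31


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s % _SEED_MOD) for s in state]


def _simulate_analysis(config: SimulationConfig):
    workers, days = generate_dataset(config)
    analysis, _ = preprocess(workers, days)
    return analysis


def vca_recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Mean per-level variance estimates and % contributions over replicates."""
    base = config or SimulationConfig()
    ests, contribs = [], []
    for s in _replicate_seeds(seed, n_replicates):
        analysis = _simulate_analysis(replace(base, seed=s))
        vd = fit_vca(analysis, per_coordinate=False)
        ests.append([vd.estimates[lvl] for lvl in ("worker", "team", "institution")])
        contribs.append([vd.contributions[lvl] for lvl in ("worker", "team", "institution")])
    ests = np.asarray(ests)
    contribs = np.asarray(contribs)
    return {
        "n_replicates": n_replicates,
        "mean_estimates": dict(zip(("worker", "team", "institution"), ests.mean(axis=0))),
        "mean_contributions_pct": dict(
            zip(("worker", "team", "institution"), contribs.mean(axis=0))
        ),
        "sd_contributions_pct": dict(
            zip(("worker", "team", "institution"), contribs.std(axis=0, ddof=1))
        ),
    }


def effect_recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    determinant: str = "physical_exertion",
) -> dict:
    """Mean recovered ilr1 coefficient for one determinant at ~1000 workers.

    Uses a larger hierarchy (50 institutions x 5 teams x 4 workers) with
    missingness off, keeping the published variance components and effect
    sizes, so the sampling error of the replicate mean is small.
    """
    base = SimulationConfig(
        n_institutions=50,
        teams_per_institution=5,
        workers_per_team=4,
        p_missing_determinant=0.0,
    )
    coefs = []
    for s in _replicate_seeds(seed, n_replicates):
        analysis = _simulate_analysis(replace(base, seed=s))
        fit = fit_model1(analysis)
        coefs.append(float(fit.table.loc[determinant, "coef_ilr1"]))
    coefs = np.asarray(coefs)
    return {
        "n_replicates": n_replicates,
        "n_workers": 1000,
        "true_coef": base.betas.get(determinant, (0.0, 0.0))[0],
        "mean_coef": float(coefs.mean()),
        "sd_coef": float(coefs.std(ddof=1)),
    }


def type1_error_study(
    n_replicates: int = 500,
    seed: int = 0,
    determinant: str = "physical_exertion",
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the joint 2-df test under an all-null generator.

    The generator keeps the study-sized hierarchy, variances and missingness
    but zeroes every fixed effect; each replicate applies complete-case
    filtering (as the real analysis would) before fitting.
    """
    base = SimulationConfig(betas={})
    rejections = 0
    degenerate = 0
    n_tested = 0
    for s in _replicate_seeds(seed, n_replicates):
        analysis = _simulate_analysis(replace(base, seed=s))
        complete, _ = complete_case_filter(analysis, DETERMINANTS)
        try:
            fit = fit_model1(complete)
        except DesignError:
            # e.g. all institutions drawn with the same type: that replicate
            # cannot identify every effect, so it contributes no test.
            degenerate += 1
            continue
        n_tested += 1
        if fit.table.loc[determinant, "p_joint"] < alpha:
            rejections += 1
    return {
        "n_replicates": n_replicates,
        "n_tested": n_tested,
        "n_degenerate_designs": degenerate,
        "determinant": determinant,
        "alpha": alpha,
        "rejection_rate": rejections / n_tested,
    }
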