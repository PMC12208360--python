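"""Restricted maximum likelihood for random-intercept linear mixed models.

The estimator targets models of the form

    y = X beta + sum_j Z_j u_j + e,
    u_j ~ N(0, sigma2_j I),   e ~ N(0, sigma2_e I),

where each ``Z_j`` is the indicator matrix of a grouping factor (here:
institutions, and teams nested in institutions — nesting is encoded simply by
giving teams globally unique labels).  Several datasets can be fitted
*jointly* with shared variance parameters but dataset-specific fixed effects;
this is how the two ilr coordinates of the behaviour composition enter the
variance-components analysis as a stacked outcome with one variance per
organisational level, while their means and random-effect realisations stay
independent across coordinates.

Estimation profiles the residual variance and the fixed effects out of the
restricted likelihood, leaving a criterion over the variance *ratios*
``gamma_j = sigma2_j / sigma2_e`` (non-negative).  The criterion is minimised
with L-BFGS-B from a deterministic ANOVA-type start and polished with
Nelder-Mead so that on balanced designs the optimum matches closed-form
expected-mean-squares estimators to high precision.  Matrix algebra uses the
Woodbury identity, so cost scales with the number of groups, not samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_LOG_2PI = float(np.log(2.0 * np.pi))


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable fixed/random designs."""


class ConvergenceError(RuntimeError):
    """Raised when the REML optimiser fails to converge; carries the trace."""

    def __init__(self, message: str, trace: list[tuple[np.ndarray, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class MixedDataset:
    """One outcome vector with its fixed design and random-factor labels."""

    y: np.ndarray
    X: np.ndarray
    factors: list[np.ndarray]  # one label array per variance component

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise DesignError(f"X has {self.X.shape[0]} rows for {n} observations")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise DesignError("non-finite values in outcome or design")
        self.factors = [np.asarray(f) for f in self.factors]
        for f in self.factors:
            if f.shape[0] != n:
                raise DesignError("factor length does not match observations")
        # Dense one-hot indicator per factor; group counts are small here.
        self._Z: list[np.ndarray] = []
        for f in self.factors:
            _, idx = np.unique(f, return_inverse=True)
            Z = np.zeros((n, idx.max() + 1))
            Z[np.arange(n), idx] = 1.0
            self._Z.append(Z)
        # Sufficient statistics: every REML criterion evaluation works off
        # these cross-products (Woodbury), so cost is per-group, not per-row.
        if self._Z:
            Zall = np.hstack(self._Z)
            self._block = np.concatenate(
                [np.full(Z.shape[1], j) for j, Z in enumerate(self._Z)]
            )
            self._ZtZ = Zall.T @ Zall
            self._ZtX = Zall.T @ self.X
            self._Zty = Zall.T @ self.y
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


@dataclass
class REMLResult:
    """Fitted variance components plus per-dataset GLS fixed effects."""

    component_names: list[str]
    gamma: np.ndarray
    sigma2_resid: float
    betas: list[np.ndarray]
    cov_betas: list[np.ndarray]
    criterion: float  # -2 * restricted log-likelihood at the optimum
    converged: bool
    n_obs: int
    n_fixed: int
    n_evals: int = 0
    trace: list = field(default_factory=list, repr=False)

    @property
    def variance_components(self) -> dict[str, float]:
        out = {name: float(g * self.sigma2_resid) for name, g in zip(self.component_names, self.gamma)}
        out["residual"] = float(self.sigma2_resid)
        return out


def _profiled_pieces(ds: MixedDataset, gamma: np.ndarray):
    """Per-dataset GLS pieces for the profiled REML criterion.

    Returns (logdet V0, logdet X'V0^-1 X, RSS_gls, beta, XtWiX) where
    V0 = I + sum_j gamma_j Z_j Z_j' (residual variance factored out).
    Everything is computed from precomputed cross-products through the
    Woodbury identity with U = [sqrt(gamma_j) Z_j]:
    a' V0^-1 b = a'b - (U'a)' (I + U'U)^-1 (U'b).
    """
    if len(gamma) and gamma.max() > 0:
        s = np.sqrt(gamma[ds._block])
        M = ds._ZtZ * np.outer(s, s)
        M[np.diag_indices_from(M)] += 1.0
        cM = cho_factor(M, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
        A = s[:, None] * ds._ZtX  # U'X
        b = s * ds._Zty  # U'y
        MiA = cho_solve(cM, A)
        Mib = cho_solve(cM, b)
        XtWiX = ds._XtX - A.T @ MiA
        XtWiy = ds._Xty - A.T @ Mib
        yWiy = ds._yty - b @ Mib
    else:
        logdet_v = 0.0
        XtWiX = ds._XtX
        XtWiy = ds._Xty
        yWiy = ds._yty
    cX = cho_factor(XtWiX, lower=True)
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cX[0]))))
    beta = cho_solve(cX, XtWiy)
    rss = float(yWiy - beta @ XtWiy)
    return logdet_v, logdet_x, rss, beta, XtWiX


def _criterion(datasets: list[MixedDataset], gamma: np.ndarray):
    """-2 restricted log-likelihood profiled over sigma2 and the betas."""
    logdets = 0.0
    rss_total = 0.0
    n_total = 0
    p_total = 0
    per_ds = []
    for ds in datasets:
        ldv, ldx, rss, beta, xtwix = _profiled_pieces(ds, gamma)
        logdets += ldv + ldx
        rss_total += rss
        n_total += ds.n_obs
        p_total += ds.n_fixed
        per_ds.append((beta, xtwix))
    df = n_total - p_total
    if df <= 0:
        raise DesignError("no residual degrees of freedom")
    sigma2 = rss_total / df
    if sigma2 <= 0:
        raise DesignError("zero residual variation; model is degenerate")
    crit = logdets + df * (1.0 + _LOG_2PI + np.log(sigma2))
    return crit, sigma2, per_ds


def _anova_start(datasets: list[MixedDataset], k: int) -> np.ndarray:
    """Deterministic starting ratios from expected-mean-squares moments.

    For each factor, the excess of the between-group variance of OLS
    residuals over its sampling expectation estimates the component; ratios
    are clipped into a safe interior range.
    """
    gamma0 = np.zeros(k)
    num = np.zeros(k)
    s2_pool = 0.0
    n_pool = 0
    for ds in datasets:
        beta, *_ = np.linalg.lstsq(ds.X, ds.y, rcond=None)
        r = ds.y - ds.X @ beta
        s2 = float(np.var(r, ddof=min(ds.n_fixed, ds.n_obs - 1)))
        s2_pool += s2 * ds.n_obs
        n_pool += ds.n_obs
        for j, Z in enumerate(ds._Z):
            sizes = Z.sum(axis=0)
            means = (Z.T @ r) / np.maximum(sizes, 1.0)
            g = len(sizes)
            if g < 2:
                continue
            between = float(np.sum(sizes * (means - r.mean()) ** 2) / (g - 1))
            nbar = float(sizes.mean())
            num[j] += max(between - s2, 0.0) / max(nbar, 1.0)
    s2_pool = max(s2_pool / max(n_pool, 1), 1e-12)
    for j in range(k):
        gamma0[j] = np.clip(num[j] / len(datasets) / s2_pool, 1e-3, 1e3)
    return gamma0


def fit_reml(
    datasets: list[MixedDataset],
    component_names: list[str] | None = None,
    tol: float = 1e-10,
    max_evals: int = 5000,
) -> REMLResult:
    """Fit shared variance components across one or more datasets by REML.

    Parameters
    ----------
    datasets
        Outcome/design/factor triples.  All datasets must declare the same
        number of random factors; the j-th factor of every dataset shares one
        variance parameter.
    component_names
        Labels for the variance components (defaults to ``vc0``, ``vc1``...).
    tol
        Convergence tolerance on the profiled criterion.
    """
    if not datasets:
        raise ValueError("no datasets to fit")
    k = len(datasets[0].factors)
    if any(len(ds.factors) != k for ds in datasets):
        raise DesignError("all datasets must share the same random-factor structure")
    if component_names is None:
        component_names = [f"vc{j}" for j in range(k)]
    if len(component_names) != k:
        raise ValueError("one name per variance component required")
    # Fixed-effects rank check up front so failures are informative.
    for ds in datasets:
        if np.linalg.matrix_rank(ds.X) < ds.n_fixed:
            raise DesignError("fixed-effect design matrix is rank deficient")

    trace: list[tuple[np.ndarray, float]] = []
    n_evals = 0

    def objective(gamma: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        g = np.maximum(np.asarray(gamma, dtype=float), 0.0)
        crit, _, _ = _criterion(datasets, g)
        trace.append((g.copy(), crit))
        return crit

    if k == 0:
        crit, sigma2, per_ds = _criterion(datasets, np.zeros(0))
        gamma_hat = np.zeros(0)
        converged = True
    else:
        gamma0 = _anova_start(datasets, k)
        res = optimize.minimize(
            objective,
            gamma0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxfun": max_evals},
        )
        # Polish: Nelder-Mead is slow but reliable near non-smooth boundaries
        # (components pinned at zero) and squeezes the criterion to ~tol.
        polish = optimize.minimize(
            objective,
            np.maximum(res.x, 0.0),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol, "maxfev": max_evals},
        )
        gamma_hat = np.maximum(polish.x, 0.0)
        converged = bool(res.success or polish.success)
        if not converged:
            raise ConvergenceError(
                f"REML did not converge after {n_evals} evaluations "
                f"(last criterion {trace[-1][1]:.6f})",
                trace,
            )
        crit, sigma2, per_ds = _criterion(datasets, gamma_hat)

    betas = [beta for beta, _ in per_ds]
    cov_betas = [sigma2 * np.linalg.inv(xtwix) for _, xtwix in per_ds]
    return REMLResult(
        component_names=list(component_names),
        gamma=gamma_hat,
        sigma2_resid=float(sigma2),
        betas=betas,
        cov_betas=cov_betas,
        criterion=float(crit),
        converged=converged,
        n_obs=sum(ds.n_obs for ds in datasets),
        n_fixed=sum(ds.n_fixed for ds in datasets),
        n_evals=n_evals,
        trace=trace,
    )
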