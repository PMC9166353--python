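"""Maximum-likelihood fitting and comparison of continuous trait-evolution models.

Seven models share one likelihood skeleton: y ~ MVN(m(theta), sigma2 * V(theta))
on the tips of a fixed tree. For a fixed V the root state (GLS mean) and the
rate sigma2 have closed-form MLEs and are profiled out; any remaining shape
parameter (alpha, a, lambda, slope, drift) is found by bounded deterministic
search (coarse grid + Brent refinement, or L-BFGS-B with jittered restarts
for the two-dimensional trend model).

ML (not REML) is used throughout so log-likelihoods are comparable across
models and valid in likelihood-ratio tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .tree_core import (
    Tree,
    eb_covariance,
    ou_covariance,
    transform_lambda,
    vcv,
)

__all__ = [
    "ModelFit",
    "DegenerateDataError",
    "NotPositiveDefiniteError",
    "fit_bm",
    "fit_white_noise",
    "fit_lambda",
    "fit_ou",
    "fit_eb",
    "fit_trend",
    "fit_drift",
    "fit_model",
    "compare_models",
    "gls_mean_profile",
]

LOG_2PI = np.log(2.0 * np.pi)

#: estimates closer than this (relative) to a bound are flagged as boundary
BOUNDARY_RTOL = 1e-3


class DegenerateDataError(ValueError):
    """Trait vector carries no variance; likelihood is unbounded."""


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Covariance matrix is not positive definite; no silent pseudo-inverse."""


@dataclass
class ModelFit:
    """Result of one maximum-likelihood trait-model fit."""

    model: str
    params: dict[str, float]
    loglik: float
    k: int
    converged: bool = True
    boundary: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    n: int = 0
    data_hash: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def __str__(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (
            f"{self.model}: logLik={self.loglik:.1f} AIC={self.aic:.1f} [{pars}]"
        )


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------

def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"covariance matrix is not positive definite: {exc}"
        ) from exc


def gls_mean_profile(V: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Profiled MLEs for the intercept-only GLS model with covariance sigma2*V.

    Returns (mu_hat, sigma2_hat, loglik, logdetV). mu_hat is the phylogenetic
    (GLS) mean, sigma2_hat the ML rate, loglik the full MVN log density.
    """
    n = y.shape[0]
    L = _chol(V)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    wy = linalg.solve_triangular(L, y, lower=True)
    w1 = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(w1 @ wy / (w1 @ w1))
    r = wy - mu * w1
    q = float(r @ r)
    if q <= 0:
        raise DegenerateDataError("zero residual variance (constant trait?)")
    sigma2 = q / n
    loglik = -0.5 * n * (LOG_2PI + np.log(sigma2) + 1.0) - 0.5 * logdet
    return mu, sigma2, loglik, logdet


def _hash_y(y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(y, dtype=float).tobytes()).hexdigest()[:12]


def _check_data(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("trait vector must be one-dimensional")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait vector contains non-finite values")
    if np.ptp(y) == 0:
        raise DegenerateDataError("trait vector is constant")
    return y


def _refine_scalar(f, grid: np.ndarray) -> tuple[float, float]:
    """Minimize f over the grid, then Brent-refine inside the bracketing cell.

    Deterministic; returns (x_min, f_min)."""
    vals = np.array([f(x) for x in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i]), float(vals[i])
    res = optimize.minimize_scalar(
        f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    if res.fun <= vals[i]:
        return float(res.x), float(res.fun)
    return float(grid[i]), float(vals[i])


# ---------------------------------------------------------------------------
# Individual models
# ---------------------------------------------------------------------------

def fit_bm(tree: Tree, y: np.ndarray) -> ModelFit:
    """Brownian motion: V = C, closed-form fit. k = 2 (sigma2, z0)."""
    y = _check_data(y)
    C = vcv(tree)
    mu, sigma2, loglik, _ = gls_mean_profile(C.values, y)
    return ModelFit(
        model="bm",
        params={"sigma2": sigma2, "z0": mu},
        loglik=loglik,
        k=2,
        n=y.shape[0],
        data_hash=_hash_y(y),
    )


def fit_white_noise(tree: Tree, y: np.ndarray) -> ModelFit:
    """Non-phylogenetic iid-normal model: V = I. k = 2 (sigma2, mean)."""
    y = _check_data(y)
    n = y.shape[0]
    mu = float(np.mean(y))
    sigma2 = float(np.mean((y - mu) ** 2))
    loglik = -0.5 * n * (LOG_2PI + np.log(sigma2) + 1.0)
    return ModelFit(
        model="white",
        params={"sigma2": sigma2, "z0": mu},
        loglik=loglik,
        k=2,
        n=n,
        data_hash=_hash_y(y),
    )


def fit_lambda(
    tree: Tree, y: np.ndarray, lam_max: float = 1.0, grid_size: int = 21
) -> ModelFit:
    """Pagel's lambda model: off-diagonal covariance scaled by lambda in
    [0, lam_max]. k = 3 (sigma2, z0, lambda)."""
    y = _check_data(y)
    C = vcv(tree)

    def nll(lam: float) -> float:
        V = transform_lambda(C, lam, lam_max)
        try:
            return -gls_mean_profile(V.values, y)[2]
        except NotPositiveDefiniteError:
            return np.inf

    grid = np.linspace(0.0, lam_max, grid_size)
    lam_hat, fmin = _refine_scalar(nll, grid)
    mu, sigma2, loglik, _ = gls_mean_profile(
        transform_lambda(C, lam_hat, lam_max).values, y
    )
    at_bound = lam_hat <= lam_max * BOUNDARY_RTOL or lam_hat >= lam_max * (
        1 - BOUNDARY_RTOL
    )
    return ModelFit(
        model="lambda",
        params={"sigma2": sigma2, "z0": mu, "lambda": lam_hat},
        loglik=loglik,
        k=3,
        boundary={"lambda": bool(at_bound)},
        n=y.shape[0],
        data_hash=_hash_y(y),
    )


def fit_ou(tree: Tree, y: np.ndarray, alpha_max: float | None = None) -> ModelFit:
    """Ornstein-Uhlenbeck with stationary covariance; alpha optimized on a
    log grid, sigma2 and root state profiled. k = 3."""
    y = _check_data(y)
    h_max = tree.max_depth()
    if alpha_max is None:
        alpha_max = 100.0 / h_max

    bm = fit_bm(tree, y)

    def nll_log(la: float) -> float:
        alpha = 10.0**la
        V = ou_covariance(tree, alpha, 1.0)
        try:
            return -gls_mean_profile(V.values, y)[2]
        except (NotPositiveDefiniteError, DegenerateDataError):
            return np.inf

    grid = np.linspace(np.log10(1e-4 / h_max), np.log10(alpha_max), 40)
    la_hat, fmin = _refine_scalar(nll_log, grid)
    loglik = -fmin
    alpha_hat = 10.0**la_hat
    flags: dict[str, bool] = {}
    warns: list[str] = []
    if loglik < bm.loglik:
        # alpha -> 0 boundary: OU nests BM; never report worse than BM
        alpha_hat = 0.0
        loglik = bm.loglik
        mu, sigma2 = bm.params["z0"], bm.params["sigma2"]
        flags["alpha"] = True
        warns.append("alpha at lower boundary; fit equals Brownian motion")
    else:
        mu, sigma2, loglik, _ = gls_mean_profile(
            ou_covariance(tree, alpha_hat, 1.0).values, y
        )
        flags["alpha"] = bool(alpha_hat >= alpha_max * (1 - BOUNDARY_RTOL))
        if flags["alpha"]:
            warns.append("alpha at upper boundary")
    # profiled sigma2 was relative to V(alpha, sigma2=1) = V(alpha, s2)/s2
    return ModelFit(
        model="ou",
        params={"sigma2": sigma2, "z0": mu, "alpha": alpha_hat},
        loglik=loglik,
        k=3,
        boundary=flags,
        warnings=warns,
        n=y.shape[0],
        data_hash=_hash_y(y),
    )


def fit_eb(tree: Tree, y: np.ndarray, a_min: float | None = None) -> ModelFit:
    """Early-burst: rate decays as exp(a t), a in [a_min, 0]. k = 3."""
    y = _check_data(y)
    h_max = tree.max_depth()
    if a_min is None:
        a_min = -10.0 / h_max

    bm = fit_bm(tree, y)

    def nll(a: float) -> float:
        if a >= 0:
            return -bm.loglik
        V = eb_covariance(tree, a, 1.0)
        try:
            return -gls_mean_profile(V.values, y)[2]
        except (NotPositiveDefiniteError, DegenerateDataError):
            return np.inf

    grid = np.linspace(a_min, 0.0, 40)
    a_hat, fmin = _refine_scalar(nll, grid)
    loglik = -fmin
    warns: list[str] = []
    if loglik <= bm.loglik + 1e-10 or a_hat >= -abs(a_min) * BOUNDARY_RTOL:
        a_hat = 0.0
        loglik = bm.loglik
        mu, sigma2 = bm.params["z0"], bm.params["sigma2"]
        at_bound = True
        warns.append("a at upper boundary 0; fit equals Brownian motion")
    else:
        mu, sigma2, loglik, _ = gls_mean_profile(
            eb_covariance(tree, a_hat, 1.0).values, y
        )
        at_bound = a_hat <= a_min * (1 - BOUNDARY_RTOL)
    return ModelFit(
        model="eb",
        params={"sigma2": sigma2, "z0": mu, "a": a_hat},
        loglik=loglik,
        k=3,
        boundary={"a": at_bound},
        warnings=warns,
        n=y.shape[0],
        data_hash=_hash_y(y),
    )


def fit_trend(
    tree: Tree,
    y: np.ndarray,
    slope_bound: float = 100.0,
    n_restarts: int = 5,
    seed: int = 0,
) -> ModelFit:
    """Time-trend diffusion: instantaneous rate sigma0^2 + slope * t.

    Two free covariance parameters (sigma0^2, slope) plus the profiled root
    state; bounded L-BFGS-B with jittered restarts. k = 3.
    """
    y = _check_data(y)
    C = vcv(tree)
    s = C.values
    s2h = 0.5 * s * s
    diag_s = s.diagonal()
    diag_s2h = s2h.diagonal()
    n = y.shape[0]
    bm = fit_bm(tree, y)

    def nloglik(theta: np.ndarray) -> float:
        log_s0, slope = theta
        s0 = np.exp(log_s0)
        if np.any(s0 * diag_s + slope * diag_s2h <= 0):
            return 1e10
        V = s0 * s + slope * s2h
        try:
            L = _chol(V)
        except NotPositiveDefiniteError:
            return 1e10
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        wy = linalg.solve_triangular(L, y, lower=True)
        w1 = linalg.solve_triangular(L, np.ones(n), lower=True)
        mu = float(w1 @ wy / (w1 @ w1))
        r = wy - mu * w1
        return 0.5 * (n * LOG_2PI + logdet + float(r @ r))

    rng = np.random.default_rng(seed)
    base = np.array([np.log(bm.params["sigma2"]), 0.0])
    best = None
    starts = [base] + [
        base + rng.normal(scale=[1.0, slope_bound / 10.0]) for _ in range(n_restarts - 1)
    ]
    for x0 in starts:
        x0 = np.clip(x0, [-30.0, -slope_bound], [30.0, slope_bound])
        res = optimize.minimize(
            nloglik,
            x0,
            method="L-BFGS-B",
            bounds=[(-30.0, 30.0), (-slope_bound, slope_bound)],
        )
        if best is None or res.fun < best.fun:
            best = res
    loglik = -float(best.fun)
    warns: list[str] = []
    if loglik < bm.loglik:
        # slope = 0 nests BM exactly; never report worse
        sigma0, slope, loglik = bm.params["sigma2"], 0.0, bm.loglik
        mu = bm.params["z0"]
        converged = True
        warns.append("optimizer failed to beat the nested BM fit; reporting BM")
    else:
        sigma0, slope = float(np.exp(best.x[0])), float(best.x[1])
        V = sigma0 * s + slope * s2h
        L = _chol(V)
        wy = linalg.solve_triangular(L, y, lower=True)
        w1 = linalg.solve_triangular(L, np.ones(n), lower=True)
        mu = float(w1 @ wy / (w1 @ w1))
        converged = bool(best.success)
    at_bound = abs(slope) >= slope_bound * (1 - BOUNDARY_RTOL)
    if at_bound:
        warns.append(f"slope at bound +/-{slope_bound}")
    return ModelFit(
        model="trend",
        params={"sigma2": sigma0, "z0": mu, "slope": slope},
        loglik=loglik,
        k=3,
        converged=converged,
        boundary={"slope": at_bound},
        warnings=warns,
        n=n,
        data_hash=_hash_y(y),
    )


def fit_drift(tree: Tree, y: np.ndarray, drift_bound: float = 100.0) -> ModelFit:
    """Directional drift: E[y_i] = z0 + drift * h_i, covariance sigma2 * C.

    Closed-form GLS in (z0, drift). On trees where all root-to-tip depths
    are equal, drift is confounded with z0; the fit then equals BM and an
    unidentifiability warning is recorded. k = 3.
    """
    y = _check_data(y)
    C = vcv(tree)
    h = C.values.diagonal().copy()
    n = y.shape[0]
    bm = fit_bm(tree, y)
    warns: list[str] = []
    flags: dict[str, bool] = {}

    rel_spread = np.ptp(h) / max(np.max(np.abs(h)), 1e-300)
    if rel_spread < 1e-8:
        warns.append(
            "all root-to-tip depths equal: drift unidentifiable (confounded "
            "with root state); reporting BM likelihood"
        )
        return ModelFit(
            model="drift",
            params={"sigma2": bm.params["sigma2"], "z0": bm.params["z0"], "drift": 0.0},
            loglik=bm.loglik,
            k=3,
            boundary={"drift": False},
            warnings=warns,
            n=n,
            data_hash=_hash_y(y),
        )

    L = _chol(C.values)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    X = np.column_stack([np.ones(n), h])
    wX = linalg.solve_triangular(L, X, lower=True)
    wy = linalg.solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(wX, wy, rcond=None)
    z0, drift = float(beta[0]), float(beta[1])
    if abs(drift) > drift_bound:
        drift = float(np.sign(drift) * drift_bound)
        # refit intercept with drift pinned at the bound
        wy_adj = wy - drift * wX[:, 1]
        z0 = float(wX[:, 0] @ wy_adj / (wX[:, 0] @ wX[:, 0]))
        flags["drift"] = True
        warns.append(f"drift clamped to +/-{drift_bound}")
    else:
        flags["drift"] = abs(drift) >= drift_bound * (1 - BOUNDARY_RTOL)
    r = wy - wX @ np.array([z0, drift])
    q = float(r @ r)
    sigma2 = q / n
    loglik = -0.5 * n * (LOG_2PI + np.log(sigma2) + 1.0) - 0.5 * logdet
    if loglik < bm.loglik - 1e-8:
        warns.append("drift fit below BM (clamped bound); reporting clamped fit")
    return ModelFit(
        model="drift",
        params={"sigma2": sigma2, "z0": z0, "drift": drift},
        loglik=loglik,
        k=3,
        boundary=flags,
        warnings=warns,
        n=n,
        data_hash=_hash_y(y),
    )


_FITTERS = {
    "bm": fit_bm,
    "white": fit_white_noise,
    "lambda": fit_lambda,
    "ou": fit_ou,
    "eb": fit_eb,
    "trend": fit_trend,
    "drift": fit_drift,
}

#: pairs (small, big) whose likelihoods are nested and LRT-comparable
_NESTED: list[tuple[str, str]] = [
    ("bm", "lambda"),
    ("bm", "ou"),
    ("bm", "eb"),
    ("bm", "trend"),
    ("bm", "drift"),
]


def fit_model(name: str, tree: Tree, y: np.ndarray, **kw) -> ModelFit:
    """Fit one model by name; see ``_FITTERS`` for the available names."""
    try:
        fitter = _FITTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_FITTERS)}"
        ) from None
    return fitter(tree, y, **kw)


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Model table sorted by AIC, with LRTs for the nested pairs present.

    All fits must be on the same data vector (checked via a hash); the
    AIC-best model is flagged in the ``best`` column.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits computed on different data vectors; not comparable")
    by_name = {f.model: f for f in fits}
    rows = []
    for f in fits:
        lrt_stat = lrt_p = np.nan
        lrt_vs = ""
        for small, big in _NESTED:
            if f.model == big and small in by_name:
                ref = by_name[small]
                stat = 2.0 * (f.loglik - ref.loglik)
                stat = max(stat, 0.0)
                df = f.k - ref.k
                lrt_stat = stat
                lrt_p = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
                if stat == 0.0:
                    lrt_p = 1.0
                lrt_vs = small
        rows.append(
            {
                "model": f.model,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
                "params": "; ".join(f"{k}={v:.4g}" for k, v in f.params.items()),
                "lrt_vs": lrt_vs,
                "lrt_stat": lrt_stat,
                "lrt_p": lrt_p,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table
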