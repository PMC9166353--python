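"""Non-phylogenetic GLS (= OLS) and phylogenetic GLS regression.

The phylogenetic fit estimates branch-length transforms by maximum
likelihood jointly with the coefficients. The residual covariance is built
in a fixed composition order: kappa applied to branch lengths, then the BM
matrix, then delta element-wise, then lambda on the off-diagonals.

Two R-squared flavours are always computed: a whitened-residual multiple
R-squared and Nagelkerke's likelihood-based pseudo-R-squared; which one a
report prints is a presentation choice, not a fitting choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .tree_core import (
    Tree,
    _clade_blocks,
    transform_delta,
    transform_lambda,
    vcv_from_blocks,
)
from .trait_models import LOG_2PI, NotPositiveDefiniteError, _chol

__all__ = [
    "RegFit",
    "gls_fit",
    "pgls_fit",
    "pgls_fit_bm",
    "anova_nested",
    "build_transformed_cov",
]

PROFILE_DROP = 1.92  # chi2(1)_{0.95} / 2

_TRANSFORM_BOUNDS = {"kappa": (0.0, 3.0), "lambda": (0.0, 1.0), "delta": (1e-4, 3.0)}
_TRANSFORM_ORDER = ("kappa", "lambda", "delta")
_MULTISTARTS = (
    {"kappa": 1.0, "lambda": 1.0, "delta": 1.0},
    {"kappa": 0.5, "lambda": 0.5, "delta": 1.5},
    {"kappa": 0.24, "lambda": 0.98, "delta": 2.5},
)


@dataclass
class RegFit:
    """A fitted (P)GLS regression."""

    response: str
    predictors: list[str]
    coef: np.ndarray  # [intercept, slopes...]
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    model_p: float
    loglik: float
    k: int
    n: int
    r2_multiple: float
    r2_nagelkerke: float
    transforms: dict[str, dict] = field(default_factory=dict)
    phylogenetic: bool = False
    # internals used by anova_nested (not part of the report surface)
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _V: np.ndarray | None = None
    _rss_whitened: float = np.nan

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "t": self.tvals,
                "p": self.pvals,
            },
            index=["intercept"] + list(self.predictors),
        )

    def __str__(self) -> str:
        kind = "PGLS" if self.phylogenetic else "GLS"
        terms = " + ".join(self.predictors) or "1"
        return (
            f"{kind} {self.response} ~ {terms}: AIC={self.aic:.1f} "
            f"p={self.model_p:.3g} R2m={self.r2_multiple:.4g} "
            f"R2n={self.r2_nagelkerke:.4g}"
        )


# ---------------------------------------------------------------------------
# Design-matrix plumbing
# ---------------------------------------------------------------------------

def _design(X, names: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def _whitened_ols(
    wy: np.ndarray, wX: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS on whitened data; returns (beta, rss, XtX_inv)."""
    n, p = wX.shape
    q, r = np.linalg.qr(wX)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(r))):
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (collinear predictors)"
        )
    beta = linalg.solve_triangular(r, q.T @ wy)
    resid = wy - wX @ beta
    rss = float(resid @ resid)
    rinv = linalg.solve_triangular(r, np.eye(p))
    return beta, rss, rinv @ rinv.T


def _gauss_loglik(n: int, rss: float, logdet: float) -> float:
    sigma2 = rss / n
    return -0.5 * n * (LOG_2PI + np.log(sigma2) + 1.0) - 0.5 * logdet


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    num = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    den = 1.0 - np.exp(2.0 * ll_null / n)
    return float(num / den)


# ---------------------------------------------------------------------------
# Non-phylogenetic GLS (identity covariance == OLS)
# ---------------------------------------------------------------------------

def gls_fit(
    y: np.ndarray,
    X,
    names: Sequence[str] | None = None,
    response: str = "y",
) -> RegFit:
    """Ordinary least squares with Gaussian ML log-likelihood and both
    pseudo-R-squared variants. An intercept column is added internally."""
    y = np.asarray(y, dtype=float)
    Xp, pred_names = _design(X, names)
    n = y.shape[0]
    if Xp.shape[0] != n:
        raise ValueError("y and X row counts differ")
    Xd = np.column_stack([np.ones(n), Xp])
    p = Xd.shape[1]
    beta, rss, XtX_inv = _whitened_ols(y, Xd)
    loglik = _gauss_loglik(n, rss, 0.0)

    tss = float(np.sum((y - y.mean()) ** 2))
    ll_null = _gauss_loglik(n, tss, 0.0)
    r2_mult = 1.0 - rss / tss if tss > 0 else np.nan
    r2_nag = _nagelkerke(loglik, ll_null, n)

    sigma2_u = rss / (n - p)
    se = np.sqrt(sigma2_u * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    lrt = max(2.0 * (loglik - ll_null), 0.0)
    model_p = float(stats.chi2.sf(lrt, p - 1)) if p > 1 else 1.0
    return RegFit(
        response=response,
        predictors=pred_names,
        coef=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        model_p=model_p,
        loglik=loglik,
        k=p + 1,
        n=n,
        r2_multiple=r2_mult,
        r2_nagelkerke=r2_nag,
        phylogenetic=False,
        _y=y,
        _X=Xd,
        _V=None,
        _rss_whitened=rss,
    )


# ---------------------------------------------------------------------------
# Phylogenetic GLS
# ---------------------------------------------------------------------------

def build_transformed_cov(
    labels: Sequence[str],
    blocks,
    kappa: float = 1.0,
    lam: float = 1.0,
    delta: float = 1.0,
) -> np.ndarray:
    """kappa on branches -> BM matrix -> delta element-wise -> lambda off-diag."""
    C = vcv_from_blocks(labels, blocks, kappa=kappa)
    if delta != 1.0:
        C = transform_delta(C, delta)
    if lam != 1.0:
        C = transform_lambda(C, lam)
    return C.values


class _PglsEngine:
    """Caches clade blocks and evaluates the profiled log-likelihood."""

    def __init__(self, tree: Tree, y: np.ndarray, Xd: np.ndarray):
        self.labels, self.blocks = _clade_blocks(tree)
        self.y = y
        self.Xd = Xd
        self.n, self.p = Xd.shape

    def cov(self, params: Mapping[str, float]) -> np.ndarray:
        return build_transformed_cov(
            self.labels,
            self.blocks,
            kappa=params.get("kappa", 1.0),
            lam=params.get("lambda", 1.0),
            delta=params.get("delta", 1.0),
        )

    def profile(self, params: Mapping[str, float], Xd: np.ndarray | None = None):
        """Profiled fit at fixed transforms. Returns a dict of internals."""
        Xd = self.Xd if Xd is None else Xd
        V = self.cov(params)
        L = _chol(V)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        wy = linalg.solve_triangular(L, self.y, lower=True)
        wX = linalg.solve_triangular(L, Xd, lower=True)
        beta, rss, XtX_inv = _whitened_ols(wy, wX)
        loglik = _gauss_loglik(self.n, rss, logdet)
        return {
            "beta": beta,
            "rss": rss,
            "XtX_inv": XtX_inv,
            "loglik": loglik,
            "V": V,
            "wy": wy,
            "wX": wX,
        }

    def nll(self, params: Mapping[str, float]) -> float:
        try:
            return -self.profile(params)["loglik"]
        except (NotPositiveDefiniteError, np.linalg.LinAlgError):
            return np.inf


def _optimize_transforms(
    engine: _PglsEngine,
    free: list[str],
    fixed: dict[str, float],
) -> dict[str, float]:
    """Joint bounded ML over the free transforms, deterministic multi-start."""
    if not free:
        return dict(fixed)
    bounds = [_TRANSFORM_BOUNDS[name] for name in free]

    def fun(x: np.ndarray) -> float:
        params = dict(fixed)
        params.update(zip(free, x))
        return engine.nll(params)

    best_x, best_f = None, np.inf
    for start in _MULTISTARTS:
        x0 = np.array(
            [np.clip(start[name], *_TRANSFORM_BOUNDS[name]) for name in free]
        )
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12}
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    params = dict(fixed)
    params.update(zip(free, best_x))
    return params


def _profile_ci(
    engine: _PglsEngine,
    name: str,
    free: list[str],
    fixed: dict[str, float],
    hat: dict[str, float],
    f_hat: float,
) -> tuple[float, float]:
    """Profile-likelihood CI for one transform, re-optimizing the others."""
    lo, hi = _TRANSFORM_BOUNDS[name]
    others = [f for f in free if f != name]
    target = f_hat + PROFILE_DROP

    def prof_nll(x: float) -> float:
        fx = dict(fixed)
        fx[name] = x
        params = _optimize_transforms(engine, others, fx)
        return engine.nll(params)

    def crossing(a: float, b: float) -> float:
        try:
            return float(
                optimize.brentq(lambda x: prof_nll(x) - target, a, b, xtol=1e-5)
            )
        except ValueError:
            return a if prof_nll(a) - target < 0 else b

    x_hat = hat[name]
    lo_ci = lo if prof_nll(lo) <= target else crossing(lo, x_hat)
    hi_ci = hi if prof_nll(hi) <= target else crossing(x_hat, hi)
    return lo_ci, hi_ci


def pgls_fit(
    tree: Tree,
    y: np.ndarray,
    X,
    transforms: Mapping[str, object] | None = None,
    names: Sequence[str] | None = None,
    response: str = "y",
    compute_ci: bool = True,
) -> RegFit:
    """Phylogenetic GLS with ML or fixed branch-length transforms.

    ``transforms`` maps a subset of {"kappa", "lambda", "delta"} to either
    the string "ML" or a fixed numeric value; unrequested transforms are
    fixed at 1. Coefficient t-tests use n - p degrees of freedom with the
    unbiased residual variance; log-likelihood and AIC use the ML variance.
    """
    y = np.asarray(y, dtype=float)
    Xp, pred_names = _design(X, names)
    n = y.shape[0]
    if len(tree.tip_labels) != n or Xp.shape[0] != n:
        raise ValueError("tree tips, y and X must be aligned (same length/order)")
    Xd = np.column_stack([np.ones(n), Xp])
    p = Xd.shape[1]

    transforms = dict(transforms or {})
    unknown = set(transforms) - set(_TRANSFORM_ORDER)
    if unknown:
        raise ValueError(f"unknown transforms: {sorted(unknown)}")
    free = [t for t in _TRANSFORM_ORDER if transforms.get(t) == "ML"]
    fixed = {t: 1.0 for t in _TRANSFORM_ORDER}
    for t, v in transforms.items():
        if v != "ML":
            fixed[t] = float(v)

    engine = _PglsEngine(tree, y, Xd)
    params = _optimize_transforms(engine, free, {t: fixed[t] for t in _TRANSFORM_ORDER})
    try:
        prof = engine.profile(params)
    except NotPositiveDefiniteError as exc:
        bad = ", ".join(f"{t}={params[t]:.3g}" for t in _TRANSFORM_ORDER)
        raise NotPositiveDefiniteError(
            f"covariance not positive definite at transforms ({bad})"
        ) from exc

    beta, rss, XtX_inv, loglik = (
        prof["beta"],
        prof["rss"],
        prof["XtX_inv"],
        prof["loglik"],
    )
    sigma2_u = rss / (n - p)
    se = np.sqrt(sigma2_u * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)

    # null model: intercept only, same covariance structure (fitted transforms)
    null_prof = engine.profile(params, Xd=np.ones((n, 1)))
    ll_null = null_prof["loglik"]
    rss_null = null_prof["rss"]
    r2_mult = 1.0 - rss / rss_null if rss_null > 0 else np.nan
    r2_nag = _nagelkerke(loglik, ll_null, n)
    lrt = max(2.0 * (loglik - ll_null), 0.0)
    model_p = float(stats.chi2.sf(lrt, p - 1)) if p > 1 else 1.0

    tinfo: dict[str, dict] = {}
    f_hat = -loglik
    for t in _TRANSFORM_ORDER:
        lo, hi = _TRANSFORM_BOUNDS[t]
        entry: dict[str, object] = {
            "estimate": params[t],
            "mode": "ML" if t in free else "fixed",
            "boundary": bool(
                t in free
                and (params[t] <= lo + 1e-3 * (hi - lo) or params[t] >= hi - 1e-3 * (hi - lo))
            ),
        }
        if t in free and compute_ci:
            entry["ci"] = _profile_ci(engine, t, free, fixed, params, f_hat)
        if t == "lambda" and t in free:
            # LRT flags vs 0 and vs 1 with the other transforms re-optimized
            for ref, key in ((0.0, "differs_from_0"), (1.0, "differs_from_1")):
                fx = {u: fixed[u] for u in _TRANSFORM_ORDER}
                fx["lambda"] = ref
                alt = _optimize_transforms(engine, [u for u in free if u != "lambda"], fx)
                ll_ref = -engine.nll(alt)
                stat = max(2.0 * (loglik - ll_ref), 0.0)
                entry[key] = bool(stats.chi2.sf(stat, 1) < 0.05)
        tinfo[t] = entry

    return RegFit(
        response=response,
        predictors=pred_names,
        coef=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        model_p=model_p,
        loglik=loglik,
        k=p + 1 + len(free),
        n=n,
        r2_multiple=r2_mult,
        r2_nagelkerke=r2_nag,
        transforms=tinfo,
        phylogenetic=True,
        _y=y,
        _X=Xd,
        _V=prof["V"],
        _rss_whitened=rss,
    )


def pgls_fit_bm(
    tree: Tree,
    y: np.ndarray,
    X,
    names: Sequence[str] | None = None,
    response: str = "y",
) -> RegFit:
    """PGLS with pure Brownian-motion residuals (all transforms fixed at 1)."""
    return pgls_fit(
        tree,
        y,
        X,
        transforms={"kappa": 1.0, "lambda": 1.0, "delta": 1.0},
        names=names,
        response=response,
    )


def anova_nested(fit_small: RegFit, fit_big: RegFit) -> dict[str, float]:
    """F test (plus an LRT cross-check) between nested regression fits.

    Both models are whitened with the bigger model's covariance so the
    residual sums of squares are comparable; predictors of the small model
    must be a subset of the big model's.
    """
    if fit_small.response != fit_big.response or fit_small.n != fit_big.n:
        raise ValueError("fits are not on the same response/data")
    if not set(fit_small.predictors) <= set(fit_big.predictors):
        raise ValueError("predictor sets are not nested")
    if fit_small._y is None or fit_big._y is None:
        raise ValueError("fits lack stored internals")
    if not np.array_equal(fit_small._y, fit_big._y):
        raise ValueError("fits are not on the same response vector")

    n = fit_big.n
    p_big = fit_big._X.shape[1]
    p_small = fit_small._X.shape[1]
    dp = p_big - p_small

    V = fit_big._V
    if V is None:
        wy, wXs, wXb = fit_big._y, fit_small._X, fit_big._X
    else:
        L = _chol(V)
        wy = linalg.solve_triangular(L, fit_big._y, lower=True)
        wXs = linalg.solve_triangular(L, fit_small._X, lower=True)
        wXb = linalg.solve_triangular(L, fit_big._X, lower=True)
    _, rss_s, _ = _whitened_ols(wy, wXs)
    _, rss_b, _ = _whitened_ols(wy, wXb)

    if dp == 0 or rss_s <= rss_b * (1 + 1e-12):
        f_stat = max((rss_s - rss_b), 0.0)
        if dp > 0:
            f_stat = (f_stat / dp) / (rss_b / (n - p_big))
        else:
            f_stat = 0.0
    else:
        f_stat = ((rss_s - rss_b) / dp) / (rss_b / (n - p_big))
    p = float(stats.f.sf(f_stat, dp, n - p_big)) if dp > 0 else 1.0
    lrt = max(n * (np.log(rss_s) - np.log(rss_b)), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, dp)) if dp > 0 else 1.0
    return {
        "f_stat": float(f_stat),
        "df1": dp,
        "df2": n - p_big,
        "p": p if dp > 0 else 1.0,
        "lrt_stat": float(lrt),
        "lrt_p": lrt_p,
    }
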