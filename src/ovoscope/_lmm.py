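"""Gaussian mixed-model engine: random intercepts and penalized smooths.

The model is y = X beta + sum_k Z_k u_k + eps with u_k ~ N(0, sigma2 *
theta_k I) and eps ~ N(0, sigma2 I).  For fixed variance ratios theta the
GLS solution for beta and the profiled sigma2 are closed form, so fitting
reduces to a low-dimensional optimization of the profiled (restricted)
log-likelihood over log theta.  Random blocks serve two roles:

* a site random intercept (Z = site indicator matrix), and
* the wiggly part of a penalized cubic regression spline, whose smoothing
  parameter is exactly the inverse of its variance ratio — the classical
  mixed-model representation of a penalized smooth.

The covariance never needs to be larger than n x n and n is around a
hundred eggs, so everything is dense Cholesky algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "RandomBlock",
    "SmoothTermInfo",
    "MixedModelFit",
    "cubic_spline_basis",
    "smooth_design",
    "fit_mixed",
    "aicc",
    "r2_nakagawa",
    "concurvity",
]

_RHO_LO, _RHO_HI = -23.0, 16.0  # log variance-ratio search box
_BOUNDARY_THETA = 1e-6


@dataclass
class RandomBlock:
    name: str
    Z: np.ndarray  # (n, m)
    is_smooth: bool = False


@dataclass
class SmoothTermInfo:
    covariate: str
    basis_dim: int
    lambda_: float  # smoothing parameter, 1 / variance ratio
    edf: float  # 1 (linear null space) + penalized-part trace


@dataclass
class MixedModelFit:
    """A fitted Gaussian mixed model and its selection bookkeeping.

    ``loglik`` is the value of the fitting criterion's objective (the log
    marginal likelihood for ML, the restricted version for REML) at the
    optimum; ``k`` counts fixed coefficients plus the residual variance,
    plus one per free variance component and smoothing parameter — the
    convention behind the "df" column of the comparison tables.
    """

    response: str
    design: str
    term_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_alpha: float  # site-intercept variance (0 if no site effect)
    sigma2_eps: float
    smooth_terms: list[SmoothTermInfo]
    loglik: float
    criterion: str
    k: int
    n: int
    fitted_fixed: np.ndarray = field(repr=False, default=None)  # type: ignore
    #: per-term fitted contributions (fixed columns and smooth blocks)
    contributions: dict[str, np.ndarray] = field(repr=False,
                                                 default_factory=dict)
    term_bases: dict[str, np.ndarray] = field(repr=False,
                                              default_factory=dict)
    theta: np.ndarray = field(default=None)  # type: ignore
    at_boundary: bool = False
    X: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def p_values(self) -> np.ndarray:
        """Approximate two-sided p from t with n - k residual df."""
        from scipy import stats

        df = max(self.n - self.k, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.beta / self.se
        return 2 * stats.t.sf(np.abs(t), df)


def _objective(
    rho: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    blocks: list[RandomBlock],
    reml: bool,
) -> tuple[float, dict]:
    """-2 * (restricted) profile log-likelihood at log variance ratios rho."""
    n, p = X.shape
    V0 = np.eye(n)
    for k, blk in enumerate(blocks):
        V0 += np.exp(rho[k]) * (blk.Z @ blk.Z.T)
    c, low = linalg.cho_factor(V0, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    ViX = linalg.cho_solve((c, low), X)
    Viy = linalg.cho_solve((c, low), y)
    G = X.T @ ViX
    beta = linalg.solve(G, X.T @ Viy, assume_a="pos")
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r))
    rss = max(rss, 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_g = np.linalg.slogdet(G)
        neg2 = (
            dof * np.log(2 * np.pi * sigma2) + logdet_v + logdet_g + dof
        )
    else:
        sigma2 = rss / n
        neg2 = n * np.log(2 * np.pi * sigma2) + logdet_v + n
    aux = dict(beta=beta, sigma2=sigma2, G=G, chol=(c, low))
    return neg2, aux


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    blocks: list[RandomBlock] | None = None,
    criterion: str = "ML",
    response: str = "y",
    design: str = "",
    term_names: list[str] | None = None,
    contribution_cols: dict[str, list[int]] | None = None,
) -> MixedModelFit:
    """Fit by profiled (restricted) maximum likelihood.

    ``contribution_cols`` maps a term name to the X columns belonging to
    it, so per-term fitted contributions can be reported (used by the
    concurvity diagnostic and partial-effect output).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    blocks = list(blocks or [])
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y sizes disagree")
    if n <= p + 2:
        raise ValueError("too few observations for the design")
    criterion = criterion.upper()
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be ML or REML")
    reml = criterion == "REML"
    K = len(blocks)

    if K == 0:
        rho_hat = np.zeros(0)
        neg2, aux = _objective(rho_hat, y, X, blocks, reml)
    elif K == 1:

        def f1(r: float) -> float:
            return _objective(np.array([r]), y, X, blocks, reml)[0]

        res = optimize.minimize_scalar(
            f1, bounds=(_RHO_LO, _RHO_HI), method="bounded",
            options={"xatol": 1e-9},
        )
        rho_hat = np.array([res.x])
        neg2, aux = _objective(rho_hat, y, X, blocks, reml)
    else:
        best = None
        for start in (0.0, -6.0, 4.0):
            res = optimize.minimize(
                lambda r: _objective(np.clip(r, _RHO_LO, _RHO_HI), y, X,
                                     blocks, reml)[0],
                np.full(K, start),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 3000},
            )
            if best is None or res.fun < best.fun:
                best = res
        rho_hat = np.clip(best.x, _RHO_LO, _RHO_HI)
        neg2, aux = _objective(rho_hat, y, X, blocks, reml)

    theta = np.exp(rho_hat)
    sigma2 = aux["sigma2"]
    beta = aux["beta"]
    se = np.sqrt(sigma2 * np.diag(linalg.inv(aux["G"])))

    sigma2_alpha = 0.0
    smooth_infos: list[SmoothTermInfo] = []
    edfs = _block_edfs(X, blocks, theta) if K else []
    for k, blk in enumerate(blocks):
        if blk.is_smooth:
            smooth_infos.append(
                SmoothTermInfo(
                    covariate=blk.name,
                    basis_dim=blk.Z.shape[1] + 2,
                    lambda_=float(1.0 / theta[k]) if theta[k] > 0 else np.inf,
                    edf=1.0 + edfs[k],
                )
            )
        else:
            sigma2_alpha += sigma2 * theta[k]

    n_free_vc = K
    k_params = p + 1 + n_free_vc
    fitted_fixed = X @ beta

    contributions: dict[str, np.ndarray] = {}
    term_bases: dict[str, np.ndarray] = {}
    if contribution_cols:
        for name, cols in contribution_cols.items():
            contributions[name] = X[:, cols] @ beta[cols]
            term_bases[name] = X[:, cols]
    # smooth contributions include the penalized part
    if K:
        u_hats = _random_effect_modes(y, X, beta, blocks, theta)
        for k, blk in enumerate(blocks):
            if blk.is_smooth:
                contrib = blk.Z @ u_hats[k]
                base = contributions.get(blk.name, 0.0)
                contributions[blk.name] = base + contrib
                prev = term_bases.get(blk.name)
                term_bases[blk.name] = (
                    np.hstack([prev, blk.Z]) if prev is not None else blk.Z
                )

    return MixedModelFit(
        response=response,
        design=design,
        term_names=term_names or [f"x{j}" for j in range(p)],
        beta=beta,
        se=se,
        sigma2_alpha=float(sigma2_alpha),
        sigma2_eps=float(sigma2),
        smooth_terms=smooth_infos,
        loglik=-0.5 * neg2,
        criterion=criterion,
        k=k_params,
        n=n,
        fitted_fixed=fitted_fixed,
        contributions=contributions,
        term_bases=term_bases,
        theta=theta,
        at_boundary=bool((theta < _BOUNDARY_THETA).any()),
        X=X,
    )


def _random_effect_modes(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    blocks: list[RandomBlock],
    theta: np.ndarray,
) -> list[np.ndarray]:
    """BLUPs of every random block at the fitted variance ratios."""
    n = len(y)
    V0 = np.eye(n)
    for k, blk in enumerate(blocks):
        V0 += theta[k] * (blk.Z @ blk.Z.T)
    resid = y - X @ beta
    Vir = linalg.solve(V0, resid, assume_a="pos")
    return [theta[k] * blk.Z.T @ Vir for k, blk in enumerate(blocks)]


def _block_edfs(
    X: np.ndarray, blocks: list[RandomBlock], theta: np.ndarray
) -> list[float]:
    """Trace of the influence matrix over each random block's coefficients.

    Treats the model as one big penalized regression: coefficients
    (beta, u_1..u_K) with penalty diag(0, 1/theta_k I); the edf of block k
    is the corresponding diagonal block trace of (C'C + P)^{-1} C'C.
    """
    C = np.hstack([X] + [blk.Z for blk in blocks])
    p = X.shape[1]
    pen = np.zeros(C.shape[1])
    lo = p
    spans = []
    for k, blk in enumerate(blocks):
        m = blk.Z.shape[1]
        pen[lo:lo + m] = 1.0 / max(theta[k], 1e-290)
        spans.append((lo, lo + m))
        lo += m
    A = C.T @ C + np.diag(pen)
    M = linalg.solve(A, C.T @ C, assume_a="pos")
    return [float(np.trace(M[a:b, a:b])) for a, b in spans]


# --------------------------------------------------------------------------
# penalized cubic regression spline pieces
# --------------------------------------------------------------------------


def cubic_spline_basis(
    x: np.ndarray, n_basis: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with interior knots at covariate quantiles.

    Returns the (n, n_basis) design matrix and the Greville abscissae of
    the basis functions.  If the covariate has too few distinct values the
    basis is reduced with a warning.
    """
    from scipy.interpolate import BSpline

    x = np.asarray(x, dtype=float)
    n_distinct = len(np.unique(x))
    if n_basis < 4:
        raise ValueError("cubic basis needs n_basis >= 4")
    if n_distinct < n_basis:
        warnings.warn(
            f"only {n_distinct} distinct covariate values; reducing basis",
            stacklevel=2,
        )
        n_basis = max(4, n_distinct)
    n_interior = n_basis - 4
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("covariate is constant")
    if n_interior > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        qs = np.array([])
    knots = np.concatenate([[lo] * 4, qs, [hi] * 4])
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    greville = np.array(
        [knots[i + 1:i + 4].mean() for i in range(n_basis)]
    )
    return B, greville


def _second_divided_difference(g: np.ndarray) -> np.ndarray:
    """(m-2, m) matrix of second divided differences on abscissae g; its
    null space is exactly the coefficient vectors linear in g, so an
    infinitely smoothed spline is exactly the least-squares line."""
    m = len(g)
    D = np.zeros((m - 2, m))
    for i in range(m - 2):
        h0, h1 = g[i + 1] - g[i], g[i + 2] - g[i + 1]
        D[i, i] = 2.0 / (h0 * (h0 + h1))
        D[i, i + 1] = -2.0 / (h0 * h1)
        D[i, i + 2] = 2.0 / (h1 * (h0 + h1))
    return D


def smooth_design(
    x: np.ndarray, n_basis: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-model decomposition of a penalized cubic regression spline.

    Returns (X_lin, Z_wiggle): the unpenalized null space reduces to the
    linear trend (handled by a plain covariate column), and Z_wiggle spans
    the penalized directions scaled so the smooth's coefficients have an
    i.i.d. prior — the variance-ratio of the block is 1/lambda.
    """
    B, g = cubic_spline_basis(x, n_basis)
    D = _second_divided_difference(g)
    S = D.T @ D
    vals, vecs = np.linalg.eigh(S)
    tol = vals.max() * 1e-10
    rng_idx = vals > tol
    Z = B @ vecs[:, rng_idx] / np.sqrt(vals[rng_idx])
    x_lin = (x - x.mean()) / x.std()
    return x_lin[:, None], Z


# --------------------------------------------------------------------------
# information criteria and variance-explained summaries
# --------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a parametric Gaussian mixed fit.

    R2m = var(X beta) / (var(X beta) + sigma2_site + sigma2_eps);
    R2c adds the site variance to the numerator.
    """
    var_f = float(np.var(fit.fitted_fixed))  # population variance
    denom = var_f + fit.sigma2_alpha + fit.sigma2_eps
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return var_f / denom, (var_f + fit.sigma2_alpha) / denom


def concurvity(
    contrib_a: np.ndarray, basis_b: np.ndarray
) -> float:
    """How much of term a's fitted contribution lies in term b's span.

    The squared-correlation measure: project the centered contribution of
    term a onto the column space of term b's basis (plus intercept); the
    returned fraction of variance explained ranges from 0 (no concurvity)
    to 1 (term a is fully expressible by term b).
    """
    g = np.asarray(contrib_a, dtype=float).ravel()
    B = np.atleast_2d(np.asarray(basis_b, dtype=float))
    if B.shape[0] != len(g):
        B = B.T
    g = g - g.mean()
    ss = float(g @ g)
    if ss < 1e-12:
        raise ValueError("term contribution is constant; concurvity undefined")
    Bc = B - B.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Bc, g, rcond=None)
    proj = Bc @ coef
    return float(np.clip((proj @ g) / ss, 0.0, 1.0))
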