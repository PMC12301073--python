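"""Penalized-spline quasi-Poisson regression (GAM) with optional unit random
intercepts (GAMM).

The model for daily death counts :math:`y_d` in unit :math:`i` is

.. math::

    \\log E[y_d] = \\alpha + f(T_d) + b_i + \\log N_{i,\\mathrm{year}(d)},
    \\qquad \\operatorname{Var}[y_d] = \\phi\\, E[y_d],

where :math:`f` is a cubic B-spline smooth of daily mean temperature with a
second-order difference penalty, :math:`b_i` are unit random intercepts
(represented as ridge-penalized dummy coefficients), the log annual population
enters as an offset, and :math:`\\phi` is a quasi-Poisson dispersion estimated
from Pearson residuals.

Fitting is by penalized iteratively reweighted least squares (PIRLS) with a
log link.  Smoothing parameters (and the random-intercept ridge) are chosen by
a restricted-maximum-likelihood criterion evaluated on the converged working
linear model -- the classical Gaussian-approximation REML used for
quasi-likelihood smoothers, with the dispersion profiled out.  The posterior
(Bayesian) covariance of the coefficients, dispersion-scaled, feeds the
relative-risk curve uncertainty downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "SmoothFit",
    "FitMetrics",
    "PirlsError",
    "build_basis",
    "fit_pirls",
    "select_lambda_reml",
    "fit_gamm",
    "compute_metrics",
]


class PirlsError(RuntimeError):
    """Raised when PIRLS fails to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class BasisSpec:
    """Cubic B-spline basis with difference penalty and absorbed constraint.

    ``knots`` is the full (padded) knot vector; ``transform`` is the k x (k-1)
    orthonormal map that absorbs the sum-to-zero identifiability constraint
    (columns span the null space of the basis column means over the fitting
    sample), so the constrained design is ``B(x) @ transform``.
    """

    k: int
    degree: int
    penalty_order: int
    knots: np.ndarray
    transform: np.ndarray
    penalty: np.ndarray  # constrained penalty, (k-1) x (k-1)
    null_dim: int  # dimension of the constrained penalty null space
    penalty_logdet_pos: float  # log pseudo-determinant of the unit penalty

    def design(self, x: np.ndarray) -> np.ndarray:
        """Constrained design matrix at new points (must lie in knot range)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        return B @ self.transform

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "degree": self.degree,
            "penalty_order": self.penalty_order,
            "knots": self.knots.tolist(),
            "transform": self.transform.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        knots = np.asarray(d["knots"], dtype=float)
        S = _difference_penalty(knots, d["degree"], d["penalty_order"])
        Z = np.asarray(d["transform"], dtype=float)
        Ss = Z.T @ S @ Z
        null_dim, logdet = _penalty_spectrum(Ss)
        return cls(
            k=d["k"],
            degree=d["degree"],
            penalty_order=d["penalty_order"],
            knots=np.asarray(d["knots"], dtype=float),
            transform=Z,
            penalty=Ss,
            null_dim=null_dim,
            penalty_logdet_pos=logdet,
        )


def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    k = knots.size - degree - 1
    return np.array([knots[j + 1 : j + degree + 1].mean() for j in range(k)])


def _difference_penalty(knots: np.ndarray, degree: int, order: int) -> np.ndarray:
    """Difference penalty as divided differences at the Greville abscissae.

    Using divided differences (rather than raw coefficient differences) makes
    the penalty null space exactly the polynomials of degree < order in the
    exposure itself, regardless of knot spacing; rows are weighted by interval
    lengths so the quadratic form approximates the integrated squared
    ``order``-th derivative.
    """
    xi = _greville(knots, degree)
    k = xi.size
    D = np.eye(k)
    for r in range(1, order + 1):
        denom = xi[r:] - xi[:-r]
        D = (D[1:] - D[:-1]) * (r / denom)[:, None]
    # quadrature-style row weights over the penalized sites
    w = (xi[order:] - xi[:-order]) / order
    D = D * np.sqrt(w)[:, None]
    return D.T @ D


def _penalty_spectrum(Ss: np.ndarray) -> tuple[int, float]:
    eig = linalg.eigvalsh(Ss)
    tol = eig.max() * 1e-10
    pos = eig[eig > tol]
    return int((eig <= tol).sum()), float(np.log(pos).sum())


def build_basis(
    x: np.ndarray, k: int = 10, degree: int = 3, penalty_order: int = 2
) -> tuple[np.ndarray, np.ndarray, BasisSpec]:
    """Build the constrained B-spline design and penalty for exposures ``x``.

    Interior knots are placed at quantiles of the distinct exposure values
    (robust to the strong seasonal skew of temperature data); boundary knots
    sit just outside the observed range.  The sum-to-zero constraint (mean of
    the smooth over the fitting sample equals zero) is absorbed into the
    basis, removing one column; the intercept is supplied separately by the
    fitting routines.

    Returns ``(design, penalty, spec)`` with ``design`` of shape (n, k-1).
    """
    x = np.asarray(x, dtype=float)
    if k < 4:
        raise ValueError("basis dimension k must be >= 4")
    ux = np.unique(x)
    if ux.size < k:
        raise ValueError(f"need at least k={k} distinct exposure values, got {ux.size}")
    n_interior = k - degree - 1
    qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.quantile(ux, qs)
    if np.any(np.diff(interior) <= 0):
        # fall back to even spacing when quantiles collide
        interior = np.linspace(ux[0], ux[-1], n_interior + 2)[1:-1]
    pad = max(1e-6, 1e-6 * (ux[-1] - ux[0]))
    lo, hi = ux[0] - pad, ux[-1] + pad
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    B = BSpline.design_matrix(x, knots, degree).toarray()
    c = B.mean(axis=0)
    Z = linalg.null_space(c[None, :])  # k x (k-1), orthonormal
    S = _difference_penalty(knots, degree, penalty_order)
    Ss = Z.T @ S @ Z
    null_dim, logdet = _penalty_spectrum(Ss)
    spec = BasisSpec(
        k=k,
        degree=degree,
        penalty_order=penalty_order,
        knots=knots,
        transform=Z,
        penalty=Ss,
        null_dim=null_dim,
        penalty_logdet_pos=logdet,
    )
    return B @ Z, Ss, spec


@dataclass
class FitMetrics:
    edf: float
    p_value_smooth: float
    marginal_r2: float
    conditional_r2: float


@dataclass
class SmoothFit:
    """A fitted penalized quasi-Poisson smooth (optionally with unit effects).

    ``coefficients`` stacks [intercept, smooth coefficients, unit effects];
    ``coef_covariance`` is the dispersion-scaled Bayesian covariance on the
    same layout.  ``edf`` is the effective degrees of freedom of the smooth
    term alone (1 = shrunk to a straight line on the log scale); ``edf_total``
    counts all penalized dimensions including intercept and unit effects.
    """

    basis: BasisSpec | None
    coefficients: np.ndarray
    coef_covariance: np.ndarray
    lam: float
    dispersion: float
    edf: float
    edf_total: float
    intercept: float
    offset_used: bool
    exposure_percentiles: tuple[float, float] | None
    converged: bool
    reml: float
    n_obs: int
    lambda_u: float = 0.0
    sigma2_u: float = 0.0
    random_intercepts: dict = field(default_factory=dict)
    pearson: float = 0.0
    deviance: float = 0.0
    n_iter: int = 0
    var_fixed_lp: float = 0.0  # Var over obs of intercept + smooth (log scale)
    mean_count: float = 0.0  # mean fitted count over obs

    # layout helpers -------------------------------------------------------
    @property
    def _q(self) -> int:
        return 0 if self.basis is None else self.basis.k - 1

    @property
    def smooth_coefs(self) -> np.ndarray:
        return self.coefficients[1 : 1 + self._q]

    @property
    def smooth_cov(self) -> np.ndarray:
        return self.coef_covariance[1 : 1 + self._q, 1 : 1 + self._q]

    def smooth_values(self, t):
        """Centered smooth f(t) (log scale, no intercept, no unit effect)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tv = np.atleast_1d(t)
        if self.basis is None:
            out = np.zeros(tv.shape)
        else:
            out = self.basis.design(tv) @ self.smooth_coefs
        return float(out[0]) if scalar else out

    def predict_log_rate(self, t, unit_id=None, offset=0.0):
        """Linear predictor (log expected count) at temperatures ``t``."""
        eta = self.intercept + self.smooth_values(t) + np.asarray(offset, float)
        if unit_id is not None:
            if unit_id not in self.random_intercepts:
                raise KeyError(f"unknown unit {unit_id!r}")
            eta = eta + self.random_intercepts[unit_id]
        return eta

    # serialization --------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "basis": None if self.basis is None else self.basis.to_dict(),
            "coefficients": self.coefficients.tolist(),
            "coef_covariance": self.coef_covariance.tolist(),
            "lam": self.lam,
            "dispersion": self.dispersion,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "intercept": self.intercept,
            "offset_used": self.offset_used,
            "exposure_percentiles": self.exposure_percentiles,
            "converged": self.converged,
            "reml": self.reml,
            "n_obs": self.n_obs,
            "lambda_u": self.lambda_u,
            "sigma2_u": self.sigma2_u,
            "random_intercepts": self.random_intercepts,
            "pearson": self.pearson,
            "deviance": self.deviance,
            "n_iter": self.n_iter,
            "var_fixed_lp": self.var_fixed_lp,
            "mean_count": self.mean_count,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SmoothFit":
        d = json.loads(s)
        d["basis"] = None if d["basis"] is None else BasisSpec.from_dict(d["basis"])
        d["coefficients"] = np.asarray(d["coefficients"], float)
        d["coef_covariance"] = np.asarray(d["coef_covariance"], float)
        if d["exposure_percentiles"] is not None:
            d["exposure_percentiles"] = tuple(d["exposure_percentiles"])
        return cls(**d)


# ---------------------------------------------------------------------------
# PIRLS core


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(t - (y - mu)))


def _run_pirls(y, X, P, offset, beta0=None, max_iter=200, tol=1e-8):
    """Penalized IRLS for the quasi-Poisson log-link model.

    Returns the converged state: coefficients, means, the penalized Hessian
    factor, and working-model quantities needed by the REML criterion.
    """
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), y.shape)
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -300, 300))
    else:
        mu = (y + np.mean(y)) / 2.0 + 1e-4
        eta = np.log(mu)
        beta = np.zeros(p)
    pen_dev = _poisson_deviance(y, mu) + beta @ P @ beta
    trace = []
    for it in range(max_iter):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        H = XtW @ X + P
        rhs = XtW @ z
        try:
            cho = linalg.cho_factor(H, lower=True)
            beta_new = linalg.cho_solve(cho, rhs)
        except linalg.LinAlgError as err:
            raise PirlsError(f"singular penalized Hessian at iteration {it}: {err}", trace)
        # step halving if the penalized deviance would increase
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand + offset
            mu_c = np.exp(np.clip(eta_c, -300, 300))
            pen_c = _poisson_deviance(y, mu_c) + cand @ P @ cand
            if np.isfinite(pen_c) and pen_c <= pen_dev + 1e-10 * (abs(pen_dev) + 1.0):
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        delta = abs(pen_dev - pen_c)
        trace.append((it, pen_c, delta))
        converged = delta < tol * (abs(pen_c) + 0.1)
        pen_dev = pen_c
        if converged:
            break
    else:
        raise PirlsError(
            f"PIRLS did not converge in {max_iter} iterations "
            f"(last penalized-deviance change {delta:.3e})",
            trace,
        )
    w = mu
    XtW = X.T * w
    XtWX = XtW @ X
    H = XtWX + P
    cho = linalg.cho_factor(H, lower=True)
    Hinv = linalg.cho_solve(cho, np.eye(p))
    edf_diag = np.einsum("ij,ji->i", Hinv, XtWX)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return {
        "beta": beta,
        "mu": mu,
        "eta": eta,
        "Hinv": Hinv,
        "edf_diag": edf_diag,
        "pearson": pearson,
        "deviance": _poisson_deviance(y, mu),
        "logdet_H": logdet_H,
        "sum_log_w": float(np.sum(np.log(w))),
        "penalty_quad": float(beta @ P @ beta),
        "n_iter": it + 1,
    }


def _assemble(y, x, offset, unit_ids, k, degree, penalty_order, basis):
    """Build the stacked design [intercept | smooth | unit dummies]."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    cols = [np.ones((n, 1))]
    if x is not None:
        x = np.asarray(x, dtype=float)
        if basis is None:
            Xs, Ss, basis = build_basis(x, k=k, degree=degree, penalty_order=penalty_order)
        else:
            Xs, Ss = basis.design(x), basis.penalty
        cols.append(Xs)
    else:
        Ss = None
    unit_levels = []
    if unit_ids is not None:
        unit_ids = np.asarray(unit_ids)
        unit_levels, codes = np.unique(unit_ids, return_inverse=True)
        U = np.zeros((n, unit_levels.size))
        U[np.arange(n), codes] = 1.0
        cols.append(U)
    X = np.hstack(cols)
    return X, Ss, basis, list(unit_levels), x


def _penalty_matrix(p, q, Ss, lam, n_units, lambda_u):
    P = np.zeros((p, p))
    if q:
        P[1 : 1 + q, 1 : 1 + q] = lam * Ss
    if n_units:
        i0 = 1 + q
        P[i0 : i0 + n_units, i0 : i0 + n_units] = lambda_u * np.eye(n_units)
    return P


def _reml_criterion(state, P_unpen_dim, logdet_P_pos, n, phi0=None):
    """Negative restricted (Laplace) quasi-likelihood (x2) at the converged
    fit: extended quasi-likelihood deviance plus the log-determinant terms.

    ``phi0`` is the quasi-Poisson scale.  During smoothing-parameter
    selection it is estimated once, by Pearson, from a low-smoothing pilot
    fit and then held fixed: profiling it from the deviance underestimates
    the scale at the low daily means typical of this outcome (deviance
    residuals shrink as the mean -> 0) and re-estimating it at every
    candidate rewards shrinkage, both of which distort the criterion.  When
    ``phi0`` is None the deviance-profiled value is used (reporting only).
    """
    Dp = state["deviance"] + state["penalty_quad"]
    nm = n - P_unpen_dim
    if phi0 is None:
        phi = Dp / nm
        if phi <= 0 or not np.isfinite(phi):
            return np.inf, phi
        neg2 = (
            nm * (1.0 + np.log(2.0 * np.pi * phi))
            + state["logdet_H"]
            - logdet_P_pos
        )
        return float(neg2), phi
    neg2 = (
        Dp / phi0
        + nm * np.log(2.0 * np.pi * phi0)
        + state["logdet_H"]
        - logdet_P_pos
    )
    return float(neg2), phi0


def _finalize(
    state, basis, lam, lambda_u, unit_levels, x, offset_used, n, reml,
    X=None, converged=True,
):
    beta = state["beta"]
    edf_total = float(np.sum(state["edf_diag"]))
    q = 0 if basis is None else basis.k - 1
    edf_smooth = float(np.sum(state["edf_diag"][1 : 1 + q])) if q else 0.0
    dispersion = state["pearson"] / max(n - edf_total, 1.0)
    Vb = dispersion * state["Hinv"]
    n_u = len(unit_levels)
    sigma2_u = dispersion / lambda_u if (n_u and lambda_u > 0) else 0.0
    rand = {}
    if n_u:
        rand = {
            str(u): float(b) for u, b in zip(unit_levels, beta[1 + q : 1 + q + n_u])
        }
    pct = None
    if x is not None:
        pct = (float(np.percentile(x, 1)), float(np.percentile(x, 99)))
    var_fixed_lp = 0.0
    if X is not None and q:
        fixed_lp = X[:, 1 : 1 + q] @ beta[1 : 1 + q]
        var_fixed_lp = float(np.var(fixed_lp))
    return SmoothFit(
        basis=basis,
        coefficients=beta,
        coef_covariance=Vb,
        lam=float(lam),
        dispersion=float(dispersion),
        edf=edf_smooth,
        edf_total=edf_total,
        intercept=float(beta[0]),
        offset_used=offset_used,
        exposure_percentiles=pct,
        converged=converged,
        reml=float(reml),
        n_obs=int(n),
        lambda_u=float(lambda_u),
        sigma2_u=float(sigma2_u),
        random_intercepts=rand,
        pearson=float(state["pearson"]),
        deviance=float(state["deviance"]),
        n_iter=state["n_iter"],
        var_fixed_lp=var_fixed_lp,
        mean_count=float(np.mean(state["mu"])),
    )


def _validate_y(y):
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if not np.any(y > 0):
        raise ValueError("all counts are zero: the log-rate model is degenerate")
    return np.asarray(y, dtype=float)


def fit_pirls(
    y,
    x=None,
    offset=0.0,
    lam: float = 0.0,
    *,
    k: int = 10,
    degree: int = 3,
    penalty_order: int = 2,
    unit_ids=None,
    lambda_u: float = 0.0,
    basis: BasisSpec | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> SmoothFit:
    """Fit the penalized quasi-Poisson smooth at fixed smoothing parameters.

    ``x=None`` fits an intercept-only model; ``unit_ids`` adds ridge-penalized
    unit dummy intercepts with ridge weight ``lambda_u`` (0 = unpenalized
    fixed effects).  ``offset`` is the log person-time (e.g. log population).
    """
    if lam < 0 or lambda_u < 0:
        raise ValueError("smoothing parameters must be nonnegative")
    y = _validate_y(y)
    X, Ss, basis, unit_levels, x = _assemble(
        y, x, offset, unit_ids, k, degree, penalty_order, basis
    )
    q = 0 if basis is None else basis.k - 1
    P = _penalty_matrix(X.shape[1], q, Ss, lam, len(unit_levels), lambda_u)
    state = _run_pirls(y, X, P, offset, max_iter=max_iter, tol=tol)
    unpen = 1 + (basis.null_dim if (q and lam > 0) else q)
    if unit_levels and lambda_u == 0:
        unpen += len(unit_levels)
    logdet_P = 0.0
    if q and lam > 0:
        logdet_P += (q - basis.null_dim) * np.log(lam) + basis.penalty_logdet_pos
    if unit_levels and lambda_u > 0:
        logdet_P += len(unit_levels) * np.log(lambda_u)
    reml, _ = _reml_criterion(state, unpen, logdet_P, len(y))
    offset_used = np.any(np.asarray(offset) != 0)
    return _finalize(
        state, basis, lam, lambda_u, unit_levels, x, bool(offset_used), len(y), reml, X=X
    )


def _reml_objective_factory(y, X, Ss, basis, unit_levels, offset, max_iter, tol):
    """Closure evaluating the REML criterion at (log10 lam, log10 lam_u),
    warm-starting PIRLS from the previous solution."""
    n = len(y)
    q = 0 if basis is None else basis.k - 1
    n_u = len(unit_levels)
    cache = {"beta": None, "phi0": None}
    unpen = 1 + (basis.null_dim if q else 0)

    def pilot_scale():
        # Pearson scale from a low-smoothing pilot (mild ridge keeps the
        # unit dummies identifiable against the intercept)
        lam_pilot = 1e-6
        lam_u_pilot = 1.0 if n_u else 0.0
        P = _penalty_matrix(X.shape[1], q, Ss, lam_pilot, n_u, lam_u_pilot)
        state = _run_pirls(y, X, P, offset, max_iter=max_iter, tol=tol)
        edf = float(np.sum(state["edf_diag"]))
        return state["pearson"] / max(n - edf, 1.0)

    def objective(theta):
        if cache["phi0"] is None:
            cache["phi0"] = pilot_scale()
        lam = 10.0 ** theta[0] if q else 0.0
        lam_u = 10.0 ** theta[1] if n_u and len(theta) > 1 else 0.0
        P = _penalty_matrix(X.shape[1], q, Ss, lam, n_u, lam_u)
        try:
            state = _run_pirls(
                y, X, P, offset, beta0=cache["beta"], max_iter=max_iter, tol=tol
            )
        except PirlsError:
            return np.inf, None, (lam, lam_u)
        cache["beta"] = state["beta"]
        logdet_P = 0.0
        if q:
            logdet_P += (q - basis.null_dim) * np.log(lam) + basis.penalty_logdet_pos
        if n_u and lam_u > 0:
            logdet_P += n_u * np.log(lam_u)
        crit, _ = _reml_criterion(state, unpen, logdet_P, n, phi0=cache["phi0"])
        return crit, state, (lam, lam_u)

    return objective


def select_lambda_reml(
    y,
    x,
    offset=0.0,
    *,
    k: int = 10,
    degree: int = 3,
    penalty_order: int = 2,
    basis: BasisSpec | None = None,
    grid: tuple[float, float, int] = (-2.0, 8.0, 15),
    refine_tol: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, SmoothFit]:
    """Select the smoothing parameter by REML: log-spaced grid plus
    golden-section refinement, returning ``(lambda_hat, fit)``."""
    y = _validate_y(y)
    X, Ss, basis, unit_levels, x = _assemble(
        y, x, offset, None, k, degree, penalty_order, basis
    )
    obj = _reml_objective_factory(y, X, Ss, basis, unit_levels, offset, max_iter, tol)
    lo, hi, npts = grid
    thetas = np.linspace(lo, hi, int(npts))
    vals = [obj([t])[0] for t in thetas]
    if not np.any(np.isfinite(vals)):
        raise PirlsError("REML criterion non-finite over the entire grid")
    i = int(np.nanargmin(vals))
    a = thetas[max(i - 1, 0)]
    b = thetas[min(i + 1, len(thetas) - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda t: obj([t])[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": refine_tol},
        )
        theta_hat = float(res.x) if res.fun <= vals[i] else thetas[i]
    else:
        theta_hat = thetas[i]
    crit, state, (lam, _) = obj([theta_hat])
    fit = _finalize(
        state, basis, lam, 0.0, unit_levels, x,
        bool(np.any(np.asarray(offset) != 0)), len(y), crit, X=X,
    )
    return lam, fit


def fit_gamm(
    y,
    x,
    offset,
    unit_ids,
    *,
    k: int = 10,
    degree: int = 3,
    penalty_order: int = 2,
    basis: BasisSpec | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    maxfev: int = 60,
) -> SmoothFit:
    """Fit the GAMM: smooth of exposure plus per-unit random intercepts.

    The random intercepts are ridge-penalized dummy coefficients; their ridge
    weight and the smooth's penalty are optimised jointly on the REML
    criterion (coarse log grid, then Nelder-Mead).  The implied variance
    component is ``sigma2_u = dispersion / lambda_u``.
    """
    y = _validate_y(y)
    unit_ids = np.asarray(unit_ids)
    if np.unique(unit_ids).size < 2:
        raise ValueError("fit_gamm needs >= 2 units; use fit_pirls for a single unit")
    X, Ss, basis, unit_levels, x = _assemble(
        y, x, offset, unit_ids, k, degree, penalty_order, basis
    )
    obj = _reml_objective_factory(y, X, Ss, basis, unit_levels, offset, max_iter, tol)
    best = (np.inf, None)
    for t1 in (0.0, 2.0, 4.0):
        for t2 in (-1.0, 0.5, 2.0, 3.5):
            v = obj([t1, t2])[0]
            if v < best[0]:
                best = (v, (t1, t2))
    if best[1] is None:
        raise PirlsError("REML criterion non-finite over the starting grid")
    res = optimize.minimize(
        lambda th: obj(th)[0],
        x0=np.asarray(best[1]),
        method="Nelder-Mead",
        options={"xatol": 0.05, "fatol": 0.01, "maxfev": maxfev},
    )
    theta = res.x if res.fun <= best[0] else np.asarray(best[1])
    crit, state, (lam, lam_u) = obj(theta)
    return _finalize(
        state, basis, lam, lam_u, unit_levels, x,
        bool(np.any(np.asarray(offset) != 0)), len(y), crit, X=X,
    )


# ---------------------------------------------------------------------------
# fit metrics


def compute_metrics(fit: SmoothFit, y=None) -> FitMetrics:
    """Smooth-term EDF and p-value plus marginal/conditional R-squared.

    R-squared follows the variance-decomposition approach for log-link count
    mixed models: the fixed-effect variance is the variance of the fitted
    fixed linear predictor (intercept + smooth, offset excluded), the random
    component is ``sigma2_u``, and the observation-level variance is the
    trigamma of the mean count over the dispersion,
    ``psi_1(lambda_bar / phi)``.  The smooth-term p-value is a Wald-type test
    on the penalized coefficients with rank set by the rounded-up EDF;
    approximate by construction.
    """
    if not fit.converged:
        raise ValueError("metrics require a converged fit")
    if fit.basis is None:
        var_f = 0.0
        p_smooth = 1.0
    else:
        var_f = fit.var_fixed_lp
        b = fit.smooth_coefs
        V = fit.smooth_cov
        r = int(np.ceil(fit.edf))
        r = max(1, min(r, b.size))
        evals, evecs = linalg.eigh(V)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order][:r], evecs[:, order][:, :r]
        evals = np.maximum(evals, evals.max() * 1e-12)
        stat = float(np.sum((evecs.T @ b) ** 2 / evals))
        p_smooth = float(stats.chi2.sf(stat, df=r))
    var_u = fit.sigma2_u
    lambda_bar = float(np.mean(y)) if y is not None else fit.mean_count
    lambda_bar = max(lambda_bar, 1e-8)
    var_eps = float(special.polygamma(1, lambda_bar / max(fit.dispersion, 1e-12)))
    total = var_f + var_u + var_eps
    return FitMetrics(
        edf=fit.edf,
        p_value_smooth=p_smooth,
        marginal_r2=var_f / total if total > 0 else 0.0,
        conditional_r2=(var_f + var_u) / total if total > 0 else 0.0,
    )
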