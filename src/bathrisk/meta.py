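"""Mixed-effects meta-regression of log peak RR on a within/between-decomposed
unit-level covariate.

The stage-2 model for unit :math:`i` and period :math:`j` is

.. math::

    \\log(\\mathrm{RR}_{ij}) = \\beta_0 + \\beta_1 (x_{ij} - \\bar x_i)
        + \\beta_2 \\bar x_i + u_i + \\varepsilon_{ij},

with unit random intercepts :math:`u_i \\sim N(0, \\sigma^2_u)` and residuals
:math:`\\varepsilon_{ij} \\sim N(0, \\sigma^2_e)`.  :math:`\\beta_1` captures
the association of within-unit deviations from the unit mean, :math:`\\beta_2`
the association of the unit means themselves.  Effects are reported as ratios
of peak RR per one SD of the covariate: ``exp(beta2 * sd_between)`` across
unit means and ``exp(beta1 * sd_within)`` across centered values, with
delta-method confidence intervals.

Estimation is REML for the linear mixed model, implemented directly (the
per-unit covariance blocks are tiny).  A weighted variant replaces the iid
residual variance by known per-row sampling variances ``v_ij`` plus an
estimated residual heterogeneity ``tau^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MetaInput", "MetaFit", "build_meta_input", "fit_meta", "ratio_per_sd"]

log = logging.getLogger(__name__)


@dataclass
class MetaInput:
    """Analysis rows for one covariate: y = log peak RR plus the decomposition."""

    data: pd.DataFrame  # columns: unit_id, period, y, v, x, x_bar, x_centered
    covariate: str

    @property
    def n_units(self) -> int:
        return self.data["unit_id"].nunique()

    @property
    def sd_between(self) -> float:
        means = self.data.groupby("unit_id")["x_bar"].first()
        return float(means.std(ddof=1))

    @property
    def sd_within(self) -> float:
        return float(self.data["x_centered"].std(ddof=1))

    @property
    def has_within_variation(self) -> bool:
        sw = self.sd_within
        return np.isfinite(sw) and sw > 1e-12


@dataclass
class MetaFit:
    """REML estimates for the within/between meta-regression."""

    covariate: str
    beta0: float
    beta1: float  # within-unit coefficient (nan in between-only mode)
    beta2: float  # between-unit coefficient
    se_beta0: float
    se_beta1: float
    se_beta2: float
    sigma2_u: float
    sigma2_e: float  # residual variance, or heterogeneity tau^2 when weighted
    sd_between: float
    sd_within: float
    weighted: bool
    n_units: int
    n_rows: int
    between_only: bool

    def _ratio(self, beta, se, sd):
        z = stats.norm.ppf(0.975)
        return (
            float(np.exp(beta * sd)),
            float(np.exp((beta - z * se) * sd)),
            float(np.exp((beta + z * se) * sd)),
        )

    @property
    def ratio_per_sd_between(self) -> tuple[float, float, float]:
        return self._ratio(self.beta2, self.se_beta2, self.sd_between)

    @property
    def ratio_per_sd_within(self) -> tuple[float, float, float]:
        if self.between_only:
            return (np.nan, np.nan, np.nan)
        return self._ratio(self.beta1, self.se_beta1, self.sd_within)

    def wald_p(self, which: str = "between") -> float:
        beta, se = (
            (self.beta2, self.se_beta2)
            if which == "between"
            else (self.beta1, self.se_beta1)
        )
        if se == 0 or not np.isfinite(se):
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(beta / se)))


def build_meta_input(
    peak_rr_table: pd.DataFrame, covariate_table: pd.DataFrame, covariate_name: str
) -> MetaInput:
    """Join the stage-1 peak-RR table with one covariate and decompose it.

    ``y`` is the natural log of the peak RR, ``v`` its sampling variance
    (squared standard error) when available.  Within-unit centering uses each
    unit's mean over the periods where the covariate is observed; rows with a
    missing covariate are dropped with a logged count, so covariates with
    partial period coverage contribute between-unit information only for the
    periods they cover.
    """
    if covariate_name not in covariate_table.columns:
        raise KeyError(f"covariate {covariate_name!r} not in the covariate table")
    cov = covariate_table[["unit_id", "period", covariate_name]].rename(
        columns={covariate_name: "x"}
    )
    df = peak_rr_table.merge(cov, on=["unit_id", "period"], how="left")
    n_missing = int(df["x"].isna().sum())
    if n_missing:
        log.info(
            "dropping %d of %d rows with missing %r", n_missing, len(df), covariate_name
        )
    df = df.dropna(subset=["x"]).copy()
    if df.empty:
        raise ValueError(f"covariate {covariate_name!r} is missing everywhere")
    df["y"] = df["log_peak_rr"].astype(float)
    if "se_log_peak_rr" in df.columns:
        df["v"] = df["se_log_peak_rr"].astype(float) ** 2
    else:
        df["v"] = np.nan
    df["x_bar"] = df.groupby("unit_id")["x"].transform("mean")
    df["x_centered"] = df["x"] - df["x_bar"]
    out = df[["unit_id", "period", "y", "v", "x", "x_bar", "x_centered"]].reset_index(
        drop=True
    )
    return MetaInput(data=out, covariate=covariate_name)


# ---------------------------------------------------------------------------
# REML machinery


def _gls_parts(y, X, codes, n_groups, base_var, s2_u, s2_e):
    """Woodbury-based GLS building blocks for V_i = diag(v + s2_e) + s2_u J.

    Returns (XtVinvX, XtVinvy, ytVinvy, logdet_V), all vectorized over rows
    (``codes`` maps each row to its unit).
    """
    d = base_var + s2_e
    if np.any(d <= 0):
        return None
    dinv = 1.0 / d
    a = np.bincount(codes, weights=dinv, minlength=n_groups)
    denom = 1.0 + s2_u * a
    if np.any(denom <= 0):
        return None
    c = s2_u / denom  # per-group Woodbury factor
    Xd = X * dinv[:, None]
    # per-group sums of D^{-1} X and D^{-1} y
    T = np.zeros((n_groups, X.shape[1]))
    np.add.at(T, codes, Xd)
    ty = np.bincount(codes, weights=dinv * y, minlength=n_groups)
    XtVinvX = X.T @ Xd - (T * c[:, None]).T @ T
    XtVinvy = Xd.T @ y - T.T @ (c * ty)
    ytVinvy = float(np.sum(dinv * y * y) - np.sum(c * ty * ty))
    logdet = float(np.sum(np.log(d)) + np.sum(np.log(denom)))
    return XtVinvX, XtVinvy, ytVinvy, logdet


def _neg2_reml(theta, y, X, codes, n_groups, base_var):
    """-2 x restricted log-likelihood; theta = (log s2_u, log s2_resid)."""
    s2_u, s2_e = np.exp(theta)
    parts = _gls_parts(y, X, codes, n_groups, base_var, s2_u, s2_e)
    if parts is None:
        return np.inf
    XtVX, XtVy, ytVy, logdet = parts
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = ytVy - beta @ XtVy
    return logdet + logdet_X + rss


def _gls(y, X, codes, n_groups, base_var, s2_u, s2_e):
    XtVX, XtVy, _, _ = _gls_parts(y, X, codes, n_groups, base_var, s2_u, s2_e)
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    return beta, cov


def fit_meta(inp: MetaInput, weighted: bool = False) -> MetaFit:
    """REML fit of the within/between mixed model.

    ``weighted=True`` uses the stage-1 sampling variances ``v_ij`` as known
    per-row variances and estimates residual heterogeneity on top (the
    reported ``sigma2_e`` is then the heterogeneity ``tau^2``); the default
    treats residuals as iid, implementing the model equation literally.

    Falls back to the between-only model (no ``beta1``) when the covariate has
    no within-unit variation, and raises for fewer than 3 units.
    """
    df = inp.data
    n_units = inp.n_units
    if n_units < 3:
        raise ValueError("meta-regression requires >= 3 units")
    if weighted and df["v"].isna().any():
        raise ValueError("weighted fit requires sampling variances for every row")
    between_only = not inp.has_within_variation
    y = df["y"].to_numpy(dtype=float)
    if between_only:
        X = np.column_stack([np.ones(len(df)), df["x_bar"].to_numpy(float)])
    else:
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["x_centered"].to_numpy(float),
                df["x_bar"].to_numpy(float),
            ]
        )
    codes, _ = pd.factorize(df["unit_id"])
    n_groups = int(codes.max()) + 1
    base_var = df["v"].to_numpy(float) if weighted else np.zeros(len(df))
    sizes = np.bincount(codes, minlength=n_groups)
    single_row_groups = bool(np.all(sizes == 1))

    scale = max(float(np.var(y)), 1e-10)
    starts = [
        np.log([0.5 * scale, 0.5 * scale]),
        np.log([0.1 * scale, 0.9 * scale]),
        np.log([0.9 * scale, 0.1 * scale]),
    ]
    lb = np.log(1e-12 * max(scale, 1.0))

    def objective(theta):
        th = np.clip(theta, lb, 10.0)
        if single_row_groups:
            # sigma2_u and sigma2_e are not separable with one row per unit
            th = np.array([lb, np.logaddexp(th[0], th[1])])
        return _neg2_reml(th, y, X, codes, n_groups, base_var)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ValueError("REML criterion non-finite: working covariance ill-conditioned")
    theta = np.clip(best.x, lb, 10.0)
    if single_row_groups:
        theta = np.array([lb, np.logaddexp(theta[0], theta[1])])
    s2_u, s2_e = np.exp(theta)
    floor = 1e-10 * max(scale, 1.0)
    s2_u = 0.0 if s2_u < floor else float(s2_u)
    s2_e_rep = 0.0 if s2_e < floor else float(s2_e)
    beta, cov = _gls(
        y, X, codes, n_groups, base_var, max(s2_u, floor * 1e-2), max(s2_e, floor * 1e-2)
    )
    se = np.sqrt(np.diag(cov))
    if between_only:
        b0, b2 = beta
        se0, se2 = se
        b1, se1 = float("nan"), float("nan")
    else:
        b0, b1, b2 = beta
        se0, se1, se2 = se
    return MetaFit(
        covariate=inp.covariate,
        beta0=float(b0),
        beta1=float(b1),
        beta2=float(b2),
        se_beta0=float(se0),
        se_beta1=float(se1),
        se_beta2=float(se2),
        sigma2_u=s2_u,
        sigma2_e=s2_e_rep,
        sd_between=inp.sd_between,
        sd_within=inp.sd_within if not between_only else float("nan"),
        weighted=bool(weighted),
        n_units=n_units,
        n_rows=len(df),
        between_only=between_only,
    )


def ratio_per_sd(fit: MetaFit) -> pd.DataFrame:
    """One reportable row: per-SD ratios of peak RR with delta-method CIs."""
    if not np.isfinite(fit.sd_between) or fit.sd_between <= 0:
        raise ValueError("between-unit SD of the covariate is zero: per-SD effect undefined")
    rb, rb_lo, rb_hi = fit.ratio_per_sd_between
    if fit.between_only:
        rw = rw_lo = rw_hi = np.nan
    else:
        if fit.sd_within <= 0:
            raise ValueError("within-unit SD of the covariate is zero")
        rw, rw_lo, rw_hi = fit.ratio_per_sd_within
    return pd.DataFrame(
        [
            {
                "covariate": fit.covariate,
                "ratio_between_per_sd": rb,
                "between_ci_low": rb_lo,
                "between_ci_high": rb_hi,
                "ratio_within_per_sd": rw,
                "within_ci_low": rw_lo,
                "within_ci_high": rw_hi,
                "n_units": fit.n_units,
                "n_rows": fit.n_rows,
            }
        ]
    )
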