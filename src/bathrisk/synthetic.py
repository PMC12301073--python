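"""Synthetic prefecture-day cohorts for temperature--bath-drowning analyses.

The real outcome data (death certificates coded as accidental drowning and
submersion in a bathtub) are restricted, so this module generates panels with
the same statistical structure: 47 prefecture-like units observed daily over
multiple years, strong winter seasonality in the death rate, quasi-Poisson
overdispersion, unit random intercepts on the log rate, annual population
offsets, and a nonlinear exposure-response in daily mean temperature whose
maximum-to-minimum risk ratio ("peak RR") is modified log-linearly by
unit-level covariates.

Every generator takes an integer seed (or a ``numpy.random.Generator``) and is
reproducible bit-for-bit.  Ground truth (the exposure-response curve and each
unit-period's true peak RR) is returned alongside the data so that recovery
tests can score the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

__all__ = [
    "UnitSpec",
    "TrueCurve",
    "Cohort",
    "DEFAULT_PERIODS",
    "simulate_temperature",
    "make_true_curve",
    "simulate_counts",
    "make_modifier_truth",
    "make_cohort",
    "write_cohort",
]

#: Analysis periods used throughout: three blocks of a 26-year window.
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = ((1995, 2003), (2004, 2012), (2013, 2020))

#: Day of year (late January) at which the seasonal temperature cycle bottoms out.
COLDEST_DOY = 28


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class UnitSpec:
    """Generating parameters for one prefecture-like unit.

    Parameters
    ----------
    unit_id : str
        Label used in output tables.
    population : float
        Residents (constant within a calendar year; the offset in the models).
    annual_mean_temp : float
        Long-run mean of daily mean temperature, deg C.
    seasonal_amplitude : float
        Half peak-to-trough seasonal swing of daily mean temperature, deg C.
    ar1_coef : float
        Lag-1 autocorrelation of the day-to-day temperature anomaly.
    noise_sd : float
        Marginal standard deviation of the temperature anomaly, deg C.
    random_intercept : float
        Unit offset on the log death rate (log scale).
    modifier_values : dict
        Covariate name -> value, for the unit-level modifier table.
    """

    unit_id: str
    population: float
    annual_mean_temp: float
    seasonal_amplitude: float = 9.5
    ar1_coef: float = 0.6
    noise_sd: float = 1.5
    random_intercept: float = 0.0
    modifier_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError("population must be positive")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be nonnegative")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("ar1_coef must satisfy |rho| < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class TrueCurve:
    """Ground-truth log relative-risk curve for the synthetic generator.

    ``log_risk_fn`` maps daily mean temperature (deg C) to log relative risk,
    normalised so that the minimum over its support is 0 at ``ref_temp`` and
    the maximum is ``log(true_peak_rr)`` at ``peak_temp``.
    """

    log_risk_fn: Callable[[np.ndarray], np.ndarray]
    ref_temp: float
    peak_temp: float
    true_peak_rr: float
    baseline_rate: float

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")


@dataclass
class Cohort:
    """A generated cohort: data plus the truth used to generate it."""

    panel: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame
    units: list[UnitSpec]
    params: dict


# ---------------------------------------------------------------------------
# temperature


def simulate_temperature(spec: UnitSpec, start_date, end_date, seed) -> pd.DataFrame:
    """Simulate a daily temperature series (tmean, tmax, tmin) for one unit.

    Daily mean temperature follows a sinusoidal annual cycle (coldest in late
    January) plus a stationary AR(1) Gaussian anomaly with marginal SD
    ``spec.noise_sd``.  Daily maximum/minimum are the mean plus/minus
    independent gamma-distributed half-ranges, so ``tmin <= tmean <= tmax``
    always holds and the diurnal range averages about 8.4 deg C.
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"start_date {start.date()} is after end_date {end.date()}")
    rng = _as_rng(seed)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - COLDEST_DOY) / 365.25 + np.pi
    )
    if spec.noise_sd > 0:
        burn = 200
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1_coef**2)
        innov = rng.normal(0.0, innov_sd, size=n + burn)
        anomaly = lfilter([1.0], [1.0, -spec.ar1_coef], innov)[burn:]
    else:
        anomaly = np.zeros(n)
    tmean = spec.annual_mean_temp + seasonal + anomaly
    # half-ranges: gamma with mean 4.2 deg C, SD ~1.65 deg C
    shape, scale = 6.5, 4.2 / 6.5
    up = rng.gamma(shape, scale, size=n)
    down = rng.gamma(shape, scale, size=n)
    return pd.DataFrame(
        {
            "date": dates,
            "tmean": tmean,
            "tmax": tmean + up,
            "tmin": tmean - down,
        }
    )


# ---------------------------------------------------------------------------
# true exposure-response curve


def make_true_curve(
    peak_rr: float,
    peak_temp: float,
    ref_temp: float,
    shape: str = "blend",
    baseline_rate: float = 3.5e-8,
    cold_curvature: float = 0.004,
    warm_curvature: float = 0.02,
    blend_weight: float = 0.35,
) -> TrueCurve:
    """Construct a ground-truth log relative-risk curve.

    The curve declines from ``log(peak_rr)`` at ``peak_temp`` to 0 at
    ``ref_temp``.  Shape ``"blend"`` (default) mixes a cubic smoothstep
    (steepest at mid-range temperatures, echoing the shape seen in national
    data) with a quadratic component (weight ``blend_weight``) so the slope at
    the reference stays nonzero and the minimum is statistically identifiable.
    Below the peak the log risk declines mildly (quadratic, ``cold_curvature``
    per deg C squared), so the maximum sits at ``peak_temp`` rather than at the
    cold boundary; above the reference a mild quadratic uptick keeps the
    minimum at ``ref_temp``.  Shape ``"smoothstep"`` sets ``blend_weight`` to 0.

    ``baseline_rate`` is the death rate (per person-day) at the reference
    temperature before unit random intercepts.
    """
    if peak_rr < 1:
        raise ValueError("peak_rr must be >= 1")
    if not peak_temp < ref_temp:
        raise ValueError("peak_temp must be below ref_temp")
    if shape not in ("blend", "smoothstep"):
        raise ValueError(f"unknown shape {shape!r}")
    w = 0.0 if shape == "smoothstep" else float(blend_weight)
    log_peak = float(np.log(peak_rr))
    span = ref_temp - peak_temp

    def log_risk(t):
        t = np.asarray(t, dtype=float)
        s = np.clip((t - peak_temp) / span, 0.0, 1.0)
        decline = (1.0 - w) * (3.0 * s**2 - 2.0 * s**3) + w * s**2
        out = log_peak * (1.0 - decline)
        cold = t < peak_temp
        out = np.where(cold, log_peak - cold_curvature * (peak_temp - t) ** 2, out)
        warmside = t > ref_temp
        out = np.where(warmside, warm_curvature * (t - ref_temp) ** 2, out)
        return out if out.ndim else float(out)

    return TrueCurve(
        log_risk_fn=log_risk,
        ref_temp=float(ref_temp),
        peak_temp=float(peak_temp),
        true_peak_rr=float(peak_rr),
        baseline_rate=float(baseline_rate),
    )


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    tmean: np.ndarray,
    curve: TrueCurve,
    unit: UnitSpec,
    dispersion: float = 1.3,
    seed=None,
) -> np.ndarray:
    """Draw daily death counts with quasi-Poisson variance ``phi * mean``.

    The conditional mean is
    ``population * baseline_rate * exp(log_risk(tmean) + random_intercept)``.
    With ``dispersion == 1`` counts are Poisson; otherwise they are
    gamma-mixed Poisson (negative binomial) with per-day size parameter
    ``m / (dispersion - 1)``, which matches the quasi-Poisson first two
    moments exactly for every mean ``m``.
    """
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1")
    rng = _as_rng(seed)
    tmean = np.asarray(tmean, dtype=float)
    mean = (
        unit.population
        * curve.baseline_rate
        * np.exp(np.asarray(curve.log_risk_fn(tmean)) + unit.random_intercept)
    )
    if dispersion == 1.0:
        return rng.poisson(mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    r = mean[pos] / (dispersion - 1.0)
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# cohorts


def _default_unit_specs(n_units: int, rng: np.random.Generator) -> list[UnitSpec]:
    # populations log-uniform over 0.5M-9M; annual mean temperatures span the
    # cool-north to warm-south gradient so the pooled panel reaches ~30 deg C
    pop = np.exp(rng.uniform(np.log(0.5e6), np.log(9e6), size=n_units))
    means = rng.uniform(9.0, 23.0, size=n_units)
    amps = rng.normal(9.5, 0.8, size=n_units).clip(7.0, 12.0)
    intercepts = rng.normal(0.0, 0.3, size=n_units)
    return [
        UnitSpec(
            unit_id=f"U{i + 1:02d}",
            population=float(pop[i]),
            annual_mean_temp=float(means[i]),
            seasonal_amplitude=float(amps[i]),
            random_intercept=float(intercepts[i]),
        )
        for i in range(n_units)
    ]


def make_modifier_truth(
    n_units: int,
    period_defs: Sequence[tuple[int, int]],
    modifier_effects: Mapping[str, float],
    seed,
    *,
    base_peak_rr: float = 9.7,
    unit_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Generate the unit-period covariate table and true log peak RRs.

    Covariates have a unit-level mean (N(20, 5^2), arbitrary percentage-like
    units) plus small period-to-period drift (N(0, 1.5^2)).  Each unit-period
    true log peak RR is the global mean plus the per-SD effects applied to the
    covariate standardised by the between-unit SD, plus a unit-level random
    deviation N(0, unit_sd^2).  ``seed`` may be an int or a Generator; two
    independent streams (covariates, deviations) are spawned from an int.

    Returns ``(covariates, truth, true_log_rr)`` with ``true_log_rr`` of shape
    (n_units, n_periods).
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if isinstance(seed, (tuple, list)):
        rng_cov, rng_dev = seed
    else:
        ss = np.random.SeedSequence(seed)
        rng_cov, rng_dev = (np.random.default_rng(s) for s in ss.spawn(2))
    modifier_effects = dict(modifier_effects or {})
    periods = [f"{a}-{b}" for a, b in period_defs]
    unit_ids = [f"U{i + 1:02d}" for i in range(n_units)]
    cov_rows = []
    zmat: dict[str, np.ndarray] = {}
    scales: dict[str, dict] = {}
    for name in modifier_effects:
        unit_means = rng_cov.normal(20.0, 5.0, size=n_units)
        dev = rng_cov.normal(0.0, 1.5, size=(n_units, len(periods)))
        x = unit_means[:, None] + dev
        sd_between = unit_means.std(ddof=1)
        zmat[name] = (x - x.mean()) / sd_between
        scales[name] = {"sd_between": float(sd_between), "center": float(x.mean())}
        for i, uid in enumerate(unit_ids):
            for j, per in enumerate(periods):
                cov_rows.append((uid, per, name, x[i, j]))
    covariates = (
        pd.DataFrame(cov_rows, columns=["unit_id", "period", "covariate", "value"])
        .pivot_table(index=["unit_id", "period"], columns="covariate", values="value")
        .reset_index()
        if cov_rows
        else pd.DataFrame({"unit_id": [], "period": []})
    )
    covariates.columns.name = None
    # standardisation used for the truth construction, for exact recovery checks
    covariates.attrs["standardization"] = scales

    dev_i = (
        rng_dev.normal(0.0, unit_sd, size=n_units) if unit_sd > 0 else np.zeros(n_units)
    )
    log_base = np.log(base_peak_rr)
    true_log_rr = np.zeros((n_units, len(periods)))
    truth_rows = []
    for i, uid in enumerate(unit_ids):
        for j, per in enumerate(periods):
            lp = log_base + dev_i[i]
            for name, eff in modifier_effects.items():
                lp += eff * zmat[name][i, j]
            true_log_rr[i, j] = lp
            truth_rows.append((uid, per, float(np.exp(lp)), float(lp)))
    truth = pd.DataFrame(
        truth_rows, columns=["unit_id", "period", "true_peak_rr", "true_log_peak_rr"]
    )
    return covariates, truth, true_log_rr


def make_cohort(
    n_units: int = 47,
    period_defs: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
    modifier_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    base_peak_rr: float = 9.7,
    peak_temp: float = 1.8,
    ref_temp: float = 30.3,
    dispersion: float = 1.3,
    unit_sd: float = 0.15,
    baseline_rate: float = 3.5e-8,
    curve_shape: str = "blend",
) -> Cohort:
    """Generate a full cohort: unit-day panel, covariate table and truth table.

    Each unit-period's true log peak RR is

    ``log(base_peak_rr) + sum_c effect_c * z_cij + dev_i``

    where ``z_cij`` is the covariate standardised by the between-unit SD of
    unit means, ``effect_c`` is the per-SD log ratio from
    ``modifier_effects``, and ``dev_i ~ N(0, unit_sd^2)`` is a unit-level
    deviation.  Counts for each day are generated from the curve of the period
    the day falls in; the returned truth table lists every unit-period true
    peak RR for recovery tests.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    period_defs = [tuple(p) for p in period_defs]
    for (a, b) in period_defs:
        if a > b:
            raise ValueError(f"period {a}-{b} is reversed")
    modifier_effects = dict(modifier_effects or {})
    ss = np.random.SeedSequence(seed)
    rng_units, rng_cov, rng_panel = (np.random.default_rng(s) for s in ss.spawn(3))

    units = _default_unit_specs(n_units, rng_units)
    periods = [f"{a}-{b}" for a, b in period_defs]
    covariates, truth, true_log_rr = make_modifier_truth(
        n_units,
        period_defs,
        modifier_effects,
        (rng_cov, rng_panel),
        base_peak_rr=base_peak_rr,
        unit_sd=unit_sd,
    )

    start = f"{period_defs[0][0]}-01-01"
    end = f"{period_defs[-1][1]}-12-31"
    frames = []
    for i, u in enumerate(units):
        child = np.random.default_rng(rng_panel.integers(2**31))
        temps = simulate_temperature(u, start, end, child)
        year = temps["date"].dt.year.to_numpy()
        deaths = np.zeros(len(temps), dtype=np.int64)
        for j, (a, b) in enumerate(period_defs):
            mask = (year >= a) & (year <= b)
            if not mask.any():
                continue
            curve = make_true_curve(
                float(np.exp(true_log_rr[i, j])),
                peak_temp,
                ref_temp,
                shape=curve_shape,
                baseline_rate=baseline_rate,
            )
            deaths[mask] = simulate_counts(
                temps["tmean"].to_numpy()[mask], curve, u, dispersion, child
            )
        frame = temps.copy()
        frame.insert(0, "unit_id", u.unit_id)
        frame["deaths"] = deaths
        frame["population"] = u.population
        frames.append(frame)
    panel = pd.concat(frames, ignore_index=True)
    panel = panel[["unit_id", "date", "deaths", "population", "tmean", "tmax", "tmin"]]

    params = {
        "n_units": n_units,
        "periods": periods,
        "modifier_effects": {k: float(v) for k, v in modifier_effects.items()},
        "seed": int(seed),
        "base_peak_rr": base_peak_rr,
        "peak_temp": peak_temp,
        "ref_temp": ref_temp,
        "dispersion": dispersion,
        "unit_sd": unit_sd,
        "baseline_rate": baseline_rate,
        "curve_shape": curve_shape,
    }
    return Cohort(panel=panel, covariates=covariates, truth=truth, units=units, params=params)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write panel/covariate/truth CSVs plus a YAML sidecar of the parameters.

    Returns the mapping of logical name to written path.  Output is
    byte-identical across runs with the same seed.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.csv",
        "params": out / "params.yaml",
    }
    panel = cohort.panel.copy()
    panel["date"] = panel["date"].dt.strftime("%Y-%m-%d")
    panel.to_csv(paths["panel"], index=False)
    cohort.covariates.to_csv(paths["covariates"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(cohort.params, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
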