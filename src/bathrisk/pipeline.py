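"""End-to-end two-stage analysis pipeline.

Stage 1 fits the national exposure-response (GAMM with unit random
intercepts) and one GAM per unit x period; stage 2 runs the within/between
meta-regression of log peak RR on each unit-level covariate.  The module also
provides the descriptive incidence-by-temperature trend table and two small
worked-example utilities (calendar day accounting and excess-death
arithmetic).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import curves as curves_mod
from . import meta as meta_mod
from . import spline

__all__ = [
    "AnalysisConfig",
    "TwoStageResult",
    "load_panel",
    "derive_temperature_metrics",
    "incidence_trend_table",
    "run_two_stage",
    "count_study_days",
    "excess_death_estimate",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["unit_id", "date", "deaths", "population", "tmean", "tmax", "tmin"]
TEMPERATURE_VARIABLES = ["tmean", "tmax", "tmin", "diurnal_range", "day_to_day_change"]
DEFAULT_PERIODS = ((1995, 2003), (2004, 2012), (2013, 2020))


@dataclass
class AnalysisConfig:
    """Configuration for a two-stage run.

    ``exposure`` is one of tmean/tmax/tmin/diurnal_range/day_to_day_change;
    ``periods`` are inclusive year ranges (non-overlapping, ordered);
    ``min_days``/``min_deaths`` are the unit-period data thresholds below
    which a stage-1 cell is skipped.
    """

    panel_path: str | None = None
    covariates_path: str | None = None
    exposure: str = "tmean"
    periods: tuple = DEFAULT_PERIODS
    k: int = 10
    n_sim: int = 1000
    seed: int = 0
    sex: str | None = None
    age_group: str | None = None
    min_days: int = 100
    min_deaths: int = 10
    weighted_meta: bool = False
    out_dir: str | None = None

    def __post_init__(self):
        if self.exposure not in TEMPERATURE_VARIABLES:
            raise ValueError(
                f"exposure must be one of {TEMPERATURE_VARIABLES}, got {self.exposure!r}"
            )
        periods = [tuple(p) for p in self.periods]
        for (a, b) in periods:
            if a > b:
                raise ValueError(f"period {a}-{b} is reversed")
        for (_, b), (a2, _) in zip(periods, periods[1:]):
            if a2 <= b:
                raise ValueError("periods must be ordered and non-overlapping")
        self.periods = tuple(periods)

    @property
    def period_labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.periods]


@dataclass
class TwoStageResult:
    national_fit: spline.SmoothFit
    national_metrics: spline.FitMetrics
    national_curve: curves_mod.RRCurve
    unit_period_fits: dict
    peak_table: pd.DataFrame
    meta_results: pd.DataFrame | None
    skipped: list
    manifest: dict


# ---------------------------------------------------------------------------
# data loading and derivations


def derive_temperature_metrics(panel: pd.DataFrame) -> pd.DataFrame:
    """Add diurnal_range and day_to_day_change columns.

    Diurnal range is tmax - tmin.  Day-to-day change is today's minus the
    previous calendar day's mean temperature within each unit; it is missing
    on a unit's first day and wherever the previous day is absent.
    """
    out = panel.sort_values(["unit_id", "date"]).reset_index(drop=True)
    out["diurnal_range"] = out["tmax"] - out["tmin"]
    prev_t = out.groupby("unit_id")["tmean"].shift(1)
    prev_d = out.groupby("unit_id")["date"].shift(1)
    gap_ok = (out["date"] - prev_d).dt.days == 1
    out["day_to_day_change"] = np.where(gap_ok, out["tmean"] - prev_t, np.nan)
    return out


def load_panel(csv_path) -> pd.DataFrame:
    """Load and validate a unit-day panel CSV, adding derived columns.

    Rows with a missing temperature are excluded, with per-variable exclusion
    counts logged (day-to-day change is derived after exclusion, so a dropped
    day also blanks the change on the following day).  A record violating
    ``tmin <= tmean <= tmax`` raises.
    """
    df = pd.read_csv(csv_path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"panel is missing required column(s): {missing_cols}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as err:
        raise ValueError(f"dates must be ISO-8601 (YYYY-MM-DD): {err}")
    n_in = len(df)
    excl = {}
    for var in ("tmean", "tmax", "tmin"):
        excl[var] = int(df[var].isna().sum())
    keep = df[["tmean", "tmax", "tmin"]].notna().all(axis=1)
    df = df.loc[keep].copy()
    log.info(
        "panel: %d rows read, %d retained; missing tmean=%d tmax=%d tmin=%d",
        n_in, len(df), excl["tmean"], excl["tmax"], excl["tmin"],
    )
    if (df["deaths"] < 0).any():
        raise ValueError("negative death counts present")
    if (df["population"] <= 0).any():
        raise ValueError("non-positive population present")
    bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
    if bad.any():
        i = df.index[bad][0]
        raise ValueError(
            f"temperature ordering violated (need tmin <= tmean <= tmax), "
            f"first offending row index {i}"
        )
    out = derive_temperature_metrics(df)
    out.attrs["exclusions"] = excl
    out.attrs["n_input_rows"] = n_in
    return out


def assign_periods(panel: pd.DataFrame, periods) -> pd.Series:
    """Period label per row (NaN outside every period)."""
    year = panel["date"].dt.year
    labels = pd.Series(pd.NA, index=panel.index, dtype="object")
    for a, b in periods:
        labels[(year >= a) & (year <= b)] = f"{a}-{b}"
    return labels


# ---------------------------------------------------------------------------
# descriptive table


def incidence_trend_table(panel: pd.DataFrame) -> tuple[pd.DataFrame, tuple]:
    """Temperature summaries by daily incidence category, with trend tests.

    Unit-days are grouped as zero incidence plus tertiles of the positive
    daily incidence per 10 million population (boundaries recomputed from the
    data).  For each temperature variable the table reports the per-group mean
    (SD) and a p-value from the linear regression of the variable on the
    ordinal group score (0-3).

    Returns ``(table, (t1, t2))`` where t1/t2 are the tertile boundaries.
    """
    inc = panel["deaths"] / panel["population"] * 1e7
    pos = inc[inc > 0]
    if pos.empty:
        raise ValueError("all incidences are zero; cannot form categories")
    if inc.nunique() < 4:
        raise ValueError("need at least 4 distinct incidence values")
    t1, t2 = np.quantile(pos, [1.0 / 3.0, 2.0 / 3.0])
    score = np.select(
        [inc == 0, inc <= t1, inc <= t2], [0, 1, 2], default=3
    )
    group_names = ["0", f">0, <={t1:.2f}", f">{t1:.2f}, <={t2:.2f}", f">{t2:.2f}"]
    rows = []
    counts = pd.Series(score).value_counts().reindex(range(4), fill_value=0)
    for var in TEMPERATURE_VARIABLES:
        if var not in panel.columns:
            continue
        vals = panel[var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        row = {"variable": var}
        for g in range(4):
            sel = ok & (score == g)
            row[group_names[g]] = (
                f"{np.mean(vals[sel]):.1f} ({np.std(vals[sel], ddof=1):.1f})"
                if sel.sum() > 1
                else ""
            )
        if np.unique(score[ok]).size > 1 and np.var(vals[ok]) > 0:
            res = stats.linregress(score[ok], vals[ok])
            row["slope"] = res.slope
            row["p_trend"] = res.pvalue
        elif np.unique(score[ok]).size > 1:
            # constant outcome: zero slope, no evidence of trend
            row["slope"], row["p_trend"] = 0.0, 1.0
        else:
            row["slope"], row["p_trend"] = np.nan, np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["group_sizes"] = counts.tolist()
    return table, (float(t1), float(t2))


# ---------------------------------------------------------------------------
# two-stage analysis


def _filter_strata(panel: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    out = panel
    for col, val in (("sex", config.sex), ("age_group", config.age_group)):
        if val is not None:
            if col not in out.columns:
                raise ValueError(f"stratum filter on {col!r} but column is absent")
            out = out[out[col] == val]
    return out


def run_two_stage(
    config: AnalysisConfig,
    panel: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> TwoStageResult:
    """Run the full analysis and (optionally) write all outputs.

    Steps: national GAMM of the exposure with unit random intercepts and a
    log-population offset; per unit x period GAM fits (cells with too few
    days or deaths are skipped with a logged warning); RR curves and the
    peak-RR table; and, when a covariate table is supplied, one
    meta-regression per covariate reporting per-SD ratios.
    """
    if panel is None:
        if config.panel_path is None:
            raise ValueError("either a panel or config.panel_path is required")
        panel = load_panel(config.panel_path)
    if covariates is None and config.covariates_path is not None:
        covariates = pd.read_csv(config.covariates_path)
    panel = _filter_strata(panel, config)
    exposure = config.exposure
    work = panel.dropna(subset=[exposure]).copy()

    ss = np.random.SeedSequence(config.seed)
    seed_national, seed_table = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
    )

    y = work["deaths"].to_numpy()
    x = work[exposure].to_numpy(dtype=float)
    offset = np.log(work["population"].to_numpy(dtype=float))
    units = work["unit_id"].to_numpy()

    national_fit = spline.fit_gamm(y, x, offset, units, k=config.k)
    national_metrics = spline.compute_metrics(national_fit, y)
    national_curve = curves_mod.rr_curve(
        national_fit, n_sim=config.n_sim, seed=seed_national
    )

    period_label = assign_periods(work, config.periods)
    fits = {}
    skipped = []
    for (unit, per), cell in work.groupby([pd.Series(units, index=work.index), period_label]):
        if len(cell) < config.min_days or cell["deaths"].sum() < config.min_deaths:
            skipped.append(
                {
                    "unit_id": unit,
                    "period": per,
                    "n_days": int(len(cell)),
                    "deaths": int(cell["deaths"].sum()),
                    "reason": "below minimum days/deaths threshold",
                }
            )
            log.warning("skipping unit=%s period=%s: too little data", unit, per)
            continue
        try:
            _, fit = spline.select_lambda_reml(
                cell["deaths"].to_numpy(),
                cell[exposure].to_numpy(dtype=float),
                np.log(cell["population"].to_numpy(dtype=float)),
                k=config.k,
            )
        except (spline.PirlsError, ValueError) as err:
            skipped.append(
                {"unit_id": unit, "period": per, "n_days": int(len(cell)),
                 "deaths": int(cell["deaths"].sum()), "reason": str(err)}
            )
            log.warning("skipping unit=%s period=%s: %s", unit, per, err)
            continue
        fits[(unit, per)] = fit

    peak_table = curves_mod.peak_rr_table(fits, n_sim=config.n_sim, seed=seed_table)

    meta_results = None
    if covariates is not None and not peak_table.empty:
        covariate_names = [
            c for c in covariates.columns if c not in ("unit_id", "period")
        ]
        if len(config.periods) < 2:
            log.info("single period: meta-regression runs in between-only mode")
        frames = []
        for name in covariate_names:
            try:
                minput = meta_mod.build_meta_input(peak_table, covariates, name)
                mfit = meta_mod.fit_meta(minput, weighted=config.weighted_meta)
                frames.append(meta_mod.ratio_per_sd(mfit))
            except (ValueError, KeyError) as err:
                log.warning("meta-regression failed for %r: %s", name, err)
        if frames:
            meta_results = pd.concat(frames, ignore_index=True)

    manifest = {
        "config": {
            k: (list(map(list, v)) if k == "periods" else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_rows": int(len(work)),
        "n_units": int(work["unit_id"].nunique()),
        "exclusions": panel.attrs.get("exclusions", {}),
        "n_unit_period_fits": len(fits),
        "skipped": skipped,
        "national": {
            "peak_rr": national_curve.peak_rr,
            "peak_temp_c": national_curve.peak_temp,
            "ref_temp_c": national_curve.ref_temp,
            "edf": national_fit.edf,
            "dispersion": national_fit.dispersion,
            "marginal_r2": national_metrics.marginal_r2,
            "conditional_r2": national_metrics.conditional_r2,
        },
    }
    result = TwoStageResult(
        national_fit=national_fit,
        national_metrics=national_metrics,
        national_curve=national_curve,
        unit_period_fits=fits,
        peak_table=peak_table,
        meta_results=meta_results,
        skipped=skipped,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_results(result, config)
    return result


def _write_results(result: TwoStageResult, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.peak_table.to_csv(out / "peak_rr.csv", index=False)
    result.national_curve.to_frame().to_csv(out / "national_rr_curve.csv", index=False)
    if result.meta_results is not None:
        result.meta_results.to_csv(out / "meta_regression.csv", index=False)
    (out / "national_fit.json").write_text(result.national_fit.to_json())
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# worked-example utilities


def count_study_days(start_date, end_date, n_units: int) -> int:
    """Calendar-exact unit-day count: days in [start, end] times units."""
    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if start > end:
        raise ValueError("start_date must not be after end_date")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return int((end - start).days + 1) * int(n_units)


def excess_death_estimate(
    attributable_fraction: float, total_deaths: float, rounding: str = "nearest_hundred"
) -> float:
    """Excess deaths = fraction x total, rounded per the stated rule."""
    if not 0.0 <= attributable_fraction <= 1.0:
        raise ValueError("attributable_fraction must be in [0, 1]")
    x = attributable_fraction * total_deaths
    if rounding == "nearest_hundred":
        return float(round(x / 100.0) * 100)
    if rounding == "none":
        return float(x)
    raise ValueError(f"unknown rounding rule {rounding!r}")
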