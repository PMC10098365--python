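"""Two-regime thermal-time fitting of germination time-courses.

The classical rate-regression construction: for each percentile g of the
seed population, read the time t_g at which the pooled cumulative
germination curve crosses g at every temperature, regress the germination
rate GR = 1/t_g on temperature separately in the sub-optimal (ascending)
and supra-optimal (descending) regions, and read the cardinal temperatures
and thermal-time constants off the fitted lines:

* sub-optimal slope  -> 1/theta_cold(g); x-intercept -> T_base (shared);
* supra-optimal x-intercept -> T_c(g); slope -> -1/theta_warm (shared);
* probit regression of theta_cold(g) and T_c(g) against the standard
  normal quantile of the within-viable rank recovers the medians and SDs
  of the two threshold distributions;
* T_opt is the intersection of the two median rate lines.

Percentiles are percent of *total seeds sown*; the probit transform maps
them to ranks within the viable population using the estimated maximum
germination percentage as the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .model import estimate_topt
from .simulate import GerminationRecord

__all__ = [
    "FitError",
    "FitConfig",
    "PercentileTimes",
    "ThermalTimeFit",
    "pooled_cumulative_curve",
    "percentile_times_from_curve",
    "interpolate_percentile_times",
    "build_gr_table",
    "split_regimes",
    "fit_suboptimal",
    "fit_supraoptimal",
    "fit_threshold_distribution",
    "fit_pipeline",
]


class FitError(RuntimeError):
    """A fitting stage could not proceed (insufficient or degenerate data)."""


@dataclass(frozen=True)
class PercentileTimes:
    """Interpolated time for one percentile at one temperature."""

    temperature: float
    percentile: float      # percent of total seeds sown
    t_g: float             # days; nan when not reached
    reached: bool


@dataclass(frozen=True)
class FitConfig:
    """Options of :func:`fit_pipeline`."""

    event: str = "er"                      # "er" (germination) or "tr"
    percentiles: Sequence[float] | None = None  # default: 10,20,.. < G_max
    reference_percentile: float | None = None   # default: 50 if available
    min_temps_per_percentile: int = 3
    #: raise on a wrong-signed percentile regression instead of dropping it
    strict: bool = False

    def __post_init__(self) -> None:
        if self.event not in ("er", "tr"):
            raise ValueError("event must be 'er' or 'tr'")


@dataclass
class ThermalTimeFit:
    """Recovered population parameters plus per-stage diagnostics."""

    T_base: float
    theta_cold_50: float
    sigma_theta: float
    T_c_50: float
    sigma_Tc: float
    theta_warm: float
    T_opt: float
    g_max_estimate: float            # percent of seeds sown
    sub_regressions: pd.DataFrame = field(repr=False)
    supra_regressions: pd.DataFrame = field(repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "T_base", "theta_cold_50", "sigma_theta", "T_c_50", "sigma_Tc",
            "theta_warm", "T_opt", "g_max_estimate")}
        out["sub_regressions"] = self.sub_regressions.to_dict("records")
        out["supra_regressions"] = self.supra_regressions.to_dict("records")
        out["diagnostics"] = self.diagnostics
        return out


# ----------------------------------------------------------------- curves

def pooled_cumulative_curve(records: Sequence[GerminationRecord],
                            event: str = "er"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Pool dishes of one temperature into a cumulative-% curve.

    Counts are summed across dishes at each scoring time and expressed as
    percent of all seeds sown; scoring noise is monotonized by a running
    maximum.
    """
    if not records:
        raise FitError("empty time-course")
    temps = {r.temperature_C for r in records}
    if len(temps) != 1:
        raise FitError(f"one temperature expected, got {sorted(temps)}")
    col = "er_count" if event == "er" else "tr_count"
    frame = pd.DataFrame([(r.time_d, getattr(r, col), r.dish_size)
                          for r in records],
                         columns=["time", "count", "size"])
    pooled = frame.groupby("time", sort=True).sum()
    pct = 100.0 * pooled["count"] / pooled["size"]
    return pooled.index.to_numpy(float), np.maximum.accumulate(
        pct.to_numpy(float))


def percentile_times_from_curve(times: np.ndarray, cum_pct: np.ndarray,
                                percentiles: Sequence[float]
                                ) -> list[tuple[float, float, bool]]:
    """Linear interpolation of percentile crossing times on a curve.

    The curve is anchored at (0, 0); a percentile above the final
    cumulative percentage is marked not reached.  Returns
    ``(percentile, t_g, reached)`` triples.
    """
    t = np.concatenate([[0.0], np.asarray(times, float)])
    c = np.concatenate([[0.0], np.asarray(cum_pct, float)])
    if np.any(np.diff(c) < 0):
        raise FitError("cumulative percentages must be non-decreasing "
                       "(monotonize first)")
    out = []
    for g in percentiles:
        if g > c[-1]:
            out.append((g, float("nan"), False))
            continue
        i = int(np.searchsorted(c, g, side="left"))
        if c[i] == g:
            # exact node: earliest time attaining g
            out.append((g, float(t[i]), True))
            continue
        t_g = t[i - 1] + (g - c[i - 1]) / (c[i] - c[i - 1]) * (t[i] - t[i - 1])
        out.append((g, float(t_g), True))
    return out


def interpolate_percentile_times(records: Sequence[GerminationRecord],
                                 percentiles: Sequence[float],
                                 event: str = "er"
                                 ) -> list[PercentileTimes]:
    """Percentile crossing times for one temperature's pooled dishes."""
    times, cum = pooled_cumulative_curve(records, event)
    temp = records[0].temperature_C
    return [PercentileTimes(temp, g, t_g, reached)
            for g, t_g, reached in
            percentile_times_from_curve(times, cum, percentiles)]


def build_gr_table(records: Sequence[GerminationRecord],
                   percentiles: Sequence[float],
                   event: str = "er") -> pd.DataFrame:
    """(temperature, percentile, t_g, gr) rows for all reached percentiles."""
    frame = pd.DataFrame([(r.temperature_C, r) for r in records],
                         columns=["temp", "rec"])
    rows = []
    for temp, grp in frame.groupby("temp"):
        for pt in interpolate_percentile_times(list(grp["rec"]), percentiles,
                                               event):
            if pt.reached and pt.t_g > 0:
                rows.append((pt.temperature, pt.percentile, pt.t_g,
                             1.0 / pt.t_g))
    return pd.DataFrame(rows, columns=["temperature", "percentile", "t_g",
                                       "gr"])


# ---------------------------------------------------------------- regimes

def split_regimes(gr_table: pd.DataFrame,
                  reference_percentile: float | None = None
                  ) -> tuple[list[float], list[float], float]:
    """Assign temperatures to the sub- and supra-optimal regions.

    The temperature with maximal GR at the reference percentile (50, or
    the lowest available) is the empirical optimum; temperatures at or
    below it are sub-optimal, at or above it supra-optimal (the argmax
    belongs to both, as in classical two-line fits).  A monotone rate
    profile yields an empty far side with a warning.
    """
    temps = sorted(gr_table["temperature"].unique())
    if len(temps) < 3:
        raise FitError(f"need >= 3 distinct temperatures, got {len(temps)}")
    available = sorted(gr_table["percentile"].unique())
    if not available:
        raise FitError("no reached percentiles")
    if reference_percentile is None:
        reference_percentile = 50.0 if 50.0 in available else available[0]
    ref = gr_table[gr_table["percentile"] == reference_percentile]
    if ref.empty:
        raise FitError(
            f"reference percentile {reference_percentile} reached nowhere")
    t_max = float(ref.loc[ref["gr"].idxmax(), "temperature"])
    sub = [t for t in temps if t <= t_max]
    supra = [t for t in temps if t >= t_max]
    if len(supra) == 1:
        warnings.warn("rates are monotone increasing over the grid; no "
                      "supra-optimal region to fit", stacklevel=2)
        supra = []
    if len(sub) == 1:
        warnings.warn("rates are monotone decreasing over the grid; no "
                      "sub-optimal region to fit", stacklevel=2)
        sub = []
    return sub, supra, reference_percentile


def _ols_line(temps: np.ndarray, gr: np.ndarray) -> tuple[float, float,
                                                          float]:
    """slope, intercept, R² of an ordinary least-squares line GR ~ T."""
    res = sm.OLS(gr, sm.add_constant(temps)).fit()
    return float(res.params[1]), float(res.params[0]), float(res.rsquared)


def _per_percentile_fits(gr_table: pd.DataFrame, regime_temps: Sequence[float],
                         *, expect_positive: bool, min_temps: int,
                         strict: bool, label: str) -> pd.DataFrame:
    sub = gr_table[gr_table["temperature"].isin(regime_temps)]
    rows, dropped = [], []
    for g, grp in sub.groupby("percentile"):
        if len(grp) < min_temps:
            dropped.append((g, "too few temperatures"))
            continue
        slope, intercept, r2 = _ols_line(grp["temperature"].to_numpy(),
                                         grp["gr"].to_numpy())
        # numerically zero slopes (flat rates) count as misassigned too
        tiny = 1e-10 * max(1.0, float(np.abs(grp["gr"]).max()))
        ok = slope > tiny if expect_positive else slope < -tiny
        if not ok:
            msg = (f"{label} regression at percentile {g:g} has a "
                   f"{'non-positive' if expect_positive else 'non-negative'}"
                   f" slope: likely regime misassignment")
            if strict:
                raise FitError(msg)
            dropped.append((g, msg))
            continue
        rows.append({"percentile": g, "slope": slope,
                     "intercept": intercept, "r2": r2,
                     "x_intercept": -intercept / slope,
                     "n_temperatures": len(grp)})
    frame = pd.DataFrame(rows, columns=["percentile", "slope", "intercept",
                                        "r2", "x_intercept",
                                        "n_temperatures"])
    frame.attrs["dropped"] = dropped
    return frame


def fit_suboptimal(gr_table: pd.DataFrame, sub_temps: Sequence[float],
                   *, min_temps: int = 3, strict: bool = True
                   ) -> pd.DataFrame:
    """Per-percentile OLS in the sub-optimal region.

    Adds ``theta_cold`` = 1/slope per percentile; ``x_intercept`` is the
    percentile's implied base temperature (the shared T_base is read off
    the reference percentile's line by the pipeline).
    """
    frame = _per_percentile_fits(gr_table, sub_temps, expect_positive=True,
                                 min_temps=min_temps, strict=strict,
                                 label="sub-optimal")
    if frame.empty:
        raise FitError("no percentile could be fitted in the sub-optimal "
                       "region")
    frame["theta_cold"] = 1.0 / frame["slope"]
    return frame


def fit_supraoptimal(gr_table: pd.DataFrame, supra_temps: Sequence[float],
                     *, min_temps: int = 3, strict: bool = True
                     ) -> pd.DataFrame:
    """Per-percentile OLS in the supra-optimal region.

    ``T_c`` per percentile is the x-intercept; the shared theta_warm is
    -1/median(slope).
    """
    frame = _per_percentile_fits(gr_table, supra_temps, expect_positive=False,
                                 min_temps=min_temps, strict=strict,
                                 label="supra-optimal")
    if frame.empty:
        raise FitError("no percentile could be fitted in the supra-optimal "
                       "region")
    frame["T_c"] = frame["x_intercept"]
    return frame


def fit_threshold_distribution(values: Sequence[float],
                               percentiles: Sequence[float],
                               g_ref: float) -> tuple[float, float, dict]:
    """(median, SD) of a threshold from per-percentile estimates.

    Probit regression: the percentile g (percent of seeds sown) occupies
    rank g/g_ref within the viable population; regressing the estimates on
    Phi^-1(g/g_ref) gives the median as intercept and the SD as the
    magnitude of the slope (sign-corrected, since ceiling temperatures
    decrease with rank).
    """
    v = np.asarray(values, float)
    g = np.asarray(percentiles, float)
    if len(np.unique(g)) < 2:
        raise FitError("need >= 2 distinct percentiles for a threshold "
                       "distribution fit")
    if g_ref <= 0:
        raise FitError("reference percentage must be positive")
    q = g / g_ref
    if np.any(q <= 0) or np.any(q >= 1):
        raise FitError("percentiles must map to ranks strictly inside "
                       "(0, 1) of the viable population")
    x = norm.ppf(q)
    res = sm.OLS(v, sm.add_constant(x)).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    return intercept, abs(slope), {
        "slope": slope, "r2": float(res.rsquared), "n": int(len(v)),
        "sd_of_estimates": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}


# --------------------------------------------------------------- pipeline

def _default_percentiles(g_max: float) -> list[float]:
    """10, 20, ... up to the largest multiple of 10 strictly below G_max."""
    top = int(np.ceil(g_max / 10.0) - 1) * 10
    return [float(g) for g in range(10, top + 1, 10)]


def fit_pipeline(records: Sequence[GerminationRecord],
                 config: FitConfig = FitConfig()) -> ThermalTimeFit:
    """End-to-end fit: percentile times -> regime split -> regressions ->
    threshold distributions -> cardinal temperatures.

    Raises :class:`FitError` with a stage label on unusable data; a
    missing supra-optimal region yields NaN ceiling parameters with a
    warning rather than a failure.
    """
    from .dormancy import estimate_gmax

    if not records:
        raise FitError("input: no records")
    frame = pd.DataFrame([(r.temperature_C, r) for r in records],
                         columns=["temp", "rec"])
    if frame["temp"].nunique() < 4:
        raise FitError("input: records must span >= 4 temperatures")

    # G_max: plateau percentage at the most permissive temperature
    per_temp_gmax = {
        float(t): estimate_gmax(list(grp["rec"]), event=config.event)[0]
        for t, grp in frame.groupby("temp")}
    g_max = max(per_temp_gmax.values())
    if g_max <= 0:
        raise FitError("interpolate: no germination observed at any "
                       "temperature")

    percentiles = (list(config.percentiles) if config.percentiles is not None
                   else _default_percentiles(g_max))
    if not percentiles:
        raise FitError(f"interpolate: G_max estimate {g_max:.1f}% leaves no "
                       "usable percentile")

    gr_table = build_gr_table(records, percentiles, config.event)
    if gr_table.empty:
        raise FitError("interpolate: no percentile reached at any "
                       "temperature")

    sub_temps, supra_temps, ref_g = split_regimes(
        gr_table, config.reference_percentile)

    sub = fit_suboptimal(gr_table, sub_temps,
                         min_temps=config.min_temps_per_percentile,
                         strict=config.strict)
    ref_row = sub[sub["percentile"] == ref_g]
    if ref_row.empty:
        raise FitError(f"sub-optimal: reference percentile {ref_g:g} not "
                       "fittable")
    t_base = float(ref_row["x_intercept"].iloc[0])

    theta_50, sigma_theta, theta_diag = fit_threshold_distribution(
        sub["theta_cold"], sub["percentile"], g_max)

    diagnostics = {"per_temperature_gmax": per_temp_gmax,
                   "reference_percentile": ref_g,
                   "percentiles": percentiles,
                   "theta_probit": theta_diag,
                   "sub_dropped": sub.attrs.get("dropped", []),
                   "event": config.event}

    if supra_temps:
        supra = fit_supraoptimal(gr_table, supra_temps,
                                 min_temps=config.min_temps_per_percentile,
                                 strict=config.strict)
        t_c_50, sigma_tc, tc_diag = fit_threshold_distribution(
            supra["T_c"], supra["percentile"], g_max)
        theta_warm = float(-1.0 / supra["slope"].median())
        diagnostics["tc_probit"] = tc_diag
        diagnostics["supra_dropped"] = supra.attrs.get("dropped", [])
        t_opt = estimate_topt(t_base, theta_50, t_c_50, theta_warm)
        diagnostics["t_opt_reference_lines"] = _reference_line_intersection(
            sub, supra, ref_g)
    else:
        warnings.warn("no supra-optimal temperatures: ceiling parameters "
                      "not estimable", stacklevel=2)
        supra = pd.DataFrame(columns=["percentile", "slope", "intercept",
                                      "r2", "x_intercept", "n_temperatures",
                                      "T_c"])
        t_c_50 = sigma_tc = theta_warm = t_opt = float("nan")

    if np.isfinite(t_opt) and not t_base < t_opt < t_c_50:
        raise FitError(
            f"cardinal-temperature ordering violated: T_base={t_base:.2f}, "
            f"T_opt={t_opt:.2f}, T_c_50={t_c_50:.2f}")

    return ThermalTimeFit(
        T_base=t_base, theta_cold_50=theta_50, sigma_theta=sigma_theta,
        T_c_50=t_c_50, sigma_Tc=sigma_tc, theta_warm=theta_warm,
        T_opt=t_opt, g_max_estimate=g_max,
        sub_regressions=sub, supra_regressions=supra,
        diagnostics=diagnostics)


def _reference_line_intersection(sub: pd.DataFrame, supra: pd.DataFrame,
                                 ref_g: float) -> float:
    """Crossing temperature of the two reference-percentile lines
    (diagnostic alternative to the median-parameter T_opt)."""
    s = sub[sub["percentile"] == ref_g]
    w = supra[supra["percentile"] == ref_g]
    if s.empty or w.empty:
        return float("nan")
    a1, b1 = float(s["slope"].iloc[0]), float(s["intercept"].iloc[0])
    a2, b2 = float(w["slope"].iloc[0]), float(w["intercept"].iloc[0])
    return (b2 - b1) / (a1 - a2)
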