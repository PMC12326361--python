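"""Extrapolation of partition measurement series to infinite dilution.

Two data-reduction routes yield the octanol-water partition coefficient
K_OW of an ionizable solute from a series of biphasic measurements:

Method 1 (pH extrapolation)
    Plot log D against the measured aqueous pH, fit a line, and read it
    off at pH 7 - the pH the aqueous phase attains at zero solute
    concentration. The value at pH 7 is log D_OW; the ionization
    correction at pH 7 then converts it to log K_OW.

Method 2 (concentration extrapolation)
    Convert each log D to log P with that measurement's own pH, fit
    log P against the overall solute concentration, and take the
    intercept at zero concentration as log K_OW.

For neutral solutes log D equals log P and a plain log P-vs-concentration
intercept (:func:`fit_logp_vs_conc`) is the only route needed.

Both methods are exact when log D is genuinely linear in the fitted
abscissa, which holds in the dilute, strongly-ionized regime; at higher
concentrations the log D-vs-pH trend curves and the two methods can
disagree - their difference is itself a useful diagnostic.

Fits are ordinary least squares by default; inverse-variance weighting
is applied only when replicate standard deviations accompany the data.
Standard errors reflect fit (residual) uncertainty only - pKa
uncertainty is not propagated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from .chem_core import Solute, UnsupportedSoluteError
from .partition import MeasurementSeries, logp_from_logd

__all__ = [
    "KowEstimate",
    "LinearFitResult",
    "InsufficientDataError",
    "DegenerateFitError",
    "linear_fit",
    "fit_method1",
    "fit_method2",
    "fit_logp_vs_conc",
    "EXTRAPOLATION_PH",
]

#: pH of the aqueous phase at zero solute concentration.
EXTRAPOLATION_PH: float = 7.0


class InsufficientDataError(ValueError):
    """Too few (distinct) data points for a meaningful fit."""


class DegenerateFitError(ValueError):
    """The fit abscissa carries no variance."""


class LinearFitResult(NamedTuple):
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def prediction_se(self, x: float, xs: Sequence[float]) -> float:
        """Standard error of the fitted mean response at ``x``."""
        xs = np.asarray(xs, dtype=float)
        sxx = float(np.sum((xs - xs.mean()) ** 2))
        # residual standard deviation recovered from se_slope
        s = self.se_slope * math.sqrt(sxx)
        return s * math.sqrt(1.0 / len(xs) + (x - xs.mean()) ** 2 / sxx)


@dataclass(frozen=True)
class KowEstimate:
    """An extrapolated partition/distribution coefficient with diagnostics.

    ``log_value`` is the headline log K_OW (or log P for the
    neutral-solute route). For Method 1, ``intermediate_logDow`` records
    the log D_OW read off at pH 7 before the ionization conversion, so
    both readings remain available.
    """

    method: str  # "ph_extrapolation" | "conc_extrapolation" | "activity_model"
    log_value: float
    std_error: float
    fit_slope: float
    fit_intercept: float
    n_points: int
    r_squared: float
    intermediate_logDow: Optional[float] = None
    extrapolation_span_warning: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a fitted estimate needs >= 3 points")
        if self.std_error < 0.0:
            raise ValueError("std_error must be >= 0")

    def to_record(self) -> dict:
        return asdict(self)


def linear_fit(
    xs: Sequence[float],
    ys: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> LinearFitResult:
    """(Optionally weighted) ordinary least-squares straight-line fit.

    ``weights`` are relative precision weights (typically inverse
    variances from replicate standard deviations). Standard errors are
    derived from the residual variance with n - 2 degrees of freedom.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all abscissa values identical")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0.0):
            raise ValueError("weights must be positive and match the data length")

    wsum = w.sum()
    xbar = float(np.sum(w * x) / wsum)
    ybar = float(np.sum(w * y) / wsum)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    sxy = float(np.sum(w * (x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    dof = n - 2
    s2 = float(np.sum(w * resid**2) / dof)
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / wsum + xbar**2 / sxx))
    syy = float(np.sum(w * (y - ybar) ** 2))
    r_squared = 1.0 - float(np.sum(w * resid**2)) / syy if syy > 0.0 else 1.0
    return LinearFitResult(slope, intercept, se_slope, se_intercept, r_squared, n)


def _series_logd_ph(series: MeasurementSeries):
    xs_ph = [m.pH_aq for m in series.measurements]
    logd = [m.logD for m in series.measurements]
    return xs_ph, logd


def _conc_weights(series: MeasurementSeries) -> Optional[List[float]]:
    """Inverse-variance weights for logD from replicate phase-conc sds.

    Var(logD) ~ [(sd_org/c_org)^2 + (sd_aq/c_aq)^2] / ln(10)^2 by error
    propagation; weights are used only when every measurement carries both
    standard deviations.
    """
    sds = [
        (m.c_org_sd, m.c_aq_sd, m.c_org, m.c_aq) for m in series.measurements
    ]
    if any(so is None or sa is None or so <= 0 or sa <= 0 for so, sa, _, _ in sds):
        return None
    ln10_sq = math.log(10.0) ** 2
    return [
        ln10_sq / ((so / co) ** 2 + (sa / ca) ** 2) for so, sa, co, ca in sds
    ]


def fit_method1(series: MeasurementSeries) -> KowEstimate:
    """pH-extrapolation route to log K_OW (ionizable solutes).

    Fits log D = a*pH + b, evaluates the line at pH 7 to obtain
    log D_OW, then applies the ionization correction at pH 7 to convert
    to log K_OW. A span warning is set when pH 7 lies farther from the
    nearest data point than the whole pH range of the data, i.e. when
    the read-off is a long extrapolation.
    """
    solute = series.solute
    if not solute.is_ionizable:
        raise UnsupportedSoluteError(
            f"{solute.name} is neutral: use fit_logp_vs_conc (log D = log P, "
            "and the pH of the aqueous phase carries no information)"
        )
    if len(series) < 3:
        raise InsufficientDataError(f"need >= 3 measurements, got {len(series)}")
    xs, ys = _series_logd_ph(series)
    if max(xs) == min(xs):
        raise DegenerateFitError("all measurements share the same pH")
    span = max(xs) - min(xs)
    if span <= 0.1:
        warnings.warn(
            f"pH span {span:.3g} <= 0.1 units: the pH-extrapolation fit is "
            "poorly conditioned",
            stacklevel=2,
        )
    fit = linear_fit(xs, ys, weights=_conc_weights(series))
    log_dow = fit.predict(EXTRAPOLATION_PH)
    log_kow = logp_from_logd(log_dow, EXTRAPOLATION_PH, solute)
    nearest = min(abs(EXTRAPOLATION_PH - x) for x in xs)
    return KowEstimate(
        method="ph_extrapolation",
        log_value=log_kow,
        std_error=fit.prediction_se(EXTRAPOLATION_PH, xs),
        fit_slope=fit.slope,
        fit_intercept=fit.intercept,
        n_points=fit.n,
        r_squared=fit.r_squared,
        intermediate_logDow=log_dow,
        extrapolation_span_warning=nearest > span,
    )


def fit_method2(series: MeasurementSeries) -> KowEstimate:
    """Concentration-extrapolation route to log K_OW (ionizable solutes).

    Converts each log D to log P with that measurement's own pH, fits
    log P = a*c_total + b, and returns the zero-concentration intercept
    as log K_OW.
    """
    solute = series.solute
    if not solute.is_ionizable:
        raise UnsupportedSoluteError(
            f"{solute.name} is neutral: use fit_logp_vs_conc"
        )
    if len(series) < 3:
        raise InsufficientDataError(f"need >= 3 measurements, got {len(series)}")
    cs = [m.c_total for m in series.measurements]
    if len(set(cs)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct overall concentrations, got {len(set(cs))}"
        )
    logp = [
        logp_from_logd(m.logD, m.pH_aq, solute) for m in series.measurements
    ]
    fit = linear_fit(cs, logp, weights=_conc_weights(series))
    nearest = min(cs)
    span = max(cs) - min(cs)
    return KowEstimate(
        method="conc_extrapolation",
        log_value=fit.intercept,
        std_error=fit.se_intercept,
        fit_slope=fit.slope,
        fit_intercept=fit.intercept,
        n_points=fit.n,
        r_squared=fit.r_squared,
        intermediate_logDow=None,
        extrapolation_span_warning=nearest > span,
    )


def fit_logp_vs_conc(series: MeasurementSeries) -> KowEstimate:
    """Zero-concentration intercept of log P for neutral solutes.

    For a neutral solute the measured ratio *is* log P, so the intercept
    of log P vs overall concentration is log K_OW directly. Ionizable
    solutes are accepted with a warning (their log D values are first
    converted to log P using each measurement's pH), but the dedicated
    Method 1/2 entry points are preferred.
    """
    solute = series.solute
    if len(series) < 3:
        raise InsufficientDataError(f"need >= 3 measurements, got {len(series)}")
    cs = [m.c_total for m in series.measurements]
    if len(set(cs)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct overall concentrations, got {len(set(cs))}"
        )
    if solute.is_ionizable:
        warnings.warn(
            f"{solute.name} is ionizable: converting log D to log P per "
            "measurement; prefer fit_method1/fit_method2",
            stacklevel=2,
        )
        ys = [logp_from_logd(m.logD, m.pH_aq, solute) for m in series.measurements]
    else:
        ys = [m.logD for m in series.measurements]
    fit = linear_fit(cs, ys, weights=_conc_weights(series))
    return KowEstimate(
        method="conc_extrapolation",
        log_value=fit.intercept,
        std_error=fit.se_intercept,
        fit_slope=fit.slope,
        fit_intercept=fit.intercept,
        n_points=fit.n,
        r_squared=fit.r_squared,
        intermediate_logDow=None,
        extrapolation_span_warning=min(cs) > (max(cs) - min(cs)),
    )
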