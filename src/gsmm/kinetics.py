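"""Growth and substrate-consumption rate estimation from time series.

Cell dry weight (CDW, g/L) is obtained from optical density as
CDW = 0.36 * OD600. Growth curves are fitted with the logistic function

    X(t) = K / (1 + ((K - X0)/X0) * exp(-r t))

(K carrying capacity in g/L, r rate constant in 1/h, X0 initial CDW in
g/L), and the specific growth rate is taken analytically from the fitted
curve, mu(t) = (dX/dt)/X = r (1 - X(t)/K), so that

    mu_max = r (1 - X0/K),

attained at t = 0 where X is smallest. Substrate consumption uses the same
logistic machinery on the mirrored (decreasing) series, differentiated
analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

OD_TO_CDW = 0.36  # g/L per OD600 unit


class FitError(RuntimeError):
    """The nonlinear fit failed or is singular on the given data."""


def relative_deficit(predicted: float, measured: float) -> float:
    """Percent shortfall of a predicted rate vs the measured one, one decimal.

    100 * (measured - predicted) / measured; negative when the prediction
    overshoots.
    """
    if measured == 0:
        raise ValueError("measured value must be nonzero")
    return round(100.0 * (measured - predicted) / measured, 1)


def od_to_cdw(od600):
    """Convert OD600 readings to cell dry weight in g/L (CDW = 0.36 * OD)."""
    od = np.asarray(od600, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD600 readings must be non-negative")
    out = OD_TO_CDW * od
    return float(out) if np.isscalar(od600) else out


def logistic(t, K: float, r: float, X0: float):
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - X0) / X0) * np.exp(-r * t))


def logistic_rate(t, K: float, r: float, X0: float):
    """dX/dt of the logistic curve, analytically."""
    x = logistic(t, K, r, X0)
    return r * x * (1.0 - x / K)


@dataclass
class GrowthCurveFit:
    K: float  # carrying capacity, g/L
    r: float  # logistic rate constant, 1/h
    X0: float  # initial CDW, g/L
    rss: float
    mu_max: float  # 1/h

    def predict(self, t):
        return logistic(t, self.K, self.r, self.X0)

    def mu(self, t):
        """Specific growth rate mu(t) = r (1 - X(t)/K) along the fit."""
        return self.r * (1.0 - self.predict(t) / self.K)


def _fit_logistic_ls(times, values) -> tuple[float, float, float, float]:
    """Multi-start least squares; deterministic given the data."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)

    def residuals(p):
        K, r, X0 = p
        return logistic(t, K, r, X0) - x

    xmax, xmin = float(x.max()), float(x.min())
    span = max(t[-1] - t[0], 1e-9)
    starts = []
    for k_scale in (1.05, 1.5, 3.0):
        for r0 in (0.5 / span * 10.0, 1.0 / span * 10.0, 4.0 / span * 10.0):
            starts.append((max(xmax * k_scale, 1e-6), r0, max(xmin, 1e-6 * xmax, 1e-9)))
    best = None
    lower = [1e-12, 1e-12, 1e-12]
    upper = [np.inf, np.inf, np.inf]
    for p0 in starts:
        try:
            res = least_squares(
                residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[3] - 1e-15:
            K, r, X0 = (float(v) for v in res.x)
            best = (K, r, X0, rss)
    if best is None:
        raise FitError("logistic fit failed from every start")
    return best


def fit_logistic(times, cdw) -> GrowthCurveFit:
    """Least-squares logistic fit of a growth curve.

    Requires at least four points with strictly increasing times. A
    non-increasing series draws a warning (the logistic model cannot
    represent decline); a flat series is an error because K and X0 are then
    unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(cdw, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(x) < 1e-12:
        raise FitError("constant series: logistic parameters unidentifiable")
    if x[-1] <= x[0]:
        import warnings

        warnings.warn("series is non-increasing; logistic fit may be meaningless")
    K, r, X0, rss = _fit_logistic_ls(t, x)
    if not (K > X0 > 0) or r <= 0:
        raise FitError(
            f"singular fit: K={K:.4g}, r={r:.4g}, X0={X0:.4g} violate K > X0 > 0, r > 0"
        )
    mu_max = r * (1.0 - X0 / K)
    return GrowthCurveFit(K=K, r=r, X0=X0, rss=rss, mu_max=mu_max)


@dataclass
class ConsumptionFit:
    """Smoothed consumption-rate curve for a depleting substrate."""

    times: np.ndarray
    rate: np.ndarray  # dC/dt, g/L/h (non-positive for depletion)
    specific_rate: np.ndarray | None  # (dC/dt)/CDW, 1/h scaled by g/g
    max_specific_rate: float | None
    C_start: float
    C_end: float


def _fit_mirrored_logistic(times, conc) -> tuple[float, float, float, float]:
    """Fit C(t) = c_top - logistic(t; K, r, X0); returns (K, r, X0, c_top).

    The mirrored-logistic family covers depletion curves that level off
    above zero, since the plateau offset c_top - K is free.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)

    def residuals(p):
        K, r, X0, c_top = p
        return (c_top - logistic(t, K, r, X0)) - c

    drop = float(c.max() - c.min())
    span = max(t[-1] - t[0], 1e-9)
    best = None
    for k_scale in (1.05, 1.5, 3.0):
        for r0 in (5.0 / span, 10.0 / span, 40.0 / span):
            K0 = max(drop * k_scale, 1e-6)
            p0 = (K0, r0, max(1e-3 * K0, 1e-9), float(c.max()) + 1e-3 * K0)
            try:
                res = least_squares(
                    residuals, p0,
                    bounds=([1e-12, 1e-12, 1e-12, -np.inf],
                            [np.inf, np.inf, np.inf, np.inf]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[4] - 1e-15:
                best = (*(float(v) for v in res.x), rss)
    if best is None:
        raise FitError("mirrored logistic fit failed from every start")
    return best[0], best[1], best[2], best[3]


def consumption_rate(times, concentrations, cdw=None) -> ConsumptionFit:
    """Fit a mirrored logistic to a depletion series and differentiate it.

    The decreasing concentration series is fitted as a constant minus a
    logistic (the same sigmoid family as the growth fit, mirrored), and
    the analytic derivative is negated back. When a concurrent CDW series
    is supplied the specific rate divides dC/dt by CDW(t), and the maximum
    specific rate is reported as the largest magnitude of that ratio.
    A constant series short-circuits to a zero rate.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(c) < 1e-12:
        zero = np.zeros_like(t)
        spec = zero if cdw is not None else None
        return ConsumptionFit(t, zero, spec, 0.0 if cdw is not None else None,
                              float(c[0]), float(c[-1]))
    c_start, c_end = float(c[0]), float(c[-1])
    K, r, X0, _ = _fit_mirrored_logistic(t, c)
    rate = -logistic_rate(t, K, r, X0)  # non-positive for depletion
    specific = None
    max_specific = None
    if cdw is not None:
        w = np.asarray(cdw, dtype=float)
        if w.shape != t.shape:
            raise ValueError("cdw series length must match times")
        if np.any(w <= 0):
            raise ValueError("cdw values must be positive for specific rates")
        specific = rate / w
        max_specific = float(np.max(np.abs(specific)))
    return ConsumptionFit(t, rate, specific, max_specific, c_start, c_end)
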