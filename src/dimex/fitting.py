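"""Rate extraction: exponential tail fits and the linear law k_off = k0 + k1*c.

The exchange decay has a documented fast initial transient (departure of
the minority of singly bound dimers present at saturation), so the default
fit window opens only after 5% of the initial tagged signal has decayed
(or after an explicit ``t_start``, whichever is later) and closes where
the averaged signal drops below a floor that keeps the log well defined.
Standard errors of fitted off-rates come from bootstrap resampling of
replicates — replicate scatter, not residuals alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from dimex.lattice import ExchangeTrace

__all__ = ["ExponentialFit", "RateFit", "average_traces", "fit_exponential", "fit_linear_rate"]

_TRANSIENT_DECAY_FRACTION = 0.05
_MIN_POINTS = 10


def average_traces(traces: Sequence[ExchangeTrace]) -> pd.DataFrame:
    """Replicate-mean time series of an exchange experiment."""
    if not traces:
        raise ValueError("no traces given")
    times = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("traces must share a common time grid")
    data = {
        "time": times,
        "n_B": np.mean([tr.n_B for tr in traces], axis=0),
        "n_B_total": np.mean([tr.n_B_total for tr in traces], axis=0),
        "n_singly": np.mean([tr.n_singly for tr in traces], axis=0),
        "n_singly_tagged": np.mean([tr.n_singly_tagged for tr in traces], axis=0),
        "n_tagged_dimers": np.mean([tr.n_tagged_dimers for tr in traces], axis=0),
    }
    return pd.DataFrame(data)


@dataclass
class ExponentialFit:
    """Fitted exponential decay rate of one exchange experiment."""

    k_off: float
    se: float
    r_squared: float
    window: tuple[float, float]
    n_points: int


@dataclass
class RateFit:
    """Linear concentration dependence of fitted off-rates."""

    c_values: np.ndarray
    k_off_values: np.ndarray
    k_off_se: np.ndarray
    k0_hat: float
    k0_se: float
    k1_hat: float
    k1_se: float
    r_squared: float
    fit_windows: list = field(default_factory=list)

    def predict(self, c) -> np.ndarray:
        return self.k0_hat + self.k1_hat * np.asarray(c, dtype=float)

    def to_record(self) -> dict:
        return {
            "c": [float(x) for x in self.c_values],
            "k_off": [float(x) for x in self.k_off_values],
            "se": [float(x) for x in self.k_off_se],
            "k0": float(self.k0_hat),
            "k0_se": float(self.k0_se),
            "k1": float(self.k1_hat),
            "k1_se": float(self.k1_se),
            "r2": float(self.r_squared),
        }


def _default_window(times: np.ndarray, nb: np.ndarray, t_start: Optional[float]) -> tuple[float, float]:
    nb0 = nb[0]
    decayed = np.nonzero(nb <= (1.0 - _TRANSIENT_DECAY_FRACTION) * nb0)[0]
    auto_start = times[decayed[0]] if decayed.size else times[-1]
    start = max(auto_start, t_start) if t_start is not None else auto_start
    return float(start), float(times[-1])


def _loglinear_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope of log(y) on t plus R^2 of the log-linear fit."""
    ly = np.log(y)
    slope, intercept = np.polyfit(t, ly, 1)
    resid = ly - (slope * t + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def fit_exponential(
    traces: Sequence[ExchangeTrace] | pd.DataFrame,
    window: Optional[tuple[float, float]] = None,
    t_start: Optional[float] = None,
    n_bootstrap: int = 200,
    rng: Optional[np.random.Generator] = None,
    column: str = "n_B",
) -> ExponentialFit:
    """Off-rate from the exponential tail of the mean tagged-monomer decay.

    Fits the least-squares slope of ``log(n_B/n_B(0))`` against ``t`` in
    the window.  When a list of replicate traces is given, the SE is the
    bootstrap (``n_bootstrap`` resamples over replicates) spread of the
    refitted rate; on an averaged frame the SE falls back to the
    residual-based slope error.
    """
    replicate_curves = None
    if isinstance(traces, pd.DataFrame):
        frame = traces
    else:
        frame = average_traces(traces)
        replicate_curves = np.array([getattr(tr, column) for tr in traces], dtype=float)
    times = frame["time"].to_numpy(dtype=float)
    nb = frame[column].to_numpy(dtype=float)

    if window is None:
        window = _default_window(times, nb, t_start)
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if np.any(nb[mask] <= 0):
        warnings.warn("fit window reaches zero signal; trimming trailing zeros")
        good = np.nonzero(mask & (nb > 0))[0]
        mask = np.zeros_like(mask)
        if good.size:
            keep = good[good < (np.nonzero(nb <= 0)[0].min() if np.any(nb <= 0) else good[-1] + 1)]
            mask[keep] = True
    if mask.sum() < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} positive points in the fit window")

    t_fit, y_fit = times[mask], nb[mask]
    slope, r2 = _loglinear_slope(t_fit, y_fit)
    k_off = -slope

    if replicate_curves is not None and replicate_curves.shape[0] > 1:
        rng = rng if rng is not None else np.random.default_rng(0)
        n_rep = replicate_curves.shape[0]
        boots = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, n_rep, size=n_rep)
            mean_curve = replicate_curves[pick].mean(axis=0)[mask]
            if np.any(mean_curve <= 0):
                continue
            s, _ = _loglinear_slope(t_fit, mean_curve)
            boots.append(-s)
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    else:
        # residual-based slope SE of the log-linear regression
        ly = np.log(y_fit)
        n = t_fit.size
        resid = ly - np.polyval(np.polyfit(t_fit, ly, 1), t_fit)
        sxx = np.sum((t_fit - t_fit.mean()) ** 2)
        se = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1) / sxx))

    return ExponentialFit(
        k_off=float(k_off), se=se, r_squared=float(r2),
        window=(float(lo), float(hi)), n_points=int(mask.sum()),
    )


def fit_linear_rate(
    c_values: Sequence[float],
    k_off_values: Sequence[float],
    k_off_se: Optional[Sequence[float]] = None,
    weighted: bool = True,
    fit_windows: Optional[list] = None,
) -> RateFit:
    """Weighted least squares of ``k_off`` on ``c`` -> (k0, k1).

    Weights are ``1/SE^2`` from the replicate-bootstrap errors of the
    per-concentration fits; an ordinary fit is available with
    ``weighted=False`` or when no SEs are given.
    """
    c = np.asarray(c_values, dtype=float)
    k = np.asarray(k_off_values, dtype=float)
    if c.size < 3:
        raise ValueError("need >= 3 concentrations for the linear rate law")
    if k_off_se is None:
        se_arr = np.full(c.size, np.nan)
        weighted = False
    else:
        se_arr = np.asarray(k_off_se, dtype=float)
    x = sm.add_constant(c)
    if weighted:
        if np.any(~np.isfinite(se_arr)) or np.any(se_arr <= 0):
            raise ValueError("weighted fit requires finite positive SEs")
        model = sm.WLS(k, x, weights=1.0 / se_arr**2)
    else:
        model = sm.OLS(k, x)
    res = model.fit()
    return RateFit(
        c_values=c,
        k_off_values=k,
        k_off_se=se_arr,
        k0_hat=float(res.params[0]),
        k0_se=float(res.bse[0]),
        k1_hat=float(res.params[1]),
        k1_se=float(res.bse[1]),
        r_squared=float(res.rsquared),
        fit_windows=fit_windows or [],
    )
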