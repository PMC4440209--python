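"""Hyperbolic critical-power model.

The power-duration relationship for severe-intensity exercise is modelled
as a hyperbola: sustaining power P above the critical power CP exhausts a
finite anaerobic work capacity AWC, so the time to exhaustion is

    tlim = AWC / (P - CP)

with CP in watts, AWC in joules and tlim in seconds. CP is the asymptote:
power at or below CP is sustainable without (model) fatigue. Two canonical
estimators are provided: ordinary least squares on the linearised form
P = CP + AWC * (1/t), and direct nonlinear least squares on the hyperbola.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CPParameters",
    "PowerTimeSeries",
    "predict_tlim",
    "fit_linearized",
    "fit_hyperbolic",
    "SustainablePowerError",
]

#: Trial-duration window (s) the protocol targets; trials outside it make
#: the two-parameter hyperbola a poor description and trigger a warning.
TLIM_WINDOW = (120.0, 600.0)


class SustainablePowerError(ValueError):
    """Raised when a prediction is requested at P <= CP (no exhaustion)."""


@dataclass(frozen=True)
class CPParameters:
    """Fitted parameters of the power-duration hyperbola.

    ``anaerobic_work_capacity`` is stored in joules; table-style output in
    kJ is an explicit I/O conversion. ``residual_sum_squares`` is in the
    fitted variable's units squared: W^2 for the linearised fit (residuals
    in power), s^2 for the hyperbolic fit (residuals in time).
    """

    critical_power: float          # W
    anaerobic_work_capacity: float  # J
    fit_method: str = "hyperbolic"
    residual_sum_squares: float = float("nan")

    def __post_init__(self) -> None:
        if not self.critical_power > 0:
            raise ValueError("critical_power must be > 0")
        if not self.anaerobic_work_capacity > 0:
            raise ValueError("anaerobic_work_capacity must be > 0")


@dataclass(frozen=True)
class PowerTimeSeries:
    """(power W, time-to-exhaustion s) pairs, one per exhaustive trial."""

    power: tuple[float, ...]
    time_limit: tuple[float, ...]
    warn_window: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "power", tuple(float(v) for v in self.power))
        object.__setattr__(self, "time_limit", tuple(float(v) for v in self.time_limit))
        p = np.asarray(self.power, dtype=float)
        t = np.asarray(self.time_limit, dtype=float)
        if p.shape != t.shape or p.ndim != 1:
            raise ValueError("power and time_limit must be 1-D and equal length")
        if p.size < 2:
            raise ValueError("at least two trials are required")
        if (p <= 0).any() or (t <= 0).any():
            raise ValueError("all powers and time limits must be > 0")
        if np.unique(p).size < 2:
            raise ValueError("at least two distinct power values are required")
        if self.warn_window and ((t < TLIM_WINDOW[0]) | (t > TLIM_WINDOW[1])).any():
            warnings.warn(
                f"trial durations outside the {TLIM_WINDOW[0]:.0f}-"
                f"{TLIM_WINDOW[1]:.0f} s window weaken the hyperbolic model",
                stacklevel=3,
            )

    @property
    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.power, dtype=float),
            np.asarray(self.time_limit, dtype=float),
        )


def predict_tlim(params: CPParameters, power: float) -> float:
    """Predicted time to exhaustion (s) at a constant power output (W)."""
    if power <= params.critical_power:
        raise SustainablePowerError(
            f"power {power:g} W does not exceed CP {params.critical_power:g} W: "
            "sustainable without fatigue, no finite time limit"
        )
    return params.anaerobic_work_capacity / (power - params.critical_power)


def fit_linearized(series: PowerTimeSeries) -> CPParameters:
    """OLS of power on inverse time: P = CP + AWC * (1/t).

    The intercept estimates CP (W) and the slope AWC (J).
    """
    p, t = series.arrays
    x = 1.0 / t
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    cp, awc = float(coef[0]), float(coef[1])
    rss = float(((p - design @ coef) ** 2).sum())
    if cp <= 0 or awc <= 0:
        raise ValueError(
            f"linearised fit produced non-physical parameters "
            f"(CP={cp:.4g} W, AWC={awc:.4g} J)"
        )
    return CPParameters(cp, awc, fit_method="linearized", residual_sum_squares=rss)


def fit_hyperbolic(
    series: PowerTimeSeries,
    init: CPParameters | None = None,
    max_nfev: int = 2000,
) -> CPParameters:
    """Nonlinear least squares on t = AWC / (P - CP), residuals in seconds.

    Initialised from the linearised fit when ``init`` is omitted. CP is
    constrained below the smallest observed power (the hyperbola is
    undefined otherwise); an infeasible initial CP is projected into the
    feasible region with a warning.
    """
    p, t = series.arrays
    p_min = float(p.min())
    cp_hi = p_min * (1.0 - 1e-6)

    if init is None:
        try:
            start = fit_linearized(series)
            cp0, awc0 = start.critical_power, start.anaerobic_work_capacity
        except ValueError:
            cp0, awc0 = 0.5 * p_min, float(np.median((p - 0.5 * p_min) * t))
    else:
        cp0, awc0 = init.critical_power, init.anaerobic_work_capacity
    if cp0 >= cp_hi:
        warnings.warn(
            f"initial CP {cp0:g} W is not below the minimum observed power "
            f"{p_min:g} W; projecting into the feasible region",
            stacklevel=2,
        )
        cp0 = 0.9 * cp_hi

    def residuals(theta: np.ndarray) -> np.ndarray:
        cp, awc = theta
        return t - awc / (p - cp)

    sol = least_squares(
        residuals,
        x0=[cp0, max(awc0, 1e-6)],
        bounds=([1e-9, 1e-9], [cp_hi, np.inf]),
        max_nfev=max_nfev,
    )
    if not sol.success:
        raise RuntimeError(
            f"hyperbolic fit did not converge: {sol.message}; "
            f"best iterate CP={sol.x[0]:.6g} W, AWC={sol.x[1]:.6g} J"
        )
    rss = float((sol.fun**2).sum())
    return CPParameters(
        float(sol.x[0]), float(sol.x[1]),
        fit_method="hyperbolic", residual_sum_squares=rss,
    )
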