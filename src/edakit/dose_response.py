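"""Concentration-response modelling for the yeast estrogen screen (YES).

Fits the four-parameter logistic (4PL)

    r(c) = floor + (ceiling - floor) / (1 + (ec50 / c)**hill)

to pooled replicate dilution series, derives effect concentrations
(EC10, EC50, ...) with first-order (delta-method) 95% confidence
intervals, and converts a sample's dilution-response curve into a
17beta-estradiol equivalent (E2-EQ) against a fitted positive-control
curve.

Internally the curve is parameterized in (floor, ceiling, log(ec50),
hill) so that the dose scale enters linearly in log space; effect
concentrations are computed analytically from the inverse 4PL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .types import PlateSeries, ValueWithCI, as_series_list

__all__ = ["DoseResponseFit", "E2Equivalent", "fit_4pl", "ec_level", "e2_equivalents"]


@dataclass
class DoseResponseFit:
    """A fitted 4PL curve with parameter covariance.

    ``cov`` is the covariance of (floor, ceiling, log_ec50, hill) from
    the least-squares fit; ``dof`` the residual degrees of freedom used
    for the t-quantile of confidence intervals.
    """

    floor: float
    ceiling: float
    ec50: float
    hill: float
    cov: np.ndarray
    dof: int
    residual_ss: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.ceiling > self.floor:
            raise ValueError("ceiling must exceed floor")
        if not (self.ec50 > 0 and self.hill > 0):
            raise ValueError("ec50 and hill must be positive")

    @property
    def log_ec50(self) -> float:
        return math.log(self.ec50)

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return _model4pl(np.asarray(conc, dtype=float),
                         self.floor, self.ceiling, self.log_ec50, self.hill)

    def inverse(self, response: float) -> float:
        """Concentration at which the fitted curve attains ``response``."""
        span = self.ceiling - self.floor
        y = (response - self.floor) / span
        if not 0 < y < 1:
            raise ValueError("response outside the open (floor, ceiling) range")
        return self.ec50 * (y / (1 - y)) ** (1.0 / self.hill)


@dataclass(frozen=True)
class E2Equivalent:
    """Estradiol-equivalent concentration of a sample (ng/L)."""

    e2_eq: ValueWithCI

    def __post_init__(self) -> None:
        if self.e2_eq.value < 0:
            raise ValueError("E2-EQ must be non-negative")


def _model4pl(c: np.ndarray, floor: float, ceiling: float,
              log_ec50: float, hill: float) -> np.ndarray:
    # (ec50/c)**hill written via logs for numerical stability
    return floor + (ceiling - floor) / (1.0 + np.exp(hill * (log_ec50 - np.log(c))))


def _pool(series: PlateSeries | Sequence[PlateSeries]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in as_series_list(series):
        xs.append(s.concentrations)
        ys.append(s.responses)
    return np.concatenate(xs), np.concatenate(ys)


def fit_4pl(series: PlateSeries | Sequence[PlateSeries]) -> DoseResponseFit:
    """Weighted least-squares 4PL fit to replicate dilution series.

    Reporter-assay noise scales with the signal, so residuals are
    weighted by 1/response (a constant-CV error model); the stored
    ``residual_ss`` is the weighted (relative-residual) sum of squares.
    Starting values are a fixed heuristic (floor = min response,
    ceiling = max response, ec50 = geometric mid-dose, hill = 1) so the
    fit is deterministic given the data.

    Raises ``ValueError`` for fewer than 5 distinct concentrations or a
    flat response, and ``RuntimeError`` on non-convergence.
    """
    conc, resp = _pool(series)
    if np.unique(conc).size < 5:
        raise ValueError("at least 5 distinct concentrations are required")
    if np.allclose(resp, resp[0]):
        raise ValueError("no response: all responses equal")

    p0 = (
        float(resp.min()),
        float(resp.max()),
        float(np.log(np.sqrt(conc.min() * conc.max()))),
        1.0,
    )
    try:
        popt, pcov = optimize.curve_fit(
            _model4pl, conc, resp, p0=p0, sigma=resp, maxfev=20000, method="lm"
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc

    floor, ceiling, log_ec50, hill = (float(v) for v in popt)
    if ceiling < floor:  # reflected solution: swap and flip the slope
        floor, ceiling, hill = ceiling, floor, -hill
    if hill <= 0 or ceiling <= floor:
        raise RuntimeError("4PL fit converged to a non-sigmoidal solution")

    resid = (resp - _model4pl(conc, floor, ceiling, log_ec50, hill)) / resp
    dof = max(conc.size - 4, 1)
    return DoseResponseFit(
        floor=floor,
        ceiling=ceiling,
        ec50=float(np.exp(log_ec50)),
        hill=hill,
        cov=np.asarray(pcov, dtype=float),
        dof=dof,
        residual_ss=float(resid @ resid),
        n_points=int(conc.size),
    )


def ec_level(fit: DoseResponseFit, level: float) -> ValueWithCI:
    """Effect concentration at ``level`` percent of the fitted span.

    EC_p solves the inverse 4PL analytically:

        EC_p = ec50 * (p / (100 - p))**(1 / hill)

    The 95% CI comes from the first-order delta method on
    log(EC_p) = log_ec50 + log(p/(100-p)) / hill using the parameter
    covariance and a t-quantile at the fit's residual degrees of
    freedom.
    """
    if not 0 < level < 100:
        raise ValueError("effect level must lie in the open interval (0, 100)")
    log_ratio = math.log(level / (100.0 - level))
    log_ecp = fit.log_ec50 + log_ratio / fit.hill
    ecp = math.exp(log_ecp)

    # gradient of log(EC_p) wrt (floor, ceiling, log_ec50, hill)
    grad = np.array([0.0, 0.0, 1.0, -log_ratio / fit.hill**2])
    var_log = float(grad @ fit.cov @ grad)
    var_log = max(var_log, 0.0)
    tq = stats.t.ppf(0.975, fit.dof)
    half = tq * ecp * math.sqrt(var_log)
    return ValueWithCI(ecp, half)


def _inverse_ci(fit: DoseResponseFit, response: float) -> ValueWithCI:
    """Delta-method CI of the inverse 4PL at a fixed response level."""
    x0 = fit.inverse(response)

    params = np.array([fit.floor, fit.ceiling, fit.log_ec50, fit.hill])

    def inv_at(p: np.ndarray) -> float:
        floor, ceiling, log_ec50, hill = p
        y = (response - floor) / (ceiling - floor)
        y = min(max(y, 1e-12), 1 - 1e-12)
        return math.exp(log_ec50) * (y / (1 - y)) ** (1.0 / hill)

    grad = np.zeros(4)
    for k in range(4):
        h = max(abs(params[k]) * 1e-6, 1e-8)
        up, dn = params.copy(), params.copy()
        up[k] += h
        dn[k] -= h
        grad[k] = (inv_at(up) - inv_at(dn)) / (2 * h)
    var = float(grad @ fit.cov @ grad)
    var = max(var, 0.0)
    tq = stats.t.ppf(0.975, fit.dof)
    return ValueWithCI(x0, tq * math.sqrt(var))


def e2_equivalents(
    sample_series: PlateSeries | Sequence[PlateSeries],
    pc_fit: DoseResponseFit,
    level: float = 10.0,
) -> E2Equivalent:
    """Estradiol equivalent of a sample from its dilution-response curve.

    The sample series' dose axis is the relative concentration of the
    sample (1 / dilution factor; 1.0 = undiluted).  The sample curve is
    fitted with its own 4PL; the relative concentration ``x`` at which
    it crosses the positive control's ``level``-percent effect response
    is interpolated from that fit, and

        E2-EQ = EC_level(PC) / x

    i.e. the PC concentration producing the same effect, scaled back to
    the undiluted sample.  The CI combines the relative half-widths of
    both curve inversions in quadrature.

    Raises ``ValueError`` ("below effect threshold") when the sample
    curve never reaches the PC's effect level.
    """
    pc_ec = ec_level(pc_fit, level)
    sample_fit = fit_4pl(sample_series)

    target_response = pc_fit.floor + (level / 100.0) * (pc_fit.ceiling - pc_fit.floor)
    conc_all, _ = _pool(sample_series)
    reached = float(sample_fit.predict(conc_all.max()))
    if not (sample_fit.floor < target_response < sample_fit.ceiling
            and reached >= target_response):
        raise ValueError(
            "below effect threshold: sample curve never reaches the "
            f"positive control's {level:g}% effect response within the "
            "tested dilution range"
        )
    x_eff = _inverse_ci(sample_fit, target_response)

    value = pc_ec.value / x_eff.value
    rel = math.hypot(pc_ec.rel if pc_ec.value else 0.0,
                     x_eff.rel if x_eff.value else 0.0)
    return E2Equivalent(ValueWithCI(value, value * rel))
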