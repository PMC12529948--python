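"""Two-state redox-couple speciation kinetics.

A phenol/quinone-imine pair (here the 4HDPA/QMI couple) interconverts
by a reversible pH-dependent two-electron reaction.  Chromatographic
peak areas of the two species, normalized to an internal standard,
give the reduced-species fraction over time:

    f(t) = plateau + (f0 - plateau) * exp(-k * t)

with ``k`` an effective first-order rate (1/h) and ``plateau`` the
equilibrium fraction.  Far from equilibrium (k*t << 1) the decline is
indistinguishable from a line with slope -k*(f0 - plateau), which is
why slow (low-pH) series are fitted linearly and fast (high-pH) series
with the exponential-plateau model.  Fractions are carried internally
on the 0-1 scale and displayed as percent.

Also included: mass-balance diagnostics (the summed normalized areas
of both species should stay constant when no side reactions occur) and
Henderson-Hasselbalch acid-base speciation for the deprotonation that
gates the oxidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SpeciesSeries",
    "KineticFit",
    "normalize_to_is",
    "species_fraction",
    "mass_balance_check",
    "fit_kinetics",
    "deprotonated_fraction",
]


@dataclass
class SpeciesSeries:
    """IS-normalized areas of a two-member redox couple at one pH.

    ``area_reduced`` plays the phenol role (4HDPA), ``area_oxidized``
    the quinone-imine role (QMI); both already normalized against the
    internal standard.
    """

    pH: float
    times: np.ndarray
    area_reduced: np.ndarray
    area_oxidized: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area_reduced = np.asarray(self.area_reduced, dtype=float)
        self.area_oxidized = np.asarray(self.area_oxidized, dtype=float)
        if not (self.times.shape == self.area_reduced.shape == self.area_oxidized.shape):
            raise ValueError("times and both area series must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.area_reduced < 0) or np.any(self.area_oxidized < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KineticFit:
    """A linear or exponential-plateau fit of a fraction time series.

    ``params`` is (f0, slope) for the linear model (slope in fraction
    units per hour) or (f0, plateau, k) for the exponential model with
    rate k in 1/h.  ``param_ci95`` holds matching 95% half-widths.
    ``r2`` is NaN for degenerate (zero-variance) data.
    """

    model: str
    params: tuple[float, ...]
    param_ci95: tuple[float, ...]
    r2: float
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model not in ("linear", "exponential_plateau"):
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if not math.isnan(self.r2) and self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            f0, slope = self.params
            return f0 + slope * t
        f0, plateau, k = self.params
        return plateau + (f0 - plateau) * np.exp(-k * t)


def normalize_to_is(raw_area: float, is_area: float):
    """Normalize a peak area against the internal-standard area."""
    is_arr = np.asarray(is_area, dtype=float)
    if np.any(is_arr <= 0):
        raise ValueError("internal-standard area must be positive")
    return np.asarray(raw_area, dtype=float) / is_arr


def species_fraction(series: SpeciesSeries) -> np.ndarray:
    """Percent of the reduced species in the couple at each timepoint.

    100 * reduced / (reduced + oxidized); errors name the first
    timepoint with a zero total.
    """
    total = series.area_reduced + series.area_oxidized
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(
            f"zero total area at t = {series.times[bad[0]]:g} h "
            f"(timepoint index {bad[0]})"
        )
    return 100.0 * series.area_reduced / total


def mass_balance_check(
    series: SpeciesSeries, tolerance: float = 0.04
) -> tuple[bool, float]:
    """Check that the summed areas of both species stay constant.

    Computes the per-timepoint sum of the two normalized areas and its
    maximum relative deviation from the series mean sum.  Returns
    (passed, max_relative_deviation); the check passes when the
    maximum deviation is below ``tolerance`` (default 4%).  A drifting
    sum indicates losses to side reactions.
    """
    if len(series) < 2:
        raise ValueError("mass balance needs at least 2 timepoints")
    total = series.area_reduced + series.area_oxidized
    mean = float(total.mean())
    if mean <= 0:
        raise ValueError("mean total area must be positive")
    max_dev = float(np.max(np.abs(total - mean)) / mean)
    return max_dev < tolerance, max_dev


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-12 * max(1.0, float(np.sum(y**2))):  # constant series
        return float("nan")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


def _linear_fit(t: np.ndarray, f: np.ndarray) -> KineticFit:
    n = t.size
    X = np.column_stack([np.ones(n), t])
    beta, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
    f0, slope = float(beta[0]), float(beta[1])
    yhat = X @ beta
    dof = n - 2
    resid = f - yhat
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tq = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")
    ci = (tq * math.sqrt(max(cov[0, 0], 0.0)), tq * math.sqrt(max(cov[1, 1], 0.0)))
    r2 = _r2(f, yhat)
    fit = KineticFit("linear", (f0, slope), ci, r2)
    if math.isnan(r2):
        fit.warnings.append("degenerate constant series: r2 undefined, slope 0")
    return fit


def _exp_model(t: np.ndarray, f0: float, plateau: float, k: float) -> np.ndarray:
    return plateau + (f0 - plateau) * np.exp(-k * t)


def _exp_fit(t: np.ndarray, f: np.ndarray) -> KineticFit:
    # deterministic starts: f0 = first value, plateau = last value,
    # k such that ~3 time constants fit in the observation window
    t_max = float(t.max())
    p0 = (float(f[0]), float(f[-1]), 3.0 / t_max if t_max > 0 else 1.0)
    try:
        popt, pcov = optimize.curve_fit(_exp_model, t, f, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential-plateau fit did not converge: {exc}") from exc
    f0, plateau, k = (float(v) for v in popt)
    if k <= 0:
        raise RuntimeError("exponential-plateau fit converged to non-positive rate")
    yhat = _exp_model(t, f0, plateau, k)
    dof = max(t.size - 3, 1)
    tq = stats.t.ppf(0.975, dof)
    diag = np.sqrt(np.clip(np.diag(np.asarray(pcov, dtype=float)), 0.0, None))
    ci = tuple(float(tq * s) for s in diag)
    return KineticFit("exponential_plateau", (f0, plateau, k), ci, _r2(f, yhat))


def fit_kinetics(
    times: np.ndarray, fractions: np.ndarray, model: str = "auto"
) -> KineticFit:
    """Fit a reduced-species fraction time series.

    ``fractions`` may be given on the 0-1 or the 0-100 scale; percent
    input is rescaled to fractions so slopes and rates always come out
    in fraction units per hour.  ``model`` is "linear",
    "exponential_plateau", or "auto" (fit both, keep the higher r2,
    ties going to the linear model).
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise ValueError("at least 4 timepoints are required")
    if np.any(f < 0) or np.any(f > 100):
        raise ValueError("fractions must lie in [0, 100]")
    if np.any(f > 1.0):  # percent scale
        f = f / 100.0

    if model == "linear":
        return _linear_fit(t, f)
    if model == "exponential_plateau":
        return _exp_fit(t, f)
    if model != "auto":
        raise ValueError(f"unknown model {model!r}")

    fit_lin = _linear_fit(t, f)
    warn = [] if t.size >= 6 else ["auto model selection with < 6 points"]
    try:
        fit_exp = _exp_fit(t, f)
    except RuntimeError:
        fit_lin.warnings.extend(warn)
        return fit_lin
    r2_lin = -math.inf if math.isnan(fit_lin.r2) else fit_lin.r2
    r2_exp = -math.inf if math.isnan(fit_exp.r2) else fit_exp.r2
    chosen = fit_exp if r2_exp > r2_lin else fit_lin
    chosen.warnings.extend(warn)
    return chosen


def deprotonated_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch fraction of the deprotonated (anionic) form.

    1 / (1 + 10**(pKa - pH)); increases monotonically with pH and is
    0.5 at pH = pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))
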