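"""Standard-addition quantification.

Ordinary least squares of response vs. spiked concentration; the
analyte concentration in the assay is the magnitude of the x-axis
intercept (a/b for response = a + b*spike).  95% confidence intervals
come from first-order (Fieller-type) propagation of the intercept and
slope covariance with a t-quantile.  Dilution correction and
signal-to-noise based LOD/LOQ extrapolation are included.

All concentrations in this module are in the units of the spike axis
(conventionally ug/L in the assay well).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .types import ValueWithCI

__all__ = ["QuantResult", "fit_standard_addition", "dilution_correct", "lod_loq_from_sn"]


@dataclass(frozen=True)
class QuantResult:
    """Outcome of one standard-addition quantification.

    ``conc_assay`` is the concentration in the measured (diluted) assay
    solution, ``conc_sample`` the dilution-corrected concentration in
    the original sample.  ``lod``/``loq`` are limits of detection and
    quantification at S/N 3 and 10 (hence loq = lod * 10/3 when both
    derive from the same scaling).
    """

    conc_assay: ValueWithCI
    conc_sample: ValueWithCI
    dilution_factor: float
    slope: float
    intercept: float
    cov: tuple[tuple[float, float], tuple[float, float]]
    dof: int
    lod: float = float("nan")
    loq: float = float("nan")

    def __post_init__(self) -> None:
        if self.conc_assay.value < 0 or self.conc_sample.value < 0:
            raise ValueError("concentrations must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


def fit_standard_addition(
    spikes: np.ndarray, responses: np.ndarray
) -> QuantResult:
    """Fit response = intercept + slope * spike and take the x-intercept.

    ``spikes`` and ``responses`` are flat arrays (replicates appear as
    repeated spike levels).  At least 3 distinct spike levels including
    the unspiked sample (level 0) are required; the recovered in-assay
    concentration is intercept/slope, with a 95% CI from the delta
    method on the ratio using the OLS coefficient covariance and the
    residual t-quantile.
    """
    x = np.asarray(spikes, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("spikes and responses must have equal length")
    levels = np.unique(x)
    if levels.size < 3:
        raise ValueError("at least 3 distinct spike levels are required")
    if 0.0 not in levels:
        raise ValueError("the unspiked sample (spike level 0) must be included")
    if np.any(y <= 0):
        raise ValueError("responses must be positive")

    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(beta[0]), float(beta[1])
    if b <= 0:
        raise ValueError("non-positive sensitivity: fitted slope must be > 0")
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    var_a, var_b, cov_ab = cov[0, 0], cov[1, 1], cov[0, 1]

    conc = a / b
    # delta method on the ratio a/b
    var_c = (var_a / b**2
             + (a**2 / b**4) * var_b
             - 2 * (a / b**3) * cov_ab)
    var_c = max(var_c, 0.0)
    tq = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")
    half = tq * math.sqrt(var_c)
    assay = ValueWithCI(abs(conc), half)
    return QuantResult(
        conc_assay=assay,
        conc_sample=assay,
        dilution_factor=1.0,
        slope=b,
        intercept=a,
        cov=((float(var_a), float(cov_ab)), (float(cov_ab), float(var_b))),
        dof=dof,
    )


def dilution_correct(result: QuantResult, aliquot_uL: float, total_uL: float) -> QuantResult:
    """Scale the in-assay concentration back to the undiluted sample.

    ``aliquot_uL`` of sample was made up to ``total_uL`` in the assay
    well, so the dilution factor is total/aliquot and both the point
    estimate and its CI scale linearly.
    """
    if not aliquot_uL > 0:
        raise ValueError("aliquot volume must be positive")
    if total_uL < aliquot_uL:
        raise ValueError("total volume must be >= aliquot volume")
    factor = total_uL / aliquot_uL
    return replace(
        result,
        conc_sample=result.conc_assay.scale(factor),
        dilution_factor=factor,
    )


def lod_loq_from_sn(measured_conc: float, measured_sn: float) -> tuple[float, float]:
    """Extrapolate LOD and LOQ from one measured concentration and its S/N.

    Assuming signal-to-noise proportional to concentration, the
    concentration at S/N 3 is the LOD and at S/N 10 the LOQ:

        lod = c * 3 / sn,   loq = c * 10 / sn
    """
    if not (measured_conc > 0 and measured_sn > 0):
        raise ValueError("measured concentration and S/N must be positive")
    lod = measured_conc * 3.0 / measured_sn
    loq = measured_conc * 10.0 / measured_sn
    return lod, loq
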