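"""Effect-balance accounting with Gaussian error propagation.

Given the effect concentrations of the reference estrogen (E2) and of
a candidate analyte, the analyte's measured concentration, and the
sample's total estradiol equivalent, the chain

    REP              = EC10(E2) / EC10(analyte)
    E2-EQ(analyte)   = REP * C
    percent          = E2-EQ(analyte) / E2-EQ(sample) * 100

quantifies how much of a sample's estrogenicity one analyte explains.
All quantities carry 95%-confidence half-widths, propagated to first
order through the partial derivatives; for these pure products and
ratios that is exactly the quadrature sum of the relative half-widths.
Inputs are treated as independent (they come from separate
experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import ValueWithCI

__all__ = [
    "EffectBalance",
    "relative_potency",
    "e2eq_analyte",
    "percent_contribution",
    "effect_balance",
]


def _ratio(num: ValueWithCI, den: ValueWithCI, scale: float = 1.0) -> ValueWithCI:
    if den.value == 0:
        raise ZeroDivisionError("division by a zero-valued quantity")
    value = num.value / den.value * scale
    rel = math.hypot(num.rel if num.value else 0.0, den.rel if den.value else 0.0)
    return ValueWithCI(value, abs(value) * rel)


def _product(a: ValueWithCI, b: ValueWithCI) -> ValueWithCI:
    value = a.value * b.value
    rel = math.hypot(a.rel if a.value else 0.0, b.rel if b.value else 0.0)
    return ValueWithCI(value, abs(value) * rel)


@dataclass(frozen=True)
class EffectBalance:
    """Full effect-balance result for one analyte in one sample.

    Concentrations are in ng/L; ``percent`` may exceed 100 when the
    analyte alone accounts for the observed activity within error.
    """

    rep: ValueWithCI
    analyte_conc: ValueWithCI
    e2eq_analyte: ValueWithCI
    e2eq_sample: ValueWithCI
    percent: ValueWithCI

    def __post_init__(self) -> None:
        if self.rep.value <= 0:
            raise ValueError("relative potency must be positive")
        if self.percent.value < 0:
            raise ValueError("percent contribution must be non-negative")
        expected = self.rep.value * self.analyte_conc.value
        if not math.isclose(self.e2eq_analyte.value, expected, rel_tol=1e-9):
            raise ValueError("inconsistent chain: E2-EQ(analyte) != REP * C")


def relative_potency(ec10_e2: ValueWithCI, ec10_analyte: ValueWithCI) -> ValueWithCI:
    """REP = EC10(E2) / EC10(analyte), both in the same units."""
    if ec10_e2.value <= 0 or ec10_analyte.value <= 0:
        raise ValueError("effect concentrations must be positive")
    return _ratio(ec10_e2, ec10_analyte)


def e2eq_analyte(rep: ValueWithCI, conc: ValueWithCI) -> ValueWithCI:
    """E2-EQ of the analyte: relative potency times its concentration."""
    if rep.value <= 0 or conc.value <= 0:
        raise ValueError("relative potency and concentration must be positive")
    return _product(rep, conc)


def percent_contribution(e2eq_of_analyte: ValueWithCI,
                         e2eq_sample: ValueWithCI) -> ValueWithCI:
    """Percent of the sample's total E2-EQ explained by the analyte."""
    if e2eq_sample.value <= 0:
        raise ValueError("sample E2-EQ must be positive")
    return _ratio(e2eq_of_analyte, e2eq_sample, scale=100.0)


def effect_balance(
    ec10_e2: ValueWithCI,
    ec10_analyte: ValueWithCI,
    analyte_conc: ValueWithCI,
    e2eq_sample: ValueWithCI,
) -> EffectBalance:
    """Run the full chain REP -> E2-EQ(analyte) -> percent contribution.

    All concentrations must be in ng/L.  Because every step is a
    product or ratio of independent inputs, the chained propagation
    equals the single-formula evaluation

        percent = (EC10(E2) * C) / (EC10(analyte) * E2-EQ(sample)) * 100

    with the four relative half-widths combined in quadrature.
    """
    rep = relative_potency(ec10_e2, ec10_analyte)
    eq_an = e2eq_analyte(rep, analyte_conc)
    pct = percent_contribution(eq_an, e2eq_sample)
    return EffectBalance(
        rep=rep,
        analyte_conc=analyte_conc,
        e2eq_analyte=eq_an,
        e2eq_sample=e2eq_sample,
        percent=pct,
    )
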