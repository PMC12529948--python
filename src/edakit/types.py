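"""Shared domain types for the effect-directed-analysis workbench.

Canonical internal units: concentration in ng/L, m/z in Da, retention
time in minutes, time in hours.  Conversions happen only at I/O
boundaries so that a mu-g/L table and an ng/L table can never be mixed
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Polarity",
    "SampleRole",
    "Feature",
    "FeatureTable",
    "MatchTolerances",
    "ConfidenceLevel",
    "PlateSeries",
    "ValueWithCI",
]


class Polarity(str, Enum):
    """Electrospray ionization polarity."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class SampleRole(str, Enum):
    """Role of a feature table within the fractionation design."""

    EXTRACT = "extract"
    FRACTION_UPPER = "fraction_upper"
    FRACTION_LOWER = "fraction_lower"
    BLANK = "blank"


@dataclass(frozen=True)
class Feature:
    """One detected LC-HRMS feature: an (m/z, RT, intensity) triple.

    Parameters
    ----------
    mz : float
        Mass-to-charge ratio in Da.  Must be positive.
    rt : float
        Retention time in minutes.  Must be non-negative.
    intensity : float
        Abstract intensity (counts); peak area or height depending on
        the upstream peak picker.  Must be positive.
    polarity : Polarity
        Ionization mode the feature was detected in.
    """

    mz: float
    rt: float
    intensity: float
    polarity: Polarity = Polarity.POSITIVE

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"feature RT must be >= 0 min, got {self.rt}")
        if not self.intensity > 0:
            raise ValueError(
                f"feature intensity must be positive, got {self.intensity}"
            )


@dataclass
class FeatureTable:
    """All features of one sample in one ionization mode.

    ``ref`` is the relative enrichment factor (REF) of the underlying
    water sample, e.g. 1 or 5 for the two SPE extract dilutions.
    """

    sample_id: str
    role: SampleRole
    ref: float
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ref > 0:
            raise ValueError(f"enrichment factor must be positive, got {self.ref}")
        pols = {f.polarity for f in self.features}
        if len(pols) > 1:
            raise ValueError("a FeatureTable must hold a single polarity")

    @property
    def polarity(self) -> Polarity | None:
        return self.features[0].polarity if self.features else None

    @property
    def total_intensity(self) -> float:
        return float(sum(f.intensity for f in self.features))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass(frozen=True)
class MatchTolerances:
    """Absolute tolerances used for feature/library matching.

    Defaults follow common QToF screening practice: 10 mDa at MS1,
    15 mDa at MS2, 1 min in retention time.
    """

    ms1_tol: float = 0.010
    ms2_tol: float = 0.015
    rt_tol: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ms1_tol", "ms2_tol", "rt_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


class ConfidenceLevel(int, Enum):
    """Identification-confidence scale for nontarget annotations.

    Level 1 is a structure confirmed with a reference standard
    (MS, MS2 and RT agree); level 2 a probable structure via spectral
    library match; level 3 a tentative candidate (MS2 evidence without
    a library hit); level 4 an unequivocal molecular formula; level 5
    exact mass only.
    """

    CONFIRMED = 1
    PROBABLE = 2
    TENTATIVE = 3
    FORMULA = 4
    MASS_ONLY = 5


@dataclass
class PlateSeries:
    """One dilution series from a microtiter-plate bioassay.

    ``concentrations`` are doses in ng/L for standards, or relative
    concentrations (1 / dilution factor) for samples of unknown
    composition.  They must be strictly positive and sorted ascending.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if not np.all(self.concentrations > 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class ValueWithCI:
    """A point estimate with a symmetric 95%-confidence half-width."""

    value: float
    ci95_half: float = 0.0

    def __post_init__(self) -> None:
        if self.ci95_half < 0:
            raise ValueError("CI half-width must be non-negative")

    @property
    def rel(self) -> float:
        """Relative half-width (half-width / |value|)."""
        if self.value == 0:
            raise ZeroDivisionError("relative error undefined for zero value")
        return self.ci95_half / abs(self.value)

    def scale(self, factor: float) -> "ValueWithCI":
        """Multiply value and half-width by a positive factor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ValueWithCI(self.value * factor, self.ci95_half * factor)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} ± {self.ci95_half:g}"


def as_series_list(series: PlateSeries | Sequence[PlateSeries]) -> list[PlateSeries]:
    """Normalize a single series or a sequence of replicates to a list."""
    if isinstance(series, PlateSeries):
        return [series]
    out = list(series)
    if not out:
        raise ValueError("at least one plate series is required")
    return out
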