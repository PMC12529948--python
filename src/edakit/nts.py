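"""Minimal nontarget-screening computations.

Exact-mass and adduct m/z arithmetic, trace-level peak picking with
screening thresholds (minimum intensity, signal-to-noise, peak-width
window), tolerance-based spectral-library matching, and assignment of
identification-confidence levels (1 = confirmed structure via
reference standard ... 5 = exact mass only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .types import ConfidenceLevel, Feature, MatchTolerances, Polarity

__all__ = [
    "Formula",
    "Trace",
    "LibraryEntry",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "monoisotopic_mass",
    "adduct_mz",
    "pick_peaks",
    "match_library",
]

# CODATA/IUPAC monoisotopic masses of the most abundant isotopes (Da).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.99840320,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
    "Si": 27.9769265327,
    "Na": 22.98976928,
    "K": 38.9637069,
}

# Mass of the charge carrier for protonation/deprotonation: the proton,
# i.e. an H atom minus its electron (1.0078250 - 0.0005486 Da).  Using
# the electron-corrected value keeps [M+H]+ of small molecules correct
# to the fourth decimal.
PROTON_MASS: float = 1.0072765

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """A molecular formula as element -> count mapping.

    Construct from a Hill-style string, e.g. ``Formula.parse("C12H11NO")``.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one atom")
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if n <= 0:
                raise ValueError(f"element count must be positive: {element}{n}")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        text = text.strip()
        if not text:
            raise ValueError("empty formula")
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            if not m.group(0):
                break
            element = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[element] = counts.get(element, 0) + n
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(tuple(sorted(counts.items())))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        d = dict(self.counts)
        out = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if el in d:
                out.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(out)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic (exact) mass of a neutral molecule in Da."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts))


_ADDUCTS = {
    "[M+H]+": +PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
}


def adduct_mz(formula: Formula | str, adduct: str) -> float:
    """m/z of a singly charged adduct ion.

    Supported adducts are ``[M+H]+`` and ``[M-H]-`` (an en-dash or
    minus sign in the label is tolerated).  The full float is
    returned; rounding is left to display code.
    """
    key = adduct.replace("−", "-").replace("–", "-")
    if key not in _ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}"
        )
    return monoisotopic_mass(formula) + _ADDUCTS[key]


@dataclass
class Trace:
    """A single extracted-ion or total-ion chromatographic trace.

    Times are in seconds and must be strictly increasing; intensities
    are non-negative counts.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size == 0:
            raise ValueError("trace must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


def _mad_sigma(x: np.ndarray) -> float:
    """Robust sigma estimate: 1.4826 * median absolute deviation."""
    if x.size == 0:
        return 0.0
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def pick_peaks(
    trace: Trace,
    min_intensity: float = 10.0,
    sn: float = 3.0,
    width_bounds: tuple[float, float] = (5.0, 60.0),
    polarity: Polarity = Polarity.POSITIVE,
    mz: float = 1.0,
) -> list[Feature]:
    """Detect chromatographic peaks in a trace.

    A local maximum is reported when its apex intensity is at least
    ``min_intensity``, the apex-to-noise ratio is at least ``sn``
    (noise = MAD-based sigma of the trace outside candidate peak
    regions), and the full width at half maximum lies within
    ``width_bounds`` seconds.  Apex times are reported in minutes.

    A flat or empty-signal trace yields an empty list, not an error.
    ``mz`` is attached to the emitted features (peak picking operates
    on one extracted-ion trace at a time); the placeholder 1.0 is used
    when the trace has no associated ion.
    """
    lo_w, hi_w = width_bounds
    if not (lo_w > 0 and hi_w > lo_w):
        raise ValueError("width bounds must satisfy 0 < lo < hi")
    y = trace.intensities
    t = trace.times
    if np.all(y == y[0]):
        return []
    dt = float(np.median(np.diff(t)))

    # candidate apexes: any strict local maximum above the floor
    idx, _ = _signal.find_peaks(y, height=min_intensity)
    if idx.size == 0:
        return []
    widths_samples = _signal.peak_widths(y, idx, rel_height=0.5)[0]
    widths_s = widths_samples * dt

    # noise floor from the trace with candidate peak regions masked out
    mask = np.ones_like(y, dtype=bool)
    for i, w in zip(idx, widths_samples):
        half = max(int(np.ceil(w)), 2)
        mask[max(i - 2 * half, 0): i + 2 * half + 1] = False
    baseline = y[mask]
    sigma = _mad_sigma(baseline)

    out: list[Feature] = []
    for i, w in zip(idx, widths_s):
        apex = float(y[i])
        if apex < min_intensity:
            continue
        if sigma > 0 and apex / sigma < sn:
            continue
        if not (lo_w <= w <= hi_w):
            continue
        out.append(
            Feature(mz=float(mz), rt=float(t[i]) / 60.0,
                    intensity=apex, polarity=polarity)
        )
    return out


@dataclass
class LibraryEntry:
    """One compound record of a spectral library.

    ``adduct_mz_by_polarity`` maps polarity to the expected precursor
    m/z; when omitted it is computed from the formula assuming
    [M+H]+ / [M-H]-.  ``ms2_peaks`` are (m/z, relative intensity)
    pairs; ``is_reference`` marks entries backed by an authentic
    reference standard (required for confidence level 1).
    """

    name: str
    formula: Formula
    expected_rt: float
    ms2_peaks: list[tuple[float, float]] = field(default_factory=list)
    adduct_mz_by_polarity: dict[Polarity, float] = field(default_factory=dict)
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not self.adduct_mz_by_polarity:
            self.adduct_mz_by_polarity = {
                Polarity.POSITIVE: adduct_mz(self.formula, "[M+H]+"),
                Polarity.NEGATIVE: adduct_mz(self.formula, "[M-H]-"),
            }
        precursor = max(self.adduct_mz_by_polarity.values())
        for frag_mz, _ in self.ms2_peaks:
            if frag_mz >= precursor + 0.010:
                raise ValueError(
                    f"MS2 fragment m/z {frag_mz} exceeds precursor {precursor}"
                )


def _ms2_score(
    feature_ms2: list[tuple[float, float]],
    library_ms2: list[tuple[float, float]],
    ms2_tol: float,
) -> float:
    """Fraction of library MS2 peaks matched within tolerance."""
    if not library_ms2:
        return 0.0
    matched = 0
    for lib_mz, _ in library_ms2:
        if any(abs(lib_mz - f_mz) <= ms2_tol for f_mz, _ in feature_ms2):
            matched += 1
    return matched / len(library_ms2)


def match_library(
    feature: Feature,
    library: list[LibraryEntry],
    tol: MatchTolerances = MatchTolerances(),
    feature_ms2: list[tuple[float, float]] | None = None,
    ms2_score_threshold: float = 0.5,
) -> list[tuple[LibraryEntry, ConfidenceLevel]]:
    """Match one feature against a spectral library.

    A library entry is a candidate when the precursor m/z agrees within
    ``tol.ms1_tol`` and the retention time within ``tol.rt_tol``.  The
    confidence level is then assigned as follows: formula/exact-mass
    agreement alone gives level 4; if the feature carries an MS2
    spectrum but the library entry has none, level 3 (MS2 evidence
    without a library spectrum); if at least ``ms2_score_threshold`` of
    the entry's MS2 peaks are matched within ``tol.ms2_tol``, level 2,
    upgraded to level 1 when the entry is backed by a reference
    standard.
    """
    results: list[tuple[LibraryEntry, ConfidenceLevel]] = []
    for entry in library:
        expected = entry.adduct_mz_by_polarity.get(feature.polarity)
        if expected is None:
            continue
        if abs(expected - feature.mz) > tol.ms1_tol:
            continue
        if abs(entry.expected_rt - feature.rt) > tol.rt_tol:
            continue
        level = ConfidenceLevel.FORMULA
        if feature_ms2:
            if not entry.ms2_peaks:
                level = ConfidenceLevel.TENTATIVE
            else:
                score = _ms2_score(feature_ms2, entry.ms2_peaks, tol.ms2_tol)
                if score >= ms2_score_threshold:
                    level = (
                        ConfidenceLevel.CONFIRMED
                        if entry.is_reference
                        else ConfidenceLevel.PROBABLE
                    )
                else:
                    level = ConfidenceLevel.TENTATIVE
        results.append((entry, level))
    return results
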