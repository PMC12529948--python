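"""Synthetic data with known ground truth for the whole pipeline.

Generates every input the analysis needs: feature tables with planted
driver compounds embedded among background features that each violate
one prioritization criterion, yeast-estrogen-screen plates following a
four-parameter logistic, standard-addition spike series, and two-state
redox interconversion time series.

Noise models: multiplicative log-normal for intensities and plate
responses (instrument-like, preserves positivity), additive Gaussian
for kinetic fractions.  Every generator is deterministic given its
seed, and ground truth is returned alongside each dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import SpeciesSeries
from .types import Feature, FeatureTable, PlateSeries, Polarity, SampleRole

__all__ = [
    "ScenarioTruth",
    "FeatureScenario",
    "gen_feature_scenario",
    "gen_yes_plate",
    "gen_standard_addition",
    "gen_kinetics",
    "DEFAULT_TIMEPOINTS_H",
    "DEFAULT_SPIKE_LEVELS_UGL",
    "DEFAULT_KINETIC_PARAMS",
]

# Sampling grid of the pH-stability experiment (hours).
DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (
    0, 3, 5, 7, 9, 12, 14, 17, 48, 73, 100, 123, 146, 173,
)

# Spike grid of the standard-addition series (ug/L in the assay),
# level 0 being the unspiked sample.
DEFAULT_SPIKE_LEVELS_UGL: tuple[float, ...] = (0.0, 210.0, 420.0, 630.0, 840.0)

# Effective two-state kinetics per pH: (f0, k [1/h], plateau).  Low-pH
# series decline so slowly that the curve is effectively linear over
# the observation window (initial slope -k*(f0-plateau)); high-pH
# series reach their plateau within ~100 h.
DEFAULT_KINETIC_PARAMS: dict[float, tuple[float, float, float]] = {
    5.0: (0.92, 1.57e-3, 0.50),
    6.0: (0.93, 1.43e-3, 0.51),
    7.0: (0.93, 3.50e-3, 0.50),
    8.0: (0.95, 3.50e-2, 0.58),
    9.0: (0.95, 4.50e-2, 0.53),
}

# Criteria a background feature can be built to violate.
_VIOLATIONS = (
    "missing_1x",      # not detected in the 1x extract
    "missing_upper",   # absent from the upper fraction
    "missing_lower",   # absent from the lower fraction
    "higher_in_1x",    # 1x intensity exceeds 5x intensity
    "in_blank",        # present in the process blank
    "low_intensity",   # below the 1%-of-total intensity share
)


@dataclass
class ScenarioTruth:
    """Ground truth emitted with every synthetic feature scenario."""

    driver_features: list[dict] = field(default_factory=list)
    background_violations: list[str] = field(default_factory=list)
    true_ec50: float = float("nan")
    true_hill: float = float("nan")
    true_conc: float = float("nan")
    true_rate_k: dict[float, float] = field(default_factory=dict)
    true_plateau: dict[float, float] = field(default_factory=dict)


@dataclass
class FeatureScenario:
    """The five feature tables of one fractionation experiment + truth."""

    extract5: FeatureTable
    extract1: FeatureTable
    upper: FeatureTable
    lower: FeatureTable
    blank: FeatureTable
    truth: ScenarioTruth

    def tables(self) -> dict[str, FeatureTable]:
        return {
            "extract5": self.extract5,
            "extract1": self.extract1,
            "upper": self.upper,
            "lower": self.lower,
            "blank": self.blank,
        }


def _lognorm_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal noise with unit median and given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def gen_feature_scenario(
    n_background: int = 100,
    n_drivers: int = 2,
    noise_cv: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    polarity: Polarity = Polarity.POSITIVE,
) -> FeatureScenario:
    """Generate the five feature tables of a fractionation experiment.

    Planted driver features appear in both extracts (5x intensity
    proportional to the enrichment factor before noise), in both
    bioactive fractions, are absent from the process blank and exceed
    1% of the summed table intensity.  Each background feature is
    constructed to violate exactly one cascade criterion; the violated
    criterion is recorded in the truth record.

    Features are laid out on a 0.5-Da m/z grid so that tolerance
    matching (10 mDa) can never confuse two distinct features; a small
    m/z and RT jitter between tables exercises the matching itself.
    """
    if n_drivers < 1:
        raise ValueError("at least one driver feature is required")
    if n_background < 0:
        raise ValueError("n_background must be non-negative")
    if not 0 <= noise_cv <= 0.5:
        raise ValueError("noise_cv must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)

    n_total = n_background + n_drivers
    mz_grid = 150.0 + 0.5 * np.arange(n_total)
    rt_grid = rng.uniform(1.0, 20.0, size=n_total)

    driver_base = 1.0e5  # counts; far above the 1% share of the table
    bg_base = rng.uniform(200.0, 1500.0, size=n_background)
    violations = [
        _VIOLATIONS[rng.integers(0, len(_VIOLATIONS))] for _ in range(n_background)
    ]

    truth = ScenarioTruth(background_violations=violations)

    def jitter_mz(mz: float) -> float:
        return mz + float(rng.normal(0.0, 0.002))

    def jitter_rt(rt: float) -> float:
        return max(float(rt + rng.normal(0.0, 0.02)), 0.0)

    def noisy(base: float) -> float:
        return float(base * _lognorm_factor(rng, noise_cv))

    rows: dict[str, list[Feature]] = {k: [] for k in
                                      ("extract5", "extract1", "upper", "lower", "blank")}

    def add(table: str, mz: float, rt: float, intensity: float) -> None:
        rows[table].append(
            Feature(mz=jitter_mz(mz), rt=jitter_rt(rt),
                    intensity=max(intensity, 1e-6), polarity=polarity)
        )

    # drivers: present everywhere except the blank, REF-proportional
    for d in range(n_drivers):
        mz, rt = float(mz_grid[d]), float(rt_grid[d])
        i5 = noisy(driver_base)
        add("extract5", mz, rt, i5)
        add("extract1", mz, rt, noisy(driver_base / 5.0))
        add("upper", mz, rt, noisy(driver_base * 0.6))
        add("lower", mz, rt, noisy(driver_base * 0.4))
        truth.driver_features.append(
            {"mz": mz, "rt": rt, "intensity_5x": i5, "formula": None}
        )

    # background features, each violating its assigned criterion
    for b in range(n_background):
        mz, rt = float(mz_grid[n_drivers + b]), float(rt_grid[n_drivers + b])
        base = float(bg_base[b])
        v = violations[b]
        i5 = noisy(base)
        add("extract5", mz, rt, i5)
        if v != "missing_1x":
            ratio = 1.5 if v == "higher_in_1x" else 0.2
            add("extract1", mz, rt, noisy(base * ratio))
        if v != "missing_upper":
            add("upper", mz, rt, noisy(base * 0.6))
        if v != "missing_lower":
            add("lower", mz, rt, noisy(base * 0.4))
        if v == "in_blank":
            add("blank", mz, rt, noisy(base * 0.5))

    scenario = FeatureScenario(
        extract5=FeatureTable("extract_5x", SampleRole.EXTRACT, 5.0, rows["extract5"]),
        extract1=FeatureTable("extract_1x", SampleRole.EXTRACT, 1.0, rows["extract1"]),
        upper=FeatureTable("fraction_upper", SampleRole.FRACTION_UPPER, 1.0, rows["upper"]),
        lower=FeatureTable("fraction_lower", SampleRole.FRACTION_LOWER, 1.0, rows["lower"]),
        blank=FeatureTable("process_blank", SampleRole.BLANK, 1.0, rows["blank"]),
        truth=truth,
    )
    return scenario


def _pc_grid(start: float = 0.66, n_steps: int = 10) -> np.ndarray:
    """Positive-control dose grid: doubling steps from ``start`` ng/L."""
    return start * 2.0 ** np.arange(n_steps)


def gen_yes_plate(
    true_ec50: float,
    hill: float = 2.4,
    floor: float = 1.0,
    ceiling: float = 10.0,
    n_dilutions: int = 7,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int | np.random.SeedSequence = 0,
    top_conc: float | None = None,
    pc_ec50: float = 82.0,
    pc_hill: float = 1.5,
) -> tuple[list[PlateSeries], list[PlateSeries]]:
    """Simulate a YES plate: analyte dilution series plus E2 control.

    The analyte is diluted 1:2 over ``n_dilutions`` levels starting at
    ``top_conc`` (default 6x the true EC50 so the curve brackets its
    midpoint); the positive control spans 10 doubling steps from
    0.66 ng/L.  Responses follow a 4PL in log-concentration with
    multiplicative log-normal noise of the stated CV.

    Returns (sample replicate series, positive-control replicate
    series); concentrations in ng/L.
    """
    if hill <= 0 or pc_hill <= 0:
        raise ValueError("Hill slopes must be positive")
    if n_dilutions < 5:
        raise ValueError("at least 5 dilution levels are required")
    if true_ec50 <= 0:
        raise ValueError("true EC50 must be positive")
    rng = np.random.default_rng(seed)

    top = top_conc if top_conc is not None else 6.0 * true_ec50
    conc = top / 2.0 ** np.arange(n_dilutions)[::-1]

    def fourpl(c: np.ndarray, ec50: float, h: float) -> np.ndarray:
        return floor + (ceiling - floor) / (1.0 + (ec50 / c) ** h)

    sample = [
        PlateSeries(conc, fourpl(conc, true_ec50, hill)
                    * _lognorm_factor(rng, noise_cv, conc.size),
                    replicate_id=f"s{r+1}")
        for r in range(n_replicates)
    ]
    pc_conc = _pc_grid()
    pc = [
        PlateSeries(pc_conc, fourpl(pc_conc, pc_ec50, pc_hill)
                    * _lognorm_factor(rng, noise_cv, pc_conc.size),
                    replicate_id=f"pc{r+1}")
        for r in range(n_replicates)
    ]
    return sample, pc


def gen_standard_addition(
    true_conc: float = 500.0,
    spike_levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS_UGL,
    slope: float = 1.0,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a standard-addition series.

    response = slope * (true_conc + spike), with multiplicative
    log-normal noise; concentrations in ug/L in the assay.  Returns
    flat (spikes, responses) arrays with replicates interleaved.
    """
    if slope <= 0:
        raise ValueError("sensitivity (slope) must be positive")
    levels = np.asarray(spike_levels, dtype=float)
    if levels.size < 3 or np.any(np.diff(levels) <= 0):
        raise ValueError("spike levels must be strictly increasing with >= 3 levels")
    rng = np.random.default_rng(seed)
    spikes = np.repeat(levels, n_replicates)
    responses = slope * (true_conc + spikes) * _lognorm_factor(rng, noise_cv, spikes.size)
    return spikes, responses


def gen_kinetics(
    pH_values: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0, 9.0),
    params: dict[float, tuple[float, float, float]] | None = None,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS_H,
    noise_sd: float = 0.01,
    total_cv: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
) -> dict[float, SpeciesSeries]:
    """Simulate two-state redox interconversion series, one per pH.

    The reduced-species fraction follows
    f(t) = plateau + (f0 - plateau) * exp(-k * t); ``params`` maps pH
    to (f0, k, plateau) and defaults to ``DEFAULT_KINETIC_PARAMS``.
    Additive Gaussian noise of ``noise_sd`` perturbs the fraction; the
    summed normalized area of the two species is constant up to a
    small multiplicative perturbation of CV ``total_cv``, so the mass
    balance holds to < 4% by construction at the default noise.
    """
    params = dict(DEFAULT_KINETIC_PARAMS if params is None else params)
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[float, SpeciesSeries] = {}
    for pH in pH_values:
        if pH not in params:
            raise ValueError(f"no kinetic parameters supplied for pH {pH}")
        f0, k, plateau = params[pH]
        if not (0 < plateau <= 1 and 0 < f0 <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if plateau > f0:
            raise ValueError("plateau must not exceed f0 for a decay scenario")
        if k < 0:
            raise ValueError("rate constant must be non-negative")
        frac = plateau + (f0 - plateau) * np.exp(-k * t)
        frac_noisy = np.clip(frac + rng.normal(0.0, noise_sd, t.size), 0.0, 1.0)
        total = _lognorm_factor(rng, total_cv, t.size)
        out[pH] = SpeciesSeries(
            pH=pH,
            times=t,
            area_reduced=frac_noisy * total,
            area_oxidized=(1.0 - frac_noisy) * total,
        )
    return out
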