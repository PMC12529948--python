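"""Exact-mass arithmetic, peak picking and library matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edakit.nts import (
    Formula,
    LibraryEntry,
    PROTON_MASS,
    Trace,
    adduct_mz,
    match_library,
    monoisotopic_mass,
    pick_peaks,
)
from edakit.types import ConfidenceLevel, Feature, MatchTolerances, Polarity

from oracles import oracle_local_maxima


class TestFormula:
    def test_parse_and_roundtrip(self):
        f = Formula.parse("C12H11NO")
        assert dict(f.counts) == {"C": 12, "H": 11, "N": 1, "O": 1}
        assert str(f) == "C12H11NO"

    @pytest.mark.parametrize("bad", ["", "Xx2", "12C", "C-1", "c6h6"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            Formula.parse(bad)


class TestExactMass:
    # frozen values computed by summing the monoisotopic mass table:
    # C12H9NO = 12*12 + 9*1.0078250319 + 14.0030740052 + 15.9949146221
    @pytest.mark.parametrize(
        "formula,mass",
        [
            ("C12H9NO", 183.068414),
            ("C12H11NO", 185.084064),
            ("H", 1.0078250),
        ],
    )
    def test_monoisotopic_mass(self, formula, mass):
        assert monoisotopic_mass(formula) == pytest.approx(mass, abs=5e-7)

    @pytest.mark.parametrize(
        "formula,adduct,mz",
        [
            # quinone-imine oxidation product, protonated
            ("C12H9NO", "[M+H]+", 184.0757),
            # 4-hydroxydiphenylamine, both polarities
            ("C12H11NO", "[M+H]+", 186.0913),
            ("C12H11NO", "[M−H]−", 184.0768),
        ],
    )
    def test_adduct_mz(self, formula, adduct, mz):
        assert adduct_mz(formula, adduct) == pytest.approx(mz, abs=5e-5)

    def test_unsupported_adduct(self):
        with pytest.raises(ValueError, match="adduct"):
            adduct_mz("C6H6", "[M+Na]+")

    def test_cross_check_against_pyteomics(self):
        """Independent mass library agrees to the fifth decimal."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for formula in ["C12H9NO", "C12H11NO", "C19H23N2O", "C6H5Cl", "C9H13NO3S"]:
            ours = monoisotopic_mass(formula)
            theirs = pyteomics_mass.calculate_mass(formula=formula)
            assert ours == pytest.approx(theirs, abs=2e-5)

    @given(
        st.fixed_dictionaries(
            {},
            optional={el: st.integers(1, 30) for el in ("C", "H", "N", "O", "S", "Cl")},
        ).filter(bool)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adduct_gap_is_two_protons(self, counts):
        f = Formula(tuple(sorted(counts.items())))
        gap = adduct_mz(f, "[M+H]+") - adduct_mz(f, "[M-H]-")
        assert gap == pytest.approx(2 * PROTON_MASS, abs=1e-12)


def gaussian_trace(apex=100.0, fwhm_s=20.0, center_s=300.0, n=600, dt=1.0,
                   noise_sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    sigma = fwhm_s / 2.3548
    y = apex * np.exp(-0.5 * ((t - center_s) / sigma) ** 2)
    y = np.clip(y + rng.normal(0, noise_sigma, n), 0, None)
    return Trace(t, y)


class TestPickPeaks:
    def test_single_clear_peak(self):
        peaks = pick_peaks(gaussian_trace())
        assert len(peaks) == 1
        assert peaks[0].rt == pytest.approx(5.0, abs=0.1)  # 300 s in minutes

    def test_apex_below_min_intensity(self):
        peaks = pick_peaks(gaussian_trace(apex=5.0, noise_sigma=0.0))
        assert peaks == []

    def test_width_bounds_reject_broad_peak(self):
        peaks = pick_peaks(gaussian_trace(fwhm_s=120.0, noise_sigma=0.0))
        assert peaks == []

    def test_flat_zero_trace_is_empty_not_error(self):
        tr = Trace(np.arange(100.0), np.zeros(100))
        assert pick_peaks(tr) == []

    def test_two_separated_peaks_match_local_max_oracle(self):
        t = np.arange(600.0)
        sigma = 20.0 / 2.3548
        y = 100 * np.exp(-0.5 * ((t - 200) / sigma) ** 2)
        y += 80 * np.exp(-0.5 * ((t - 320) / sigma) ** 2)
        tr = Trace(t, y)
        peaks = pick_peaks(tr)
        assert len(peaks) == 2
        assert len(peaks) == oracle_local_maxima(y, 10.0)

    def test_scale_invariance_above_threshold(self):
        tr = gaussian_trace()
        base = pick_peaks(tr)
        scaled = pick_peaks(Trace(tr.times, tr.intensities * 7.0))
        assert len(base) == len(scaled)
        assert [p.rt for p in base] == pytest.approx([p.rt for p in scaled])

    def test_infinite_min_intensity_gives_nothing(self):
        assert pick_peaks(gaussian_trace(), min_intensity=1e12) == []


def entry(name, formula, rt, ms2=(), reference=False):
    return LibraryEntry(name=name, formula=Formula.parse(formula), expected_rt=rt,
                        ms2_peaks=list(ms2), is_reference=reference)


class TestMatchLibrary:
    tol = MatchTolerances()

    def test_match_within_tolerances(self):
        # measured 186.0914 @ 9.90 min against a reference standard at 10.06 min
        feat = Feature(mz=186.0914, rt=9.90, intensity=1e5)
        lib = [entry("4-hydroxydiphenylamine", "C12H11NO", 10.06)]
        hits = match_library(feat, lib, self.tol)
        assert len(hits) == 1
        assert hits[0][1] is ConfidenceLevel.FORMULA

    def test_mz_offset_beyond_tolerance(self):
        feat = Feature(mz=186.0913 + 0.012, rt=10.0, intensity=1e5)
        lib = [entry("x", "C12H11NO", 10.0)]
        assert match_library(feat, lib, self.tol) == []

    def test_confidence_levels(self):
        ms2 = [(156.0784, 100.0), (128.0601, 40.0), (77.0378, 20.0)]
        feat = Feature(mz=184.0757, rt=9.92, intensity=6e4)
        feat_ms2 = [(156.0790, 90.0), (128.0595, 50.0)]
        lib = [
            entry("with-spectrum", "C12H9NO", 10.1, ms2=ms2),
            entry("reference", "C12H9NO", 10.1, ms2=ms2, reference=True),
            entry("no-spectrum", "C12H9NO", 10.1),
        ]
        levels = {e.name: lv for e, lv in match_library(feat, lib, self.tol,
                                                        feature_ms2=feat_ms2)}
        # 2 of 3 library peaks matched -> score 0.67 >= 0.5
        assert levels["with-spectrum"] is ConfidenceLevel.PROBABLE
        assert levels["reference"] is ConfidenceLevel.CONFIRMED
        assert levels["no-spectrum"] is ConfidenceLevel.TENTATIVE

    def test_without_ms2_formula_level(self):
        feat = Feature(mz=184.0757, rt=9.92, intensity=6e4)
        hits = match_library(feat, [entry("q", "C12H9NO", 10.1)], self.tol)
        assert hits[0][1] is ConfidenceLevel.FORMULA

    def test_empty_library(self):
        feat = Feature(mz=184.0757, rt=9.92, intensity=6e4)
        assert match_library(feat, [], self.tol) == []

    def test_equals_brute_force_all_pairs(self, rng):
        lib = [entry(f"c{i}", "C12H11NO", float(rt))
               for i, rt in enumerate(rng.uniform(0, 20, 50))]
        # jitter the expected m/z so only some entries fall inside tolerance
        for e in lib:
            e.adduct_mz_by_polarity[Polarity.POSITIVE] += float(rng.normal(0, 0.008))
        feat = Feature(mz=186.0913, rt=10.0, intensity=1e4)
        got = {e.name for e, _ in match_library(feat, lib, self.tol)}
        expected = {
            e.name for e in lib
            if abs(e.adduct_mz_by_polarity[Polarity.POSITIVE] - feat.mz) <= 0.010
            and abs(e.expected_rt - feat.rt) <= 1.0
        }
        assert got == expected

    def test_tolerance_monotonicity(self, rng):
        lib = [entry(f"c{i}", "C12H11NO", float(rt))
               for i, rt in enumerate(rng.uniform(9, 11, 20))]
        for e in lib:
            e.adduct_mz_by_polarity[Polarity.POSITIVE] += float(rng.normal(0, 0.008))
        feat = Feature(mz=186.0913, rt=10.0, intensity=1e4)
        narrow = {e.name for e, _ in match_library(feat, lib, MatchTolerances(0.005, 0.015, 0.5))}
        wide = {e.name for e, _ in match_library(feat, lib, MatchTolerances(0.02, 0.015, 2.0))}
        assert narrow <= wide
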