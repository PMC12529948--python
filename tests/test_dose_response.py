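"""4PL dose-response fitting, effect concentrations and E2 equivalents."""

import numpy as np
import pytest
from scipy import optimize

from edakit.dose_response import _model4pl, ec_level, e2_equivalents, fit_4pl
from edakit.synthetic import gen_yes_plate
from edakit.types import PlateSeries


def plate(conc, resp, rep="r1"):
    return PlateSeries(np.asarray(conc, float), np.asarray(resp, float), rep)


class TestFit4PL:
    def test_noiseless_identifiability(self):
        sample, _ = gen_yes_plate(true_ec50=820_000, hill=2.4, noise_cv=0.0,
                                  n_replicates=1, seed=0)
        fit = fit_4pl(sample)
        assert fit.ec50 == pytest.approx(820_000, rel=1e-6)
        assert fit.hill == pytest.approx(2.4, rel=1e-6)
        assert fit.floor == pytest.approx(1.0, abs=1e-6)
        assert fit.ceiling == pytest.approx(10.0, rel=1e-6)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="5 distinct"):
            fit_4pl(plate([1, 2], [0.1, 0.9]))

    def test_flat_data_is_no_response(self):
        with pytest.raises(ValueError, match="no response"):
            fit_4pl(plate([1, 2, 4, 8, 16], [1.0] * 5))

    def test_dose_scale_equivariance(self):
        sample, _ = gen_yes_plate(true_ec50=1000.0, hill=1.8, noise_cv=0.05,
                                  n_replicates=2, seed=4)
        fit = fit_4pl(sample)
        scaled = [plate(s.concentrations * 50.0, s.responses, s.replicate_id)
                  for s in sample]
        fit_s = fit_4pl(scaled)
        assert fit_s.ec50 == pytest.approx(fit.ec50 * 50.0, rel=1e-6)
        assert fit_s.hill == pytest.approx(fit.hill, rel=1e-6)
        assert fit_s.floor == pytest.approx(fit.floor, rel=1e-6)
        assert fit_s.ceiling == pytest.approx(fit.ceiling, rel=1e-6)


class TestECLevel:
    @pytest.fixture
    def noisy_fit(self):
        sample, _ = gen_yes_plate(true_ec50=820_000, hill=2.4, noise_cv=0.08,
                                  n_replicates=3, seed=7)
        return fit_4pl(sample)

    def test_level_50_is_ec50(self, noisy_fit):
        assert ec_level(noisy_fit, 50.0).value == pytest.approx(noisy_fit.ec50, rel=1e-12)

    def test_closed_form_hill_one(self):
        conc = np.geomspace(1, 1e4, 9)
        resp = _model4pl(conc, 0.0, 1.0, np.log(100.0), 1.0)
        fit = fit_4pl(plate(conc, resp))
        ec10 = ec_level(fit, 10.0)
        assert ec10.value == pytest.approx(100.0 * (10 / 90), rel=1e-6)

    def test_strictly_increasing_in_level(self, noisy_fit):
        values = [ec_level(noisy_fit, lv).value for lv in (5, 10, 25, 50, 75, 95)]
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("bad", [0.0, 100.0, -3.0, 120.0])
    def test_level_domain(self, noisy_fit, bad):
        with pytest.raises(ValueError):
            ec_level(noisy_fit, bad)

    def test_delta_ci_matches_parametric_bootstrap(self, noisy_fit):
        """First-order EC10 CI within 10% of a 2000-refit bootstrap CI."""
        fit = noisy_fit
        ec10 = ec_level(fit, 10.0)
        sample, _ = gen_yes_plate(true_ec50=820_000, hill=2.4, noise_cv=0.08,
                                  n_replicates=3, seed=7)
        conc = np.concatenate([s.concentrations for s in sample])
        pred = fit.predict(conc)
        cv = np.sqrt(fit.residual_ss / fit.dof)  # weighted fit: relative scatter
        rng = np.random.default_rng(11)
        p0 = (pred.min(), pred.max(),
              float(np.log(np.sqrt(conc.min() * conc.max()))), 1.0)
        draws = []
        for _ in range(2000):
            y = pred * (1 + rng.normal(0, cv, conc.size))
            popt, _ = optimize.curve_fit(_model4pl, conc, y, p0=p0, sigma=y,
                                         maxfev=20000, method="lm")
            fl, ce, lec, h = popt
            if ce < fl:
                fl, ce, h = ce, fl, -h
            if h > 0:
                draws.append(np.exp(lec) * (10 / 90) ** (1 / h))
        lo, hi = np.quantile(draws, [0.025, 0.975])
        boot_half = (hi - lo) / 2
        assert ec10.ci95_half == pytest.approx(boot_half, rel=0.10)

    def test_ec50_ci_coverage(self):
        """Delta-method 95% CI covers the true EC50 in >= 90% of noisy fits."""
        covered = 0
        n_sim = 200
        for ss in np.random.SeedSequence(555).spawn(n_sim):
            sample, _ = gen_yes_plate(true_ec50=820_000, hill=2.4, noise_cv=0.1,
                                      n_replicates=3, seed=ss)
            ec50 = ec_level(fit_4pl(sample), 50.0)
            if abs(ec50.value - 820_000) <= ec50.ci95_half:
                covered += 1
        assert covered / n_sim >= 0.90


class TestE2Equivalents:
    @pytest.fixture
    def pc_fit(self):
        _, pc = gen_yes_plate(true_ec50=820_000, hill=2.4, noise_cv=0.0,
                              n_replicates=1, seed=0, pc_ec50=82.0, pc_hill=1.5)
        return fit_4pl(pc)

    def test_diluted_standard_self_consistency(self, pc_fit):
        """A sample that is E2 at a known strength recovers that strength."""
        e2_strength = 140.0  # ng/L at relative concentration 1
        rel = 1.0 / 2.0 ** np.arange(10)[::-1]
        resp = pc_fit.predict(e2_strength * rel)
        result = e2_equivalents(plate(rel, resp), pc_fit)
        assert result.e2_eq.value == pytest.approx(e2_strength, rel=1e-6)

    def test_scaling_with_strength(self, pc_fit):
        """A 10x stronger sample recovers a 10x larger E2-EQ."""
        rel = 1.0 / 2.0 ** np.arange(10)[::-1]
        resp = pc_fit.predict(1400.0 * rel)
        result = e2_equivalents(plate(rel, resp), pc_fit)
        assert result.e2_eq.value == pytest.approx(1400.0, rel=1e-6)

    def test_below_effect_threshold(self, pc_fit):
        rel = 1.0 / 2.0 ** np.arange(7)[::-1]
        resp = 1.0 + 0.001 * rel + 1e-4 * np.arange(7)  # essentially no induction
        with pytest.raises(ValueError, match="below effect threshold"):
            e2_equivalents(plate(rel, resp), pc_fit)

    def test_ci_coverage_noisy_replicates(self, pc_fit):
        """E2-EQ CI covers the constructed truth in >= 90% of simulations."""
        truth = 140.0
        rel = 1.0 / 2.0 ** np.arange(10)[::-1]
        mean_resp = pc_fit.predict(truth * rel)
        sigma = np.sqrt(np.log(1 + 0.1**2))
        covered = 0
        n_sim = 200
        for ss in np.random.SeedSequence(808).spawn(n_sim):
            rng = np.random.default_rng(ss)
            series = [
                plate(rel, mean_resp * rng.lognormal(0, sigma, rel.size), f"r{k}")
                for k in range(3)
            ]
            res = e2_equivalents(series, pc_fit)
            if abs(res.e2_eq.value - truth) <= res.e2_eq.ci95_half:
                covered += 1
        assert covered / n_sim >= 0.90
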