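"""USP II simulation, P-PSD inversion, DE, f2 and crystallinity."""

import numpy as np
import pytest

import nanopbpk as npk
from nanopbpk.dissolution import (
    DissolutionMedium,
    DissolutionProfile,
    crystallinity_degree,
    dissolution_efficiency,
    f2_similarity,
    fit_ppsd,
    simulate_usp2,
)
from nanopbpk.psd import expand_psd
from nanopbpk.studies import DISSOLUTION_TIMES_MIN, SLS_025_MEDIUM

TIMES = np.array(DISSOLUTION_TIMES_MIN)


class TestCrystallinity:
    def test_raw_material_worked_example(self):
        assert crystallinity_degree(51.31, 1.0, 58.0) == pytest.approx(88.46, abs=0.01)

    def test_content_corrected_nanocrystal_example(self):
        assert crystallinity_degree(35.14, 0.9, 58.0) == pytest.approx(67.31, abs=0.02)

    def test_reference_enthalpy_is_fully_crystalline(self):
        assert crystallinity_degree(58.0, 1.0, 58.0) == 100.0

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            crystallinity_degree(50.0, 0.0, 58.0)


class TestF2:
    def _profile(self, values):
        return DissolutionProfile(TIMES, np.asarray(values, dtype=float))

    def test_identical_profiles_give_100(self):
        p = self._profile([10, 30, 50, 70, 80, 85, 90, 92, 93])
        assert f2_similarity(p, p) == pytest.approx(100.0)

    def test_constant_ten_point_offset_closed_form(self):
        a = self._profile([10, 20, 30, 40, 50, 55, 60, 65, 70])
        b = self._profile([20, 30, 40, 50, 60, 65, 70, 75, 80])
        expected = 50.0 * np.log10(100.0 / np.sqrt(1.0 + 100.0))
        assert f2_similarity(a, b) == pytest.approx(expected, abs=1e-9)
        assert f2_similarity(a, b) == pytest.approx(49.89, abs=0.01)

    def test_symmetry(self):
        a = self._profile([5, 15, 30, 55, 70, 80, 88, 91, 93])
        b = self._profile([12, 28, 45, 66, 78, 85, 90, 93, 95])
        assert f2_similarity(a, b) == pytest.approx(f2_similarity(b, a))

    def test_window_stops_at_joint_85_percent(self):
        # identical tails after both reach 85% must not inflate similarity
        a = self._profile([10, 30, 86, 90, 95, 96, 97, 97, 97])
        b = self._profile([40, 70, 88, 90, 95, 96, 97, 97, 97])
        full_msd_f2 = 50.0 * np.log10(100.0 / np.sqrt(1.0 + np.mean((a.percent_dissolved - b.percent_dissolved) ** 2)))
        assert f2_similarity(a, b) < full_msd_f2

    def test_mismatched_grids_rejected(self):
        a = self._profile([10] * 9)
        b = DissolutionProfile(TIMES + 1.0, np.full(9, 10.0))
        with pytest.raises(ValueError):
            f2_similarity(a, b)


class TestDE:
    def test_instant_release_is_100(self):
        p = DissolutionProfile(np.array([0.0, 50.0, 150.0]), np.array([100.0, 100.0, 100.0]))
        assert dissolution_efficiency(p, 150.0) == pytest.approx(100.0)

    def test_linear_rise_is_50(self):
        p = DissolutionProfile(np.array([0.0, 75.0, 150.0]), np.array([0.0, 50.0, 100.0]))
        assert dissolution_efficiency(p, 150.0) == pytest.approx(50.0)

    def test_invariant_to_redundant_collinear_points(self):
        t = np.array([0.0, 30.0, 60.0, 150.0])
        y = np.array([0.0, 40.0, 80.0, 80.0])
        base = dissolution_efficiency(DissolutionProfile(t, y), 150.0)
        t2 = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 100.0, 150.0])
        y2 = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 80.0, 80.0])
        assert dissolution_efficiency(DissolutionProfile(t2, y2), 150.0) == pytest.approx(base)

    def test_t_end_beyond_profile_rejected(self):
        p = DissolutionProfile(np.array([5.0, 10.0]), np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            dissolution_efficiency(p, 150.0)


class TestUSP2:
    def test_medium_solubility_arithmetic(self, drug):
        assert SLS_025_MEDIUM.solubility(drug) == pytest.approx(0.009 + 0.0755 * 8.7)
        assert SLS_025_MEDIUM.solubility(drug) == pytest.approx(0.66585)

    def test_submicron_sink_dissolves_at_first_sample(self, drug):
        psd = expand_psd(0.05, 1e-12, 1)  # 50 nm monodisperse
        prof = simulate_usp2(psd, drug, SLS_025_MEDIUM, 100.0, TIMES)
        assert prof.percent_dissolved[0] >= 99.9

    def test_mass_conservation(self, drug):
        psd = expand_psd(44.15, 42.5, 8)
        prof = simulate_usp2(psd, drug, SLS_025_MEDIUM, 100.0, TIMES)
        assert np.all(prof.percent_dissolved >= -1e-9)
        assert np.all(prof.percent_dissolved <= 100.0 + 1e-9)
        assert np.all(np.diff(prof.percent_dissolved) >= -1e-9)

    def test_non_sink_saturates_at_solubility(self, drug):
        medium = DissolutionMedium(volume=100.0, surfactant_conc=0.0)  # Cs*V = 0.9 mg
        psd = expand_psd(5.0, 2.0, 5)
        prof = simulate_usp2(psd, drug, medium, 100.0, TIMES)
        cap = medium.solubility(drug) * medium.volume / 100.0 * 100.0  # % of dose
        assert prof.percent_dissolved[-1] <= cap * 1.01

    def test_fine_step_reference_integration(self, drug):
        # independent oracle: explicit Euler at dt -> 0 for a monodisperse
        # bin, including the dissolved-concentration feedback on the
        # driving force
        r0, dose = 20.0, 50.0
        psd = expand_psd(r0, 1e-12, 1)
        cs = SLS_025_MEDIUM.solubility(drug)
        vol = SLS_025_MEDIUM.volume
        dt = 1e-4  # min
        m = dose
        t_grid = [0.0]
        masses = [m]
        d_cm2_min = drug.diff_coeff * 60.0
        t = 0.0
        while m > dose * 1e-4 and t < 150.0:
            r = r0 * (m / dose) ** (1 / 3)
            c = (dose - m) / vol
            rate = 3 * d_cm2_min * m * ((cs - c) * 1e-3) / (drug.density * (r * 1e-4) ** 2)
            m -= rate * dt
            t += dt
            t_grid.append(t)
            masses.append(max(m, 0.0))
        # time to 90% dissolved from the oracle
        pct_oracle = 100.0 * (1 - np.array(masses) / dose)
        t90_oracle = np.interp(90.0, pct_oracle, t_grid)
        sim = simulate_usp2(psd, drug, SLS_025_MEDIUM, dose, np.linspace(0.01, 30, 600))
        t90_sim = np.interp(90.0, sim.percent_dissolved, sim.times)
        assert t90_sim == pytest.approx(t90_oracle, rel=0.005)


class TestFitPPSD:
    @pytest.mark.parametrize("seed", [5, 17])
    def test_round_trip_recovery_under_one_percent_noise(self, drug, seed):
        # sampling includes early points so the fast-dissolving profile
        # constrains the distribution before it plateaus
        times = np.array([1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 30.0, 45.0, 60.0])
        truth = expand_psd(11.4, 7.15, 10)
        clean = simulate_usp2(truth, drug, SLS_025_MEDIUM, 100.0, times)
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(0.01**2))
        noisy = DissolutionProfile(
            times,
            np.clip(clean.percent_dissolved * np.exp(rng.normal(-sigma**2 / 2, sigma, times.shape)), 0, 105),
            medium=SLS_025_MEDIUM,
            dose=100.0,
        )
        rep = fit_ppsd(noisy, drug, n_bins=10)
        assert rep.psd.mean_radius == pytest.approx(11.4, rel=0.10)

    def test_zero_noise_fit_is_self_consistent(self, drug):
        truth = expand_psd(44.15, 42.5, 8)
        clean = simulate_usp2(truth, drug, SLS_025_MEDIUM, 100.0, TIMES)
        clean.medium = SLS_025_MEDIUM
        rep = fit_ppsd(clean, drug, n_bins=8, init=(30.0, 30.0))
        assert rep.afe == pytest.approx(1.0, abs=0.01)
        assert rep.aafe == pytest.approx(1.0, abs=0.01)

    def test_slow_profile_fits_larger_radius_than_fast(self, drug):
        slow = npk.make_dissolution_fixture("raw", noise_cv=0.0)
        fast = npk.make_dissolution_fixture("nc", noise_cv=0.0)
        rep_slow = fit_ppsd(slow, drug, n_bins=8)
        rep_fast = fit_ppsd(fast, drug, n_bins=10)
        assert rep_slow.psd.mean_radius > 3 * rep_fast.psd.mean_radius

    def test_degenerate_profile_rejected(self, drug):
        flat = DissolutionProfile(TIMES, np.zeros(9), medium=SLS_025_MEDIUM)
        with pytest.raises(ValueError):
            fit_ppsd(flat, drug)
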