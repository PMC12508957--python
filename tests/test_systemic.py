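"""Whole-body PBPK core: mass balance, linear oracles, elimination routes."""

import numpy as np
import pytest

import nanopbpk as npk
from nanopbpk.systemic import clearance_summary, michaelis_menten_rate, simulate_iv


class TestMichaelisMenten:
    def test_saturating_limit(self):
        assert michaelis_menten_rate(0.05, 3.914, 1e9) == pytest.approx(0.05, rel=1e-6)

    def test_zero_concentration(self):
        assert michaelis_menten_rate(0.1, 1.0, 0.0) == 0.0

    def test_half_saturation(self):
        assert michaelis_menten_rate(0.0517, 0.9035, 0.9035) == pytest.approx(0.02585)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            michaelis_menten_rate(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            michaelis_menten_rate(1.0, 0.0, 1.0)


class TestIVSimulation:
    def test_mass_balance_within_0p1_percent(self, rat_iv_2mgkg, rat_iv_5mgkg):
        assert rat_iv_2mgkg.mass_balance_error <= 1e-3
        assert rat_iv_5mgkg.mass_balance_error <= 1e-3

    def test_monotone_elimination_after_bolus(self, rat_iv_2mgkg):
        res = rat_iv_2mgkg
        body = sum(
            v for k, v in res.pools.items()
            if not (k.startswith("metabolized") or k == "renal_excreted")
        )
        assert np.all(np.diff(body) <= 1e-9 * res.dose)

    def test_superposition_in_linear_regime(self, drug, rat):
        lo = simulate_iv(drug, rat, dose=1e-3, duration=12.0)
        hi = simulate_iv(drug, rat, dose=2e-3, duration=12.0)
        mask = lo.plasma > lo.plasma.max() * 1e-3
        ratio = hi.plasma[mask] / lo.plasma[mask]
        assert np.allclose(ratio, 2.0, rtol=5e-3)

    def test_insignificant_renal_route(self, drug, rat, rat_iv_2mgkg):
        summ = clearance_summary(rat_iv_2mgkg)
        f = summ["fractions"]
        renal = f["renal_excreted"]
        metabolized = sum(v for k, v in f.items() if k.startswith("metabolized"))
        assert renal < 0.01 * metabolized

    def test_invalid_doses_rejected(self, drug, rat):
        with pytest.raises(ValueError):
            simulate_iv(drug, rat, dose=0.0)
        with pytest.raises(ValueError):
            simulate_iv(drug, rat, dose=1.0, duration=-1.0)


class TestOneCompartmentOracle:
    """With near-instant distribution and a fixed plasma clearance the whole
    body collapses to one compartment: C(t) = (D/Vss) * exp(-CL/Vss * t)."""

    @pytest.fixture()
    def fast_physiology(self, rat):
        p = rat.model_copy(deep=True)
        for t in p.tissues:
            t.blood_flow = t.blood_flow * 1000.0
        p.cardiac_output = p.cardiac_output * 1000.0
        p.renal_clearance_rule = "explicit:1.0"  # L/h plasma
        return p

    @pytest.fixture()
    def inert_drug(self, drug):
        d = drug.model_copy(deep=True)
        d.enzymes = {
            sp: [e.model_copy(update={"vmax": 0.0}) for e in enz]
            for sp, enz in d.enzymes.items()
        }
        return d

    def test_matches_analytic_solution(self, inert_drug, fast_physiology):
        dose = 0.7
        vss = npk.steady_state_vd(fast_physiology, inert_drug)
        cl = 1.0
        res = simulate_iv(inert_drug, fast_physiology, dose=dose, duration=6.0)
        k = cl / vss
        mask = res.time >= 0.25  # past the mixing transient
        analytic = dose / vss * np.exp(-k * res.time[mask]) * 1000.0  # ng/mL
        assert np.allclose(res.plasma[mask], analytic, rtol=1e-3)

    def test_clearance_summary_recovers_configured_cl(self, inert_drug, fast_physiology):
        res = simulate_iv(inert_drug, fast_physiology, dose=0.7, duration=24.0)
        assert clearance_summary(res)["cl_total"] == pytest.approx(1.0, rel=5e-3)

    def test_zero_elimination_auc_inf_not_estimable(self, inert_drug, fast_physiology):
        p = fast_physiology.model_copy(update={"renal_clearance_rule": "explicit:0.0"})
        res = simulate_iv(inert_drug, p, dose=0.7, duration=6.0)
        with pytest.raises(ValueError):
            clearance_summary(res)


class TestSteadyStateVd:
    def test_identity_case_all_kp_one(self, drug, rat):
        p = rat.model_copy(deep=True)
        for t in p.tissues:
            t.kp = 1.0
        d = drug.model_copy(deep=True)
        d.bp_ratio = {**d.bp_ratio, "rat": 1.0}
        expected = (
            p.venous_volume + p.arterial_volume + sum(t.volume for t in p.tissues)
        )
        assert npk.steady_state_vd(p, d) == pytest.approx(expected)

    def test_dose_normalised_iv_profiles_superpose(self, rat_iv_2mgkg, rat_iv_5mgkg):
        # mild saturation only: dose-normalised profiles within a few percent
        lo = rat_iv_2mgkg.plasma / rat_iv_2mgkg.dose
        hi = rat_iv_5mgkg.plasma / rat_iv_5mgkg.dose
        mask = lo > lo.max() * 0.01
        assert np.allclose(hi[mask], lo[mask], rtol=0.05)
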