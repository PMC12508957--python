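"""Fold-error statistics, NCA conventions and steady-state metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopbpk.metrics import (
    aafe,
    afe,
    fold_error,
    nca,
    steady_state_metrics,
    validation_report,
)


class TestFoldError:
    def test_printed_parameter_pairs(self):
        assert fold_error(560.4, 521.2) == pytest.approx(1.07, abs=0.01)
        assert fold_error(1086.8, 970.4) == pytest.approx(1.12, abs=0.01)

    def test_identity_and_error(self):
        assert fold_error(3.3, 3.3) == 1.0
        with pytest.raises(ValueError):
            fold_error(1.0, 0.0)


class TestAfeAafe:
    def test_self_comparison_is_exactly_one(self):
        pairs = [(x, x) for x in (1.0, 12.5, 970.4)]
        assert afe(pairs) == 1.0
        assert aafe(pairs) == 1.0

    def test_geometric_cancellation_and_absolute_symmetry(self):
        pairs = [(2.0, 1.0), (0.5, 1.0)]  # FEs {2, 0.5}
        assert afe(pairs) == pytest.approx(1.0, abs=1e-12)
        assert aafe(pairs) == pytest.approx(2.0, abs=1e-12)

    def test_three_fe_example(self):
        pairs = [(1.07, 1.0), (0.97, 1.0), (0.74, 1.0)]
        assert afe(pairs) == pytest.approx(0.916, abs=5e-4)

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 100.0), st.floats(0.01, 100.0)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_jensen_inequalities(self, pairs):
        a, aa = afe(pairs), aafe(pairs)
        assert aa >= 1.0 - 1e-12
        assert aa >= a - 1e-12
        assert aa >= 1.0 / a - 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            afe([])


def test_validation_pass_rule_boundaries():
    ok = validation_report([(1.0, 1.0), (1.5, 1.0), (0.7, 1.0)])
    assert ok.passed
    bad_fe = validation_report([(1.0, 1.0), (2.5, 1.0)])
    assert not bad_fe.passed
    # all FE individually inside [0.2, 2] but AAFE >= 2 fails
    bad_aafe = validation_report([(2.0, 1.0)] * 9 + [(0.2, 1.0)])
    assert not bad_aafe.passed


class TestNCA:
    def test_linear_up_rule_simple_triangle(self):
        r = nca([0.0, 1.0, 2.0], [0.0, 100.0, 0.0])
        # rising edge linear trapezoid = 50; AUC_t truncates at the last
        # positive concentration, so the zero tail adds nothing
        assert r.auc_t == pytest.approx(50.0)
        assert r.cmax == 100.0
        assert r.tmax == 1.0

    def test_monoexponential_closed_form(self):
        t = np.linspace(0.0, 60.0, 241)
        c = 100.0 * np.exp(-0.1 * t)
        r = nca(t, c)
        assert r.t_half == pytest.approx(math.log(2) / 0.1, rel=1e-3)
        assert r.auc_inf == pytest.approx(1000.0, rel=1e-3)
        assert r.lambda_z == pytest.approx(0.1, rel=1e-3)

    def test_auc_additive_over_partitions(self):
        t = np.linspace(0.0, 10.0, 101)
        c = 50.0 * np.exp(-0.3 * t) + 5.0
        full = nca(t, c).auc_t
        left = nca(t[:51], c[:51]).auc_t
        right = nca(t[50:], c[50:]).auc_t
        assert left + right == pytest.approx(full, rel=1e-12)

    def test_lambda_z_not_estimable_flags_absent(self):
        r = nca([0, 1, 2, 3, 4], [0.0, 10.0, 10.0, 10.0, 10.0])
        assert r.auc_inf is None
        assert r.t_half is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nca([0, 1], [1.0, 2.0])
        with pytest.raises(ValueError):
            nca([0, 1, 1], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            nca([0, 1, 2], [1.0, -2.0, 3.0])


class TestSteadyState:
    def test_flat_profile_zero_fluctuation(self):
        t = np.linspace(0, 48, 97)
        r = steady_state_metrics(t, np.full_like(t, 40.0), tau=24.0)
        assert r.fluctuation_index == 0.0
        assert r.cavg == pytest.approx(40.0)
        assert r.at_steady_state

    def test_one_compartment_superposition_oracle(self):
        # analytic steady-state superposition of q24h first-order oral dosing
        ka, ke, tau = 1.2, 0.15, 24.0
        fdv = 1000.0  # F*Dose/V in ng/mL
        t = np.linspace(0.0, tau, 2001)
        pref = fdv * ka / (ka - ke)
        css = pref * (
            np.exp(-ke * t) / (1 - math.exp(-ke * tau))
            - np.exp(-ka * t) / (1 - math.exp(-ka * tau))
        )
        r = steady_state_metrics(t, css, tau=tau)
        # closed forms for the same superposition
        auc_tau = fdv / ke  # equals single-dose AUC_inf at steady state
        tmax = math.log((ka * (1 - math.exp(-ke * tau))) / (ke * (1 - math.exp(-ka * tau)))) / (ka - ke)
        cmax = pref * (
            math.exp(-ke * tmax) / (1 - math.exp(-ke * tau))
            - math.exp(-ka * tmax) / (1 - math.exp(-ka * tau))
        )
        assert r.auc_tau == pytest.approx(auc_tau, rel=0.01)
        assert r.cmax_ss == pytest.approx(cmax, rel=0.01)
        assert r.ctrough <= r.cavg <= r.cmax_ss

    def test_interval_not_covered_rejected(self):
        with pytest.raises(ValueError):
            steady_state_metrics([0, 1, 2], [1, 2, 3], tau=24.0)
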