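"""Shared fixtures: packaged records and session-cached simulations.

The oral PBBM runs take seconds each; every test that needs the canonical
study arms (rat NC / rat raw suspension, human 350 mg NC) reuses one
session-scoped simulation instead of re-integrating.
"""

from __future__ import annotations

import numpy as np
import pytest

import nanopbpk as npk
from nanopbpk.metrics import nca
from nanopbpk.studies import build_scenario


@pytest.fixture(scope="session")
def drug():
    return npk.builtin_drug()


@pytest.fixture(scope="session")
def rat():
    return npk.builtin_physiology("rat")


@pytest.fixture(scope="session")
def human():
    return npk.builtin_physiology("human")


@pytest.fixture(scope="session")
def rat_iv_2mgkg(drug, rat):
    return npk.simulate_iv(drug, rat, dose=2.0 * rat.body_weight, duration=24.0)


@pytest.fixture(scope="session")
def rat_iv_5mgkg(drug, rat):
    return npk.simulate_iv(drug, rat, dose=5.0 * rat.body_weight, duration=24.0)


@pytest.fixture(scope="session")
def rat_po_nc(drug, rat):
    _, _, _, form = build_scenario("rat_po_nc")
    return npk.simulate_oral(drug, rat, form, duration=10.0)


@pytest.fixture(scope="session")
def rat_po_raw(drug, rat):
    _, _, _, form = build_scenario("rat_po_raw")
    return npk.simulate_oral(drug, rat, form, duration=10.0)


@pytest.fixture(scope="session")
def human_po_nc(drug, human):
    sc, _, _, form = build_scenario("human_po_nc_350mg")
    return npk.simulate_oral(drug, human, form, duration=sc.duration, dt_out=0.05)


@pytest.fixture(scope="session")
def rat_po_nc_nca(rat_po_nc):
    res, _ = rat_po_nc
    return nca(res.time, res.plasma)


@pytest.fixture(scope="session")
def rat_po_raw_nca(rat_po_raw):
    res, _ = rat_po_raw
    return nca(res.time, res.plasma)


@pytest.fixture(scope="session")
def human_po_nc_nca(human_po_nc):
    res, _ = human_po_nc
    return nca(res.time, res.plasma)
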