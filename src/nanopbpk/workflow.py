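"""End-to-end workflow: i.v. development, oral refinement, extrapolation.

``compute_core_outputs`` runs the deterministic backbone (crystallinity
arithmetic, rat i.v. PBPK, rat oral PBBM with the fitted P-PSDs, human
extrapolation, distribution volumes) and returns the headline quantities.
``reproduce_study`` chains every stage of the modelling workflow —
including P-PSD fitting on dissolution fixtures, the rat population
simulation, human multiple-dose steady state and the sensitivity sweeps —
into one consolidated report; each stage is isolated so one failure does
not abort the rest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .absorption import simulate_oral
from .config import builtin_drug, builtin_physiology
from .dissolution import (
    crystallinity_degree,
    dissolution_efficiency,
    f2_similarity,
    fit_ppsd,
)
from .metrics import nca, steady_state_metrics
from .population import VariabilitySpec, coverage_check, run_population
from .sensitivity import DEFAULT_SWEEPS, PSAConfig, rank_sensitivities, run_psa
from .studies import build_scenario
from .synthetic import make_dissolution_fixture, make_observed_pk
from .systemic import simulate_iv, steady_state_vd

__all__ = ["compute_core_outputs", "reproduce_study", "RunManifest"]


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: int | None
    package_version: str
    config_hashes: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    @staticmethod
    def hash_file(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def compute_core_outputs(seed: int = 0) -> dict[str, float]:
    """Deterministic headline outputs of the packaged models.

    Crystallinity worked examples, rat i.v. AUC_inf at both dose levels and
    the dose-normalised ratio, the distribution volumes of both species,
    the rat oral nanocrystal/raw-material exposure, and the single-dose
    human nanocrystal simulation.  ``seed`` is accepted for interface
    symmetry; every quantity here is deterministic.
    """
    out: dict[str, float] = {}
    out["crystallinity_raw_pct"] = crystallinity_degree(51.31, 1.0, 58.0)
    out["crystallinity_nc_pct"] = crystallinity_degree(35.14, 0.9, 58.0)

    drug = builtin_drug()
    rat = builtin_physiology("rat")
    human = builtin_physiology("human")
    out["rat_vss_l"] = steady_state_vd(rat, drug)
    out["human_vss_l"] = steady_state_vd(human, drug)

    res2 = simulate_iv(drug, rat, dose=2.0 * rat.body_weight, duration=24.0)
    res5 = simulate_iv(drug, rat, dose=5.0 * rat.body_weight, duration=24.0)
    n2 = nca(res2.time, res2.plasma)
    n5 = nca(res5.time, res5.plasma)
    out["rat_iv_aucinf_2mgkg"] = n2.auc_inf
    out["rat_iv_aucinf_5mgkg"] = n5.auc_inf
    out["rat_iv_auc_ratio"] = n5.auc_inf / n2.auc_inf

    _, _, _, form_nc = build_scenario("rat_po_nc")
    _, _, _, form_raw = build_scenario("rat_po_raw")
    res_nc, _ = simulate_oral(drug, rat, form_nc, duration=10.0)
    res_raw, _ = simulate_oral(drug, rat, form_raw, duration=10.0)
    nn, nr = nca(res_nc.time, res_nc.plasma), nca(res_raw.time, res_raw.plasma)
    out["rat_po_nc_cmax"] = nn.cmax
    out["rat_po_nc_auct"] = nn.auc_t
    out["rat_po_raw_cmax"] = nr.cmax
    out["rat_po_raw_auct"] = nr.auc_t

    sc, _, _, form_h = build_scenario("human_po_nc_350mg")
    res_h, _ = simulate_oral(drug, human, form_h, duration=sc.duration, dt_out=0.05)
    nh = nca(res_h.time, res_h.plasma)
    out["human_nc_cmax"] = nh.cmax
    out["human_nc_auct"] = nh.auc_t
    out["human_nc_tmax"] = nh.tmax
    return out


def _stage(report: dict, name: str, fn) -> None:
    t0 = time.perf_counter()
    try:
        report["stages"][name] = {"status": "ok", "result": fn()}
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
    report["stages"][name]["wall_time_s"] = round(time.perf_counter() - t0, 2)


def reproduce_study(
    seed: int = 0,
    include_population: bool = True,
    include_steady_state: bool = True,
    include_psa: bool = True,
    psa_tests: int = 7,
) -> dict:
    """Run the full modelling workflow and return a consolidated report.

    Stage failures are recorded per stage and do not interrupt the others.
    Stochastic stages derive their streams from ``seed``; rerunning with
    the same seed reproduces the report values exactly.
    """
    report: dict = {"seed": seed, "stages": {}}

    _stage(report, "core_outputs", lambda: compute_core_outputs(seed))

    def ppsd_stage():
        drug = builtin_drug()
        out = {}
        nc_fix = make_dissolution_fixture("nc", noise_cv=1.0, seed=seed)
        raw_fix = make_dissolution_fixture("raw", noise_cv=1.0, seed=seed + 1)
        fit_nc = fit_ppsd(nc_fix, drug, n_bins=10)
        fit_raw = fit_ppsd(raw_fix, drug, n_bins=8)
        out["nc_fitted_mean_radius_um"] = fit_nc.psd.mean_radius
        out["raw_fitted_mean_radius_um"] = fit_raw.psd.mean_radius
        out["nc_fit_aafe"] = fit_nc.aafe
        out["raw_fit_aafe"] = fit_raw.aafe
        out["nc_de_pct"] = dissolution_efficiency(nc_fix, 150.0)
        out["raw_de_pct"] = dissolution_efficiency(raw_fix, 150.0)
        out["f2_raw_vs_nc"] = f2_similarity(raw_fix, nc_fix)
        return out

    _stage(report, "ppsd_fitting", ppsd_stage)

    if include_population:

        def population_stage():
            _, drug, rat, form = build_scenario("rat_po_nc")
            spec = VariabilitySpec(seed=seed)
            pop = run_population(drug, rat, form, n=7, repeats=10, spec=spec, duration=10.0)
            obs = make_observed_pk("rat_po_nc", noise_cv=20.0, n_subjects=7, seed=seed + 2)
            cov = coverage_check(
                obs["time_h"].to_numpy(), obs["conc_ng_ml"].to_numpy(), pop
            )
            return {
                "n_subjects": pop.n_subjects,
                "n_failures": len(pop.failures),
                "coverage_5_95": cov,
                "median_cmax": float(np.median([r.cmax for r in pop.nca_results])),
            }

        _stage(report, "population", population_stage)

    if include_steady_state:

        def steady_state_stage():
            out = {}
            for name, label in [
                ("human_po_nc_350mg", "nc_350mg"),
                ("human_po_tablet_600mg", "tablet_600mg"),
            ]:
                _, drug, human, form = build_scenario(name)
                res, _ = simulate_oral(
                    drug, human, form, duration=15 * 24.0, dt_out=0.1,
                    n_doses=15, tau=24.0, rtol=1e-5, atol=1e-7,
                )
                ss = steady_state_metrics(res.time, res.plasma, tau=24.0)
                out[label] = {
                    "cmax_ss": ss.cmax_ss,
                    "ctrough": ss.ctrough,
                    "cavg": ss.cavg,
                    "auc_tau": ss.auc_tau,
                    "fluctuation_pct": ss.fluctuation_index,
                    "at_steady_state": ss.at_steady_state,
                }
            return out

        _stage(report, "steady_state", steady_state_stage)

    if include_psa:

        def psa_stage():
            _, drug, rat, form = build_scenario("rat_po_nc")
            results = []
            for cfg in DEFAULT_SWEEPS.values():
                cfg_small = PSAConfig(
                    cfg.parameter, cfg.minimum, cfg.baseline, cfg.maximum, psa_tests
                )
                results.append(run_psa(drug, rat, form, cfg_small, duration=10.0))
            ranked = rank_sensitivities(results)
            return {
                "ranking": [r.parameter for r in ranked],
                "range_ratios": {r.parameter: r.range_ratio() for r in ranked},
                "cmax_monotone_in_radius": bool(
                    np.all(np.diff(next(r for r in results if r.parameter == "mean_radius").cmax) <= 1e-9)
                ),
            }

        _stage(report, "psa", psa_stage)

    report["n_failed"] = sum(1 for s in report["stages"].values() if s["status"] == "failed")
    return report
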