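"""Noncompartmental analysis and fold-error validation statistics.

Implements the conventional NCA parameter set (Cmax, tmax, AUC by
linear-up/log-down trapezoid, terminal slope by log-linear regression,
AUC extrapolated to infinity) and the ratio-based prediction-accuracy
statistics used to validate PBPK simulations against observed data:

    FE_i  = predicted_i / observed_i
    AFE   = 10 ** mean(log10 FE_i)        (bias; under/over-prediction)
    AAFE  = 10 ** mean(|log10 FE_i|)      (absolute accuracy)

A simulation is conventionally accepted when every FE lies in [0.2, 2]
and both AFE and AAFE are below 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "fold_error",
    "afe",
    "aafe",
    "validation_report",
    "ValidationReport",
    "nca",
    "NCAResult",
    "steady_state_metrics",
    "SteadyStateResult",
]


def fold_error(predicted: float, observed: float) -> float:
    """Ratio of predicted to observed; the per-point accuracy measure."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return predicted / observed


def _fold_errors(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    if len(pairs) == 0:
        raise ValueError("at least one (predicted, observed) pair required")
    fes = np.array([fold_error(p, o) for p, o in pairs], dtype=float)
    if np.any(fes <= 0):
        raise ValueError("fold errors must be positive (predicted > 0 required)")
    return fes


def afe(pairs: Sequence[tuple[float, float]]) -> float:
    """Average fold error: geometric mean of the per-point fold errors."""
    return float(10 ** np.mean(np.log10(_fold_errors(pairs))))


def aafe(pairs: Sequence[tuple[float, float]]) -> float:
    """Absolute average fold error: 10 ** mean(|log10 FE|); always >= 1."""
    return float(10 ** np.mean(np.abs(np.log10(_fold_errors(pairs)))))


@dataclass
class ValidationReport:
    """Per-point fold errors with summary statistics and the pass rule."""

    fe: list[float]
    afe: float
    aafe: float
    passed: bool

    @property
    def n(self) -> int:
        return len(self.fe)


def validation_report(pairs: Sequence[tuple[float, float]]) -> ValidationReport:
    """FE/AFE/AAFE over (predicted, observed) pairs plus the acceptance flag.

    Pass rule: every FE in [0.2, 2] and AFE < 2 and AAFE < 2.
    """
    fes = _fold_errors(pairs)
    a, aa = afe(pairs), aafe(pairs)
    passed = bool(np.all((fes >= 0.2) & (fes <= 2.0)) and a < 2.0 and aa < 2.0)
    return ValidationReport(fe=[float(f) for f in fes], afe=a, aafe=aa, passed=passed)


@dataclass
class NCAResult:
    cmax: float  # ng/mL
    tmax: float  # h
    auc_t: float  # ng*h/mL, to last quantifiable point
    auc_inf: Optional[float]  # ng*h/mL; None when lambda_z not estimable
    lambda_z: Optional[float]  # 1/h
    t_half: Optional[float]  # h
    lambda_z_points: int = 3


def _auc_linear_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """Trapezoidal AUC, linear when concentration rises, log when it falls."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def nca(
    times: Sequence[float],
    conc: Sequence[float],
    dose: float | None = None,
    lambda_z_points: int = 3,
) -> NCAResult:
    """Noncompartmental analysis of a concentration-time profile.

    Parameters
    ----------
    times, conc : sequences
        Sampling times (h) and plasma concentrations (ng/mL).  Times must be
        strictly increasing; concentrations non-negative.
    dose : float, optional
        Administered dose (mg); retained for clearance bookkeeping by callers.
    lambda_z_points : int
        Number of terminal points for the log-linear terminal-slope fit.

    AUC_t uses the linear-up/log-down trapezoid to the last positive
    concentration.  AUC_inf = AUC_t + C_last/lambda_z; when the terminal fit
    is not estimable (fewer than the requested positive terminal points, or a
    non-declining tail) AUC_inf, lambda_z and t_half are reported absent.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 3:
        raise ValueError("need >= 3 matching time/concentration points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])

    # truncate at last positive concentration
    pos = np.nonzero(c > 0)[0]
    if len(pos) == 0:
        return NCAResult(0.0, float(t[0]), 0.0, None, None, None, lambda_z_points)
    last = pos[-1]
    auc_t = _auc_linear_up_log_down(t[: last + 1], c[: last + 1])

    lam = None
    tail = np.nonzero((c > 0) & (np.arange(len(c)) > imax))[0]
    if len(tail) >= lambda_z_points:
        idx = tail[-lambda_z_points:]
        slope, _ = np.polyfit(t[idx], np.log(c[idx]), 1)
        if slope < 0:
            lam = float(-slope)

    if lam is None:
        return NCAResult(cmax, tmax, float(auc_t), None, None, None, lambda_z_points)
    auc_inf = float(auc_t + c[last] / lam)
    return NCAResult(cmax, tmax, float(auc_t), auc_inf, lam, float(math.log(2) / lam), lambda_z_points)


@dataclass
class SteadyStateResult:
    cmax_ss: float  # ng/mL
    ctrough: float  # ng/mL
    cavg: float  # ng/mL, AUC_tau / tau
    auc_tau: float  # ng*h/mL
    fluctuation_index: float  # %
    at_steady_state: bool = True
    interval_start: float = 0.0
    drift: float = field(default=0.0)  # relative AUC change between last two intervals


def steady_state_metrics(
    times: Sequence[float],
    conc: Sequence[float],
    tau: float,
    drift_tolerance: float = 0.05,
) -> SteadyStateResult:
    """Multiple-dose metrics over the final complete dosing interval.

    The profile must cover at least one full interval of length ``tau``
    ending at the last sample.  Fluctuation index = (Cmax,ss - Ctrough) /
    Cavg * 100.  When the profile covers two or more intervals and the AUC
    of the final interval differs from the preceding one by more than
    ``drift_tolerance`` (relative), the result is flagged as not at steady
    state (a warning flag, not an error).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t[-1] - t[0] + 1e-9 < tau:
        raise ValueError("profile does not cover one dosing interval")

    def interval_auc(t0: float, t1: float) -> float:
        m = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        return _auc_linear_up_log_down(t[m], c[m])

    t_end = t[-1]
    t_start = t_end - tau
    m = (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
    ti, ci = t[m], c[m]
    auc_tau = interval_auc(t_start, t_end)
    cavg = auc_tau / tau
    cmax_ss = float(np.max(ci))
    ctrough = float(min(ci[0], ci[-1]))
    fi = (cmax_ss - ctrough) / cavg * 100.0 if cavg > 0 else 0.0

    drift = 0.0
    at_ss = True
    if t_end - t[0] + 1e-9 >= 2 * tau:
        prev = interval_auc(t_start - tau, t_start)
        if prev > 0:
            drift = abs(auc_tau - prev) / prev
            at_ss = drift <= drift_tolerance
    return SteadyStateResult(
        cmax_ss=cmax_ss,
        ctrough=ctrough,
        cavg=float(cavg),
        auc_tau=float(auc_tau),
        fluctuation_index=float(fi),
        at_steady_state=at_ss,
        interval_start=float(t_start),
        drift=float(drift),
    )
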