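"""Particle size distributions for dissolution modelling.

A product particle size distribution (P-PSD) is summarised by the arithmetic
mean and standard deviation of particle radius, interpreted as the first two
moments of a log-normal distribution of (mass-weighted) radius.  For
simulation the continuous distribution is discretised into a small number of
equal-mass bins, each represented by a single radius.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import PSD

__all__ = ["expand_psd", "lognormal_params_from_moments"]


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Return (mu, sigma) of ln(R) for a log-normal with arithmetic mean/SD.

    sigma^2 = ln(1 + (sd/mean)^2),  mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    sigma = float(np.sqrt(sigma2))
    mu = float(np.log(mean) - sigma2 / 2.0)
    return mu, sigma


def expand_psd(mean_radius: float, sd_radius: float, n_bins: int) -> PSD:
    """Discretise a log-normal radius distribution into equal-mass bins.

    Parameters
    ----------
    mean_radius, sd_radius : float
        Arithmetic mean and standard deviation of particle radius (um).
    n_bins : int
        Number of equal mass-fraction bins.

    Each bin carries mass fraction 1/n_bins at the conditional mean radius of
    its quantile slice.  Conditional means reproduce the arithmetic mean
    exactly; the between-bin SD slightly underestimates the continuous SD, so
    a single linear rescale of the radii about the mean is applied to make
    both reconstructed moments exact.  Radii are strictly positive and
    increasing.
    """
    if mean_radius <= 0 or sd_radius < 0 or n_bins < 1:
        raise ValueError("mean_radius > 0, sd_radius >= 0 and n_bins >= 1 required")

    # Degenerate (monodisperse) distribution.
    if n_bins == 1 or sd_radius / mean_radius < 1e-6:
        radii = np.full(n_bins, float(mean_radius))
        # Monodisperse: spread identical radii with infinitesimal increments so
        # the "strictly increasing" contract holds.
        radii = radii * (1.0 + 1e-12 * np.arange(n_bins))
        fracs = np.full(n_bins, 1.0 / n_bins)
        return PSD(
            mean_radius=mean_radius,
            sd_radius=sd_radius,
            n_bins=n_bins,
            bins=[(float(r), float(f)) for r, f in zip(radii, fracs)],
        )

    mu, sigma = lognormal_params_from_moments(mean_radius, sd_radius)
    q = np.linspace(0.0, 1.0, n_bins + 1)
    z = stats.norm.ppf(q)  # includes -inf/+inf endpoints

    # E[R | slice] for log-normal: e^{mu+sigma^2/2} * dPhi(z-sigma)/dPhi(z)
    phi_hi = stats.norm.cdf(z[1:] - sigma)
    phi_lo = stats.norm.cdf(z[:-1] - sigma)
    radii = mean_radius * (phi_hi - phi_lo) * n_bins

    # Moment correction: exact mean is preserved by conditional means up to
    # floating error; rescale spread so the discrete SD matches sd_radius.
    m = float(np.mean(radii))
    s = float(np.std(radii))
    if s > 0:
        radii = m + (radii - m) * (sd_radius / s)
    radii = radii + (mean_radius - float(np.mean(radii)))
    if np.any(radii <= 0):
        # Very heavy-tailed inputs: fall back to uncorrected conditional means
        # (mean still exact, SD conservative).
        radii = mean_radius * (phi_hi - phi_lo) * n_bins

    fracs = np.full(n_bins, 1.0 / n_bins)
    return PSD(
        mean_radius=mean_radius,
        sd_radius=sd_radius,
        n_bins=n_bins,
        bins=[(float(r), float(f)) for r, f in zip(radii, fracs)],
    )
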