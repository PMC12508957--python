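"""Inverse P-PSD fitting: recover a particle size distribution from a
dissolution profile, plus the standard in vitro comparison metrics."""

import numpy as np

import nanopbpk as npk
from nanopbpk.dissolution import DissolutionProfile
from nanopbpk.psd import expand_psd
from nanopbpk.studies import SLS_025_MEDIUM

drug = npk.builtin_drug()

# round trip: simulate a USP II profile from a known PSD (11.4 +/- 7.15 um,
# 0.25% SLS, 100 mg / 900 mL), add 1% noise, and invert it back
times = np.array([1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 30.0, 45.0, 60.0])
clean = npk.simulate_usp2(expand_psd(11.4, 7.15, 10), drug, SLS_025_MEDIUM, 100.0, times)
rng = np.random.default_rng(42)
sigma = np.sqrt(np.log1p(0.01**2))
noisy = DissolutionProfile(
    times,
    np.clip(clean.percent_dissolved * np.exp(rng.normal(-sigma**2 / 2, sigma, times.shape)), 0, 105),
    medium=SLS_025_MEDIUM,
    dose=100.0,
)
fit = npk.fit_ppsd(noisy, drug, n_bins=10)
print(
    f"recovered P-PSD: mean radius {fit.psd.mean_radius:.1f} um (true 11.4), "
    f"SD {fit.psd.sd_radius:.1f} um (true 7.15); fit AFE {fit.afe:.3f}, AAFE {fit.aafe:.3f}"
)

# in vitro comparison metrics on the packaged synthetic fixtures
nc = npk.make_dissolution_fixture("nc", noise_cv=1.0, seed=42)
raw = npk.make_dissolution_fixture("raw", noise_cv=1.0, seed=43)

de_nc = npk.dissolution_efficiency(nc, 150.0)
de_raw = npk.dissolution_efficiency(raw, 150.0)
print(f"dissolution efficiency: nanocrystals {de_nc:.1f}%, raw material {de_raw:.1f}%")
print(f"f2 similarity raw vs nanocrystals: {npk.f2_similarity(raw, nc):.1f} (<50 = dissimilar)")
print(f"crystallinity from fusion enthalpy 35.14 J/g at 90% content: "
      f"{npk.crystallinity_degree(35.14, 0.9, 58.0):.2f}%")
# The inversion recovers the generating distribution from the noisy curve;
# DE separates the fast and slow formulations, and f2 < 50 confirms their
# release behaviours are statistically different.
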