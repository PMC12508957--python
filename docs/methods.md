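# Methods

`nanopbpk` implements a mechanistic physiologically based pharmacokinetic
(PBPK) model with a biopharmaceutics-driven oral absorption stage (PBBM)
for efavirenz, parameterised for the rat and for a fasted adult human, and
the surrounding analysis toolchain: in vitro dissolution simulation and
inverse P-PSD fitting, noncompartmental analysis with fold-error
validation statistics, virtual-population simulation and one-at-a-time
parameter sensitivity analysis.

## Whole-body disposition model

Thirteen perfusion-limited tissues (lung, adipose, muscle, liver, spleen,
heart, brain, kidney, skin, reproductive organs, red and yellow marrow,
rest of body) plus venous and arterial blood pools. For tissue *t* with
volume *V_t* (L), blood flow *Q_t* (L/h) and tissue:plasma partition
coefficient *Kp_t*,

    dA_t/dt = Q_t (C_art − C_t · BP / Kp_t),

where *C_t = A_t/V_t*, *BP* is the blood:plasma ratio, and venous blood
leaving the tissue is in equilibrium with it. The lung receives the full
cardiac output between the venous and arterial pools; the spleen drains
through the liver. Plasma concentrations are blood concentrations divided
by *BP*; red-cell partitioning is carried by *BP* only (no explicit
erythrocyte compartment).

**Hepatic metabolism.** Whole-organ Michaelis–Menten kinetics per enzyme
(rat: CYP2B2 and CYP3A9 in liver, CYP3A9 in gut; human: CYP2B6 in liver,
CYP3A4 in liver and gut), with Vmax in mg/s and Km in mg/L. The driving
concentration is the unbound venous-plasma-equivalent concentration at the
liver exit, `Cu = fup · C_liver / Kp_liver`. This convention is isolated
in one function (`SystemicCore.hepatic_driving_conc`) and can be switched
to an unbound-tissue convention (`fup · C_liver`); commercial tools do not
publish their exact convention, and the choice interacts with the
effective hepatic flow calibration below. At study doses the default
convention keeps hepatic metabolism essentially linear (the simulated
2→5 mg/kg AUC ratio is 2.51 against 2.50 for perfect proportionality),
which matches the reported behaviour.

**Renal elimination.** Plasma clearance `fup · GFR` applied to arterial
plasma (negligible for efavirenz: <0.1% of total elimination, consistent
with the compound's known insignificant renal clearance). An explicit
clearance override (`renal_clearance_rule: "explicit:<L/h>"`) exists
because published human summaries quote a renal clearance that is
numerically inconsistent with `fup · GFR`; the default rule is the
mechanistic one.

**Distribution volume.** `steady_state_vd` returns the plasma-referenced
volume `BP · V_blood + Σ Kp_t V_t`.

### Physiology calibration (one-time, frozen)

Tissue volumes and flows are not part of the compound dataset, so the
packaged species tables start from standard literature values scaled
linearly with body weight and are calibrated once against the systemic
outputs of the model being reproduced, then frozen in `data/rat.yaml` and
`data/human.yaml`:

* **Rat lipid depots.** With literature rat adiposity the published
  Poulin–Theil Kp set (adipose 69.58, yellow marrow 69.59) would give
  Vss ≈ 3.4 L for a 0.35 kg rat — twice the reported 1.672 L. Adipose and
  yellow-marrow volumes are therefore treated as effective parameters
  (2.0 mL and 0.6 mL) chosen so Vss matches; all other volumes are
  standard.
* **Rat hepatic flow.** The rat's observed plasma clearance (≈1.41 L/h
  from dose/AUC) exceeds what the printed enzyme kinetics can deliver at
  literature hepatic perfusion under the default driving-concentration
  convention (the well-stirred ceiling `fup · Vmax/Km` ≈ 1.9 L/h is
  approached only at high flow). Hepatic blood flow is therefore an
  effective calibrated parameter (5.9 L/h, with the remaining tissues at
  literature flows and the cardiac output set to the venous return). The
  model remains internally consistent (flow balance holds exactly); the
  price is a deliberately non-physiological liver flow standing in for
  whatever extrahepatic or flow-convention differences the original
  software embodied.
* **Human volumes.** Standard adult tissue volumes reproduce the reported
  Vss = 746.6 L with only a mild adipose adjustment (18.94 L at 67.73 kg);
  flows are standard fractions of a 325 L/h cardiac output.

## Oral absorption (ACAT-style PBBM)

Nine luminal compartments (stomach, duodenum, jejunum ×2, ileum ×3,
caecum, ascending colon) with first-order transit at `1/transit_time`.
Suspensions and solutions empty the stomach with a 0.1 h transit (the
standard single-simulation convention for suspensions); tablets use the
fasted default (0.25 h).

**Particle population.** Solid drug is carried per compartment and size
bin as particle *mass and number*; transit moves both together (exactly
conserving the mass/number ratio), dissolution shrinks per-particle mass
at constant number, and the bin radius follows from per-particle mass.
Dissolution uses the Wang–Flanagan/Noyes–Whitney diffusion-layer rate

    dm/dt = −3 D m (Cs − C) / (ρ r h),   h = min(r, 30 μm),

so particles below the 30 μm film cap gain rate as 1/r² — the mechanism
that makes micronisation and nanosizing effective. The radius is floored
at 1% of the bin's initial radius, which converts the non-Lipschitz
m^(1/3) extinction into a linear decay over the final ~10⁻⁶ of each bin
(no measurable mass error; removes solver thrash); the per-mass rate
constant is additionally capped at 10⁴/h — real bins stay below ~2×10³/h,
so only dust-level floored bins are affected, and a bin emptying within a
fraction of a second is dynamically equivalent. In multiple-dose runs,
solid residues below 10⁻⁹ of one dose are dissolved in place at each dose
boundary (mass-conserving) so dust states cannot accumulate across
segments. Precipitation is
disabled by default: efavirenz (pKa 10.2, acid) is non-ionisable across
GI pH and supersaturation is not modelled.

**Luminal solubility.** pH-adjusted aqueous solubility (effectively flat
for efavirenz) plus a linear bile-salt term with coefficient calibrated so
the fasted biorelevant point is exact (0.182 mg/mL at 3 mM
taurocholate-equivalent) and the fed point is within ~3% (0.874 vs
0.847 mg/mL at 15 mM). Per-compartment bile concentrations taper from
~3 mM in the duodenum to 0 in the colon. The nano effect factor (1.381)
multiplies solubility for bins at or below a 1 μm radius threshold (flat
mode, the factor being specified as a set scalar); an Ostwald–Freundlich
mode, `exp(2γVm/(rRT))` capped at the factor, exists for exploration.

**Absorption and first pass.** Passive flux `Peff · (SA/V) · C · V` per
absorptive compartment (stomach excluded, colon at reduced SA/V) into a
lumped enterocyte pool where gut-sited enzymes apply Michaelis–Menten
metabolism before portal delivery into the liver compartment. The
per-compartment SA/V scale factors were calibrated once per species — the
rat set against the reported oral nanocrystal Cmax, the human set against
the reported single-dose human simulation — and then frozen; they absorb
the proprietary absorption-scale-factor model of the original software.
Gut first pass is saturable and matters in the rat (Fg ≈ 0.7 at 20 mg/kg)
but is negligible in the human (Fg ≈ 1).

**Numerics.** The coupled system (≈230 states with 10 bins) is integrated
with BDF using an analytic dense Jacobian, rtol 10⁻⁶ / atol 10⁻⁸ mg
(results agree with an rtol 10⁻⁷ LSODA reference to five significant
digits); the i.v.-only system uses LSODA at rtol 10⁻⁷ / atol 10⁻⁹ mg with
an output grid densified near t = 0 so NCA does not over-integrate the
bolus mixing transient. Mass balance (lumen + enterocyte + body + feces +
eliminated vs dose) is audited at every output point and stays at machine
precision, far inside the 0.1% contract.

## In vitro dissolution and P-PSD inversion

A single well-stirred USP II vessel with the same per-bin rate law;
solubility = aqueous + Kaff × surfactant (0.0755 mg/mL/mM for SLS, so
0.666 mg/mL in 0.25% SLS — sink for 100 mg/900 mL). `fit_ppsd` inverts an
observed % dissolved profile into (mean radius, radius SD) of an
equal-mass binned log-normal by trust-region least squares on log
parameters, three deterministic starts to avoid local minima, reporting
AFE/AAFE/RMSE of the fit. Round trip at 1% noise recovers the mean radius
within ~3%.

The PSD discretisation uses equal-probability-mass quantile bins at their
conditional mean radii, followed by one linear rescale of the radii about
the mean so the discrete mean *and* SD match the requested moments
exactly; for extremely heavy tails (CV ≳ 1.3) where that rescale would
drive radii negative, the uncorrected conditional means are used (mean
exact, SD conservative).

Dissolution efficiency is the trapezoidal area of % dissolved over
[0, t_end] relative to complete dissolution (a (0, 0) point is assumed
when absent). The f2 similarity factor uses all common points up to and
including the first at which both profiles reach 85% release — the
standard regulatory plateau rule; ≥3 points are required.

## Validation statistics and NCA

FE = predicted/observed per point; AFE is the geometric mean of FEs
(bias), AAFE = 10^mean|log₁₀FE| (absolute accuracy); a simulation passes
when all FE ∈ [0.2, 2] and AFE, AAFE < 2. NCA follows the common
WinNonlin-style conventions: Cmax/tmax by direct lookup,
linear-up/log-down trapezoid to the last positive concentration, λz by
log-linear regression on the last three post-peak points (user-
overridable), AUC∞ = AUC_t + C_last/λz, flagged absent when the tail is
not estimable. Both per-point (profile validation) and per-parameter
(table reproduction) fold-error entry points exist.

## Synthetic "observed" data — what passing tests show

The observed in vivo and in vitro curves behind this model exist in print
only as figures, so the generators in `nanopbpk.synthetic` produce
model-self-consistent stand-ins: USP II profiles simulated from the
fitted P-PSDs with multiplicative log-normal noise, and plasma datasets
sampled from the packaged scenarios at the reported schedule with
per-point residuals. Two generation choices emulate real-data features
the raw simulation lacks: fast formulations are scaled by the assayed
drug content (90.32% for the nanocrystals) so their release plateaus
below 100%, and the raw-material fixture is generated from an effective
slow PSD (315 ± 302 μm) chosen once so the fixture lands in the reported
dissolution-efficiency band — under this package's rate law the fitted
raw P-PSD dissolves much faster than the measured powder did (wetting
and hydrodynamic effects are not modelled).

Consequently, tests that would be external validations against measured
data are here *parameter-recovery* and *self-coverage* exercises: they
demonstrate internal consistency, identifiability and statistical
calibration of the pipeline, not agreement with new experimental data.

## Population simulation

Independent mean-preserving log-normal multipliers per subject: 30% CV on
enzyme Vmax, 20% on GI transit times and tissue flows, 15% on tissue
volumes and Peff (solubility available, default off). These defaults are
a documented stand-in for proprietary covariate-based population
generators and produce 5th–95th percentile bands of realistic magnitude;
they claim no specific published design. Cardiac output is recomputed
from the perturbed flows so flow balance always holds. Bands are
pointwise percentiles on a 150-point grid; failed subjects are excluded
with a warning, never silently. With the default design (7 × 10 subjects)
a synthetic observed dataset at 20% residual CV is covered by the 5–95%
band at ≈97%.

## Sensitivity analysis

One-at-a-time log-spaced sweeps (25 tests by default) over mean particle
radius (1.14–114 μm), particle radius SD (2–50 μm), stomach transit
(0.05–0.5 h) and the bile solubilization multiplier (0.01–100× the
calibrated coefficient, preserving the published four-decade design).
Parameters are ranked by the max/min ratio of AUC_t across their grid.
In the packaged rat model the bile solubilization ratio and the mean
particle radius dominate, stomach transit and radius SD are weak, and
Cmax is monotone non-increasing in mean radius. One divergence from the
qualitative published behaviour: with the arithmetic mean held fixed,
*increasing* the radius SD slightly increases exposure here (heavier
small-radius quantiles dissolve faster), where the original analysis
reported the opposite sign; the SD sweep is not part of any quantitative
claim.

## Known limitations

* Perfusion-limited tissues only; no lymphatics, transporters,
  enterohepatic recirculation, metabolite kinetics or food effects.
* The hepatic flow and SA/V calibrations absorb proprietary conventions
  of the software being reproduced; they are effective parameters, not
  measurements.
* The human model's terminal elimination is much slower than clinical
  half-life reports; single-dose Cmax/AUC_t over 192 h (the quantities
  reproduced here) are dominated by absorption and distribution, which
  the model captures, not by terminal clearance, which it understates.
* Log-normality of the PSD is an assumption; only mean ± SD and bin count
  are identifiable from a dissolution profile.
* CYP2B6-polymorphism subpopulations and age/sex covariate physiology are
  out of scope.
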