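"""Canonical study definitions for the packaged efavirenz models.

One place for the reference dosing scenarios used across the workflow,
the synthetic-data generators and the examples: the fitted P-PSD summaries
(mean radius +/- SD over n bins), the in vitro media, and builders that
assemble drug/physiology/formulation triples for each simulated study arm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DoseForm, DrugRecord, Formulation, Physiology, builtin_drug, builtin_physiology
from .dissolution import DissolutionMedium
from .psd import expand_psd

__all__ = [
    "PPSD_RAW",
    "PPSD_NC",
    "PPSD_TABLET",
    "SLS_025_MEDIUM",
    "SLS_050_MEDIUM",
    "DISSOLUTION_TIMES_MIN",
    "PK_SAMPLING_TIMES_H",
    "Scenario",
    "SCENARIOS",
    "build_scenario",
]

# Fitted product particle size distributions: (mean radius um, SD um, bins)
PPSD_RAW = (44.15, 42.5, 8)
PPSD_NC = (11.4, 7.15, 10)
PPSD_TABLET = (13.77, 27.5, 10)

# 0.25% w/v SLS == 8.7 mM; the tablet profile was generated in 0.5% SLS.
SLS_025_MEDIUM = DissolutionMedium(volume=900.0, surfactant_conc=8.7)
SLS_050_MEDIUM = DissolutionMedium(volume=900.0, surfactant_conc=17.4)

#: USP II sampling schedule (min).
DISSOLUTION_TIMES_MIN = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0)

#: In vivo plasma sampling schedule (h).
PK_SAMPLING_TIMES_H = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class Scenario:
    name: str
    species: str
    route: str  # "iv" or "po"
    dose_mg_per_kg: float | None  # per-kg dosing (rat studies)
    dose_mg: float | None  # absolute dose (human studies)
    psd: tuple[float, float, int] | None
    nano_effect: bool = False
    duration: float = 10.0

    def dose_for(self, phys: Physiology) -> float:
        if self.dose_mg is not None:
            return self.dose_mg
        return self.dose_mg_per_kg * phys.body_weight


SCENARIOS: dict[str, Scenario] = {
    "rat_iv_2mgkg": Scenario("rat_iv_2mgkg", "rat", "iv", 2.0, None, None, duration=24.0),
    "rat_iv_5mgkg": Scenario("rat_iv_5mgkg", "rat", "iv", 5.0, None, None, duration=24.0),
    "rat_po_raw": Scenario("rat_po_raw", "rat", "po", 20.0, None, PPSD_RAW, False, 10.0),
    "rat_po_nc": Scenario("rat_po_nc", "rat", "po", 20.0, None, PPSD_NC, True, 10.0),
    "human_po_nc_350mg": Scenario(
        "human_po_nc_350mg", "human", "po", None, 350.0, PPSD_NC, True, 192.0
    ),
    "human_po_tablet_600mg": Scenario(
        "human_po_tablet_600mg", "human", "po", None, 600.0, PPSD_TABLET, False, 192.0
    ),
}


def build_scenario(
    name: str,
    drug: DrugRecord | None = None,
) -> tuple[Scenario, DrugRecord, Physiology, Formulation | None]:
    """Materialise a named scenario into model inputs.

    Returns the scenario, the drug record, the species physiology and, for
    oral scenarios, the formulation (None for i.v.).
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    drug = drug if drug is not None else builtin_drug()
    phys = builtin_physiology(sc.species)
    form = None
    if sc.route == "po":
        mean_r, sd_r, nb = sc.psd
        dose_form = (
            DoseForm.oral_tablet if "tablet" in name else DoseForm.oral_suspension
        )
        form = Formulation(
            form=dose_form,
            dose=sc.dose_for(phys),
            psd=expand_psd(mean_r, sd_r, nb),
            nano_effect=sc.nano_effect,
        )
    return sc, drug, phys, form
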