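"""Domain records for the PBPK/PBBM model and their structured-text I/O.

Every model symbol lives in one of five validated record types:

* :class:`DrugRecord` — compound physicochemistry, protein binding,
  permeability and enzyme kinetics (species-resolved where they differ).
* :class:`Physiology` — whole-body tissue volumes/flows with tissue:plasma
  partition coefficients, blood pools, renal function, and the GI chain.
* :class:`GICompartment` — one luminal segment of the absorption model.
* :class:`Formulation` — dosage form, dose and particle size distribution.
* :class:`PSD` — binned particle size distribution.

Records serialise to/from plain YAML with explicit unit conventions:
volumes L (GI lumen mL), flows L/h, amounts mg, concentrations mg/L
(plasma) or mg/mL (lumen, solubility), radii um, times h, Vmax mg/s,
Km mg/L, Peff cm/s, diffusion coefficient cm^2/s.
"""

from __future__ import annotations

import importlib.resources
from enum import Enum
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Species",
    "DoseForm",
    "EnzymeKinetics",
    "DrugRecord",
    "Tissue",
    "GICompartment",
    "Physiology",
    "PSD",
    "Formulation",
    "load_drug_record",
    "load_physiology",
    "builtin_drug",
    "builtin_physiology",
    "save_record",
]


class Species(str, Enum):
    rat = "rat"
    human = "human"


class DoseForm(str, Enum):
    iv_bolus = "iv_bolus"
    oral_suspension = "oral_suspension"
    oral_tablet = "oral_tablet"
    oral_solution = "oral_solution"


class _Record(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EnzymeKinetics(_Record):
    """Whole-organ Michaelis-Menten kinetics for one enzyme at one site."""

    enzyme: str
    site: Literal["liver", "gut"]
    vmax: float  # mg/s, whole organ
    km: float  # mg/L

    @field_validator("vmax")
    @classmethod
    def _vmax_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("vmax must be >= 0")
        return v

    @field_validator("km")
    @classmethod
    def _km_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("km must be > 0")
        return v


class DrugRecord(_Record):
    """Compound-level model inputs.

    Species-dependent quantities (unbound fraction, blood:plasma ratio,
    effective permeability, enzyme panel) are keyed by species name.
    """

    name: str
    mw: float  # g/mol
    logp: float
    pka: float
    pka_type: Literal["acid", "base", "neutral"] = "acid"
    diff_coeff: float  # cm^2/s
    density: float  # g/mL
    sol_aq: float  # mg/mL
    sol_aq_ph: float  # reference pH of sol_aq
    sol_fassif: float  # mg/mL
    sol_fessif: float  # mg/mL
    solubilization_factor: float  # dimensionless (stored, unused in simulation)
    bile_sr: float  # fitted luminal solubilization coefficient (dimensionless)
    interfacial_tension: float  # J/m^2
    nano_factor: float = 1.0  # dimensionless >= 1
    nano_radius_threshold: float = 1.0  # um; flat nano factor applies below this
    fup: dict[str, float]  # fraction unbound in plasma, per species
    bp_ratio: dict[str, float]  # blood:plasma ratio, per species
    peff: dict[str, float]  # effective permeability cm/s, per species
    enzymes: dict[str, list[EnzymeKinetics]]  # per species
    kaff: float = 0.0  # mg/mL/mM, surfactant affinity (in vitro only)

    @field_validator("mw", "diff_coeff", "density", "sol_aq", "sol_fassif", "sol_fessif")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("nano_factor")
    @classmethod
    def _nano_ge_one(cls, v: float) -> float:
        if v < 1:
            raise ValueError("nano_factor must be >= 1")
        return v

    @field_validator("fup")
    @classmethod
    def _fup_fraction(cls, v: dict[str, float]) -> dict[str, float]:
        for sp, f in v.items():
            if not (0 < f <= 1):
                raise ValueError(f"fup[{sp}] must be in (0, 1]")
        return v

    @model_validator(mode="after")
    def _solubility_order(self) -> "DrugRecord":
        if not (self.sol_fessif >= self.sol_fassif >= self.sol_aq):
            raise ValueError("solubility ordering sol_fessif >= sol_fassif >= sol_aq violated")
        return self

    def enzymes_for(self, species: Species | str) -> list[EnzymeKinetics]:
        return self.enzymes[Species(species).value]

    def fup_for(self, species: Species | str) -> float:
        return self.fup[Species(species).value]

    def bp_for(self, species: Species | str) -> float:
        return self.bp_ratio[Species(species).value]

    def peff_for(self, species: Species | str) -> float:
        return self.peff[Species(species).value]


class Tissue(_Record):
    name: str
    volume: float  # L
    blood_flow: float  # L/h (liver: total outflow incl. splanchnic inflows)
    kp: float  # tissue:plasma partition coefficient

    @field_validator("volume", "kp")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("blood_flow")
    @classmethod
    def _flow_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("blood_flow must be >= 0")
        return v


_GI_ORDER = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "caecum",
    "colon",
)


class GICompartment(_Record):
    name: str
    volume: float  # mL of luminal fluid
    transit_time: float  # h
    ph: float
    bile_salt_conc: float  # mM (taurocholate-equivalent)
    sa_v: float  # 1/cm, absorptive surface-to-volume scale factor
    absorption_enabled: bool = True

    @field_validator("volume", "transit_time")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("bile_salt_conc", "sa_v")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v


class Physiology(_Record):
    """Species whole-body physiology with drug-specific Kp values filled in.

    Flow bookkeeping: ``cardiac_output`` equals the lung (pulmonary) flow.
    The spleen drains through the liver, and the liver's ``blood_flow`` is its
    total outflow (hepatic artery + splanchnic inflow), so the venous return
    is the sum of all tissue flows excluding lung and spleen; that sum must
    equal the cardiac output.
    """

    species: Species
    body_weight: float  # kg
    tissues: list[Tissue]
    venous_volume: float  # L (blood)
    arterial_volume: float  # L (blood)
    plasma_fraction: float = 0.55  # plasma fraction of blood volume
    cardiac_output: float  # L/h
    gfr: float  # L/h
    gi: list[GICompartment]
    renal_clearance_rule: str = "fup_times_gfr"  # or "explicit:<value L/h>"
    portal_flow: float  # L/h, mesenteric/portal blood flow for gut first pass
    enterocyte_volume: float  # L, lumped enterocyte pool

    @field_validator("body_weight", "venous_volume", "arterial_volume", "cardiac_output", "portal_flow", "enterocyte_volume")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @model_validator(mode="after")
    def _checks(self) -> "Physiology":
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")
        if "lung" not in names or "liver" not in names:
            raise ValueError("physiology requires lung and liver tissues")
        venous_return = sum(
            t.blood_flow for t in self.tissues if t.name not in ("lung", "spleen")
        )
        if abs(venous_return - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError(
                f"tissue flows into venous pool ({venous_return:.6g} L/h) "
                f"!= cardiac output ({self.cardiac_output:.6g} L/h)"
            )
        gi_names = tuple(c.name for c in self.gi)
        if gi_names != _GI_ORDER:
            raise ValueError(f"GI chain must be ordered {_GI_ORDER}, got {gi_names}")
        return self

    def tissue(self, name: str) -> Tissue:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def plasma_volume(self) -> float:
        return (self.venous_volume + self.arterial_volume) * self.plasma_fraction

    def renal_clearance(self, fup: float) -> float:
        """Renal plasma clearance (L/h) under the configured rule."""
        rule = self.renal_clearance_rule
        if rule == "fup_times_gfr":
            return fup * self.gfr
        if rule.startswith("explicit:"):
            return float(rule.split(":", 1)[1])
        raise ValueError(f"unknown renal clearance rule {rule!r}")


class PSD(_Record):
    """Binned particle size distribution (radii um, mass fractions sum to 1)."""

    mean_radius: float  # um
    sd_radius: float  # um
    n_bins: int
    bins: list[tuple[float, float]]  # (radius um, mass fraction)

    @model_validator(mode="after")
    def _checks(self) -> "PSD":
        if self.mean_radius <= 0 or self.sd_radius < 0 or self.n_bins < 1:
            raise ValueError("mean_radius > 0, sd_radius >= 0, n_bins >= 1 required")
        if len(self.bins) != self.n_bins:
            raise ValueError("len(bins) != n_bins")
        radii = [r for r, _ in self.bins]
        fracs = [f for _, f in self.bins]
        if any(r <= 0 for r in radii):
            raise ValueError("bin radii must be strictly positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("bin radii must be strictly increasing")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("bin mass fractions must sum to 1 within 1e-9")
        return self

    @property
    def radii(self) -> list[float]:
        return [r for r, _ in self.bins]

    @property
    def fractions(self) -> list[float]:
        return [f for _, f in self.bins]


class Formulation(_Record):
    form: DoseForm
    dose: float  # mg
    psd: Optional[PSD] = None
    nano_effect: bool = False

    @model_validator(mode="after")
    def _checks(self) -> "Formulation":
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.form in (DoseForm.oral_suspension, DoseForm.oral_tablet) and self.psd is None:
            raise ValueError(f"{self.form.value} requires a particle size distribution")
        return self


# ---------------------------------------------------------------------------
# YAML I/O


def _read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return doc


def load_drug_record(path: str | Path) -> DrugRecord:
    """Read and validate a drug record from a YAML config file."""
    return DrugRecord.model_validate(_read_yaml(path))


def save_record(record: _Record, path: str | Path) -> None:
    """Serialise any record back to YAML (round-trips bit-identically)."""
    with open(path, "w") as fh:
        yaml.safe_dump(record.model_dump(mode="json"), fh, sort_keys=False)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("nanopbpk").joinpath("data", name)))


def builtin_drug(name: str = "efavirenz") -> DrugRecord:
    """Load a drug record packaged with the library."""
    return load_drug_record(_data_path(f"{name}.yaml"))


def _scale_physiology(doc: dict, body_weight: float) -> dict:
    """Linearly scale volumes, flows and GFR from the reference body weight."""
    ref_bw = float(doc.pop("reference_body_weight"))
    s = body_weight / ref_bw
    doc = dict(doc)
    doc["body_weight"] = body_weight
    for key in ("venous_volume", "arterial_volume", "cardiac_output", "gfr", "portal_flow", "enterocyte_volume"):
        doc[key] = float(doc[key]) * s
    doc["tissues"] = [
        {**t, "volume": float(t["volume"]) * s, "blood_flow": float(t["blood_flow"]) * s}
        for t in doc["tissues"]
    ]
    doc["gi"] = [{**c, "volume": float(c["volume"]) * s} for c in doc["gi"]]
    return doc


def load_physiology(
    species: Species | str,
    body_weight: float | None = None,
    path: str | Path | None = None,
) -> Physiology:
    """Load a packaged (or external) physiology, scaled to ``body_weight``.

    The packaged tables carry the calibrated reference physiologies (rat
    0.35 kg, human 67.73 kg) with the drug's tissue partition coefficients
    already slotted per tissue.  Volumes, flows and GFR scale linearly with
    body weight.
    """
    sp = Species(species)
    if body_weight is not None and body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    doc = _read_yaml(path if path is not None else _data_path(f"{sp.value}.yaml"))
    ref_bw = float(doc["reference_body_weight"])
    doc = _scale_physiology(doc, body_weight if body_weight is not None else ref_bw)
    return Physiology.model_validate(doc)


def builtin_physiology(species: Species | str, body_weight: float | None = None) -> Physiology:
    return load_physiology(species, body_weight)
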