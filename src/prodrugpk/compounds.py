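"""Compound metadata and molar dose arithmetic.

Mouse PK studies prescribe doses in mg/kg of the dosed form, while exposure
and mass-balance quantities are most naturally expressed in µmol of
active-moiety equivalents.  A pro-drug (here, a valine-ester conjugate) is
dosed at a *molar-equivalent* mg/kg dose relative to its parent drug, so
that the two arms of a study deliver the same number of micromoles.

The conversion between the two scales requires only the molar mass of the
active moiety and a dimensionless salt factor (dosed-form mass per mole of
active moiety divided by the active-moiety molar mass).  Molecular masses
are configuration inputs: they are read from a registry file, never derived
from structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

ROUTE_IV = "IV_bolus"
ROUTE_PO = "PO"
ROUTES = (ROUTE_IV, ROUTE_PO)

#: Default mouse body weight in kg ("approximately 30 g" study animals).
DEFAULT_BODY_WEIGHT_KG = 0.030


@dataclass(frozen=True)
class Compound:
    """A dosed chemical entity.

    Parameters
    ----------
    name:
        Registry key for the compound.
    molar_mass:
        Molar mass of the active moiety in g/mol, > 0.
    salt_factor:
        Ratio of dosed-form mass to active-moiety mass basis, >= 1
        (1 for a free base/acid).
    role:
        ``"parent"`` or ``"prodrug"``.
    parent_name:
        Name of the parent compound; required when ``role == "prodrug"``.
    """

    name: str
    molar_mass: float
    salt_factor: float = 1.0
    role: str = "parent"
    parent_name: str | None = None

    def __post_init__(self) -> None:
        if not (self.molar_mass > 0 and math.isfinite(self.molar_mass)):
            raise ValueError(f"molar_mass must be finite and > 0, got {self.molar_mass}")
        if not (self.salt_factor >= 1 and math.isfinite(self.salt_factor)):
            raise ValueError(f"salt_factor must be >= 1, got {self.salt_factor}")
        if self.role not in ("parent", "prodrug"):
            raise ValueError(f"role must be 'parent' or 'prodrug', got {self.role!r}")
        if self.role == "prodrug" and not self.parent_name:
            raise ValueError("a prodrug must name its parent compound")

    @property
    def mass_basis(self) -> float:
        """Dosed-form g per mol of active moiety (molar_mass × salt_factor)."""
        return self.molar_mass * self.salt_factor


@dataclass(frozen=True)
class DoseEvent:
    """A single administration to one subject.

    ``route`` is ``"IV_bolus"`` (bolus into the central compartment) or
    ``"PO"`` (first-order absorption from a depot).
    """

    subject_id: str
    time: float
    route: str
    dose_mg_per_kg: float
    compound: Compound
    body_weight: float = DEFAULT_BODY_WEIGHT_KG

    def __post_init__(self) -> None:
        if self.time < 0 or not math.isfinite(self.time):
            raise ValueError(f"dose time must be finite and >= 0, got {self.time}")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if not (self.dose_mg_per_kg > 0 and math.isfinite(self.dose_mg_per_kg)):
            raise ValueError(f"dose_mg_per_kg must be > 0, got {self.dose_mg_per_kg}")
        if not (self.body_weight > 0 and math.isfinite(self.body_weight)):
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")


def dose_umol(event: DoseEvent) -> float:
    """Dose of a :class:`DoseEvent` in µmol of active-moiety equivalents.

    mg/kg × kg gives mg of dosed form; dividing by the mass basis (g/mol,
    numerically mg/mmol) gives mmol, and ×1000 gives µmol.
    """
    amount = event.dose_mg_per_kg * event.body_weight * 1000.0 / event.compound.mass_basis
    if not (amount > 0 and math.isfinite(amount)):
        raise ValueError(f"computed dose is not finite and positive: {amount}")
    return amount


def molar_equivalent_dose(parent_dose_mg_per_kg: float, parent: Compound, conjugate: Compound) -> float:
    """mg/kg dose of ``conjugate`` molar-equivalent to a parent mg/kg dose.

    Scales by the ratio of dosed-form mass bases so that both doses deliver
    the same µmol of active moiety.
    """
    if parent_dose_mg_per_kg <= 0:
        raise ValueError("parent dose must be > 0")
    if conjugate.role != "prodrug":
        raise ValueError(f"{conjugate.name!r} is not a prodrug")
    if conjugate.parent_name != parent.name:
        raise ValueError(
            f"prodrug {conjugate.name!r} references parent {conjugate.parent_name!r}, not {parent.name!r}"
        )
    return parent_dose_mg_per_kg * conjugate.mass_basis / parent.mass_basis


def load_registry(path: str | Path) -> dict[str, Compound]:
    """Read a compound registry from a YAML mapping ``name -> fields``.

    Each entry carries ``molar_mass`` and optionally ``salt_factor``,
    ``role`` and ``parent_name``.  Prodrug parent references are validated.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"registry file {path} must contain a mapping of compounds")
    registry: dict[str, Compound] = {}
    for name, fields in raw.items():
        if not isinstance(fields, Mapping):
            raise ValueError(f"registry entry {name!r} must be a mapping")
        unknown = set(fields) - {"molar_mass", "salt_factor", "role", "parent_name"}
        if unknown:
            raise ValueError(f"registry entry {name!r} has unknown keys {sorted(unknown)}")
        registry[name] = Compound(name=name, **fields)
    for compound in registry.values():
        if compound.role == "prodrug" and compound.parent_name not in registry:
            raise ValueError(
                f"prodrug {compound.name!r} references unknown parent {compound.parent_name!r}"
            )
    return registry


def default_registry() -> dict[str, Compound]:
    """The registry shipped with the package (see ``data/compounds.yaml``)."""
    return load_registry(Path(__file__).parent / "data" / "compounds.yaml")
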