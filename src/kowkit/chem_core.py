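"""Acid-base speciation primitives for monoprotic solutes.

Conventions used throughout the package:

* ``pKa`` always refers to the conjugate acid. For an acid AH the reaction
  is ``AH + H2O <-> A- + H3O+``; for a base B the tabulated constant
  describes ``BH+ + H2O <-> B + H3O+``, so a literature value such as
  lidocaine's 7.92 is used unchanged.
* Speciation is concentration-based: activity corrections are ignored,
  which is an excellent approximation at the small species concentrations
  relevant for partition measurements.
* The water autoprotolysis constant is fixed at ``K_W = 1e-14``
  (25 degC); temperatures are carried as metadata only.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "K_W",
    "IonizationClass",
    "Solute",
    "AqueousState",
    "ph_from_hydronium",
    "hydronium_from_ph",
    "fraction_ionized",
    "dissociation_quotient",
    "UnsupportedSoluteError",
]

#: Autoprotolysis (ion product) constant of water at 25 degC, (mol/L)^2.
K_W: float = 1.0e-14


class UnsupportedSoluteError(ValueError):
    """Raised when an operation does not apply to the solute's ionization class."""


class IonizationClass(str, enum.Enum):
    """Monoprotic ionization behaviour of a solute."""

    ACID = "acid"
    BASE = "base"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class Solute:
    """An (optionally ionizable) solute.

    Parameters
    ----------
    name:
        Free-text identifier, e.g. ``"naproxen"``.
    ionization_class:
        ``acid``, ``base`` or ``neutral``.
    pKa:
        Negative decadic log of the acid dissociation constant of the
        conjugate acid. Required for acids and bases, forbidden for
        neutral solutes.
    pKa_temperature:
        Temperature (degC) at which the pKa was determined. Metadata only;
        no van 't Hoff correction is applied.
    pKa_ionic_strength:
        Ionic strength (mol/L) of the pKa determination. Metadata only.
    """

    name: str
    ionization_class: IonizationClass
    pKa: Optional[float] = None
    pKa_temperature: Optional[float] = None
    pKa_ionic_strength: Optional[float] = None

    def __post_init__(self) -> None:
        cls = IonizationClass(self.ionization_class)
        object.__setattr__(self, "ionization_class", cls)
        if cls is IonizationClass.NEUTRAL:
            if self.pKa is not None:
                raise ValueError("neutral solutes must not carry a pKa")
        else:
            if self.pKa is None:
                raise ValueError(f"{cls.value} solute requires a pKa")
            if not 0.0 < self.pKa < 14.0:
                raise ValueError(f"pKa {self.pKa} outside (0, 14)")
            if not 2.0 <= self.pKa <= 12.0:
                warnings.warn(
                    f"pKa {self.pKa} outside [2, 12]; the dilute-speciation "
                    "model is questionable for very strong acids/bases",
                    stacklevel=2,
                )

    @property
    def is_ionizable(self) -> bool:
        return self.ionization_class is not IonizationClass.NEUTRAL

    @property
    def Ka(self) -> float:
        """Dissociation constant ``10**-pKa`` of the conjugate acid."""
        if self.pKa is None:
            raise UnsupportedSoluteError(f"{self.name}: neutral solute has no Ka")
        return 10.0 ** (-self.pKa)


@dataclass(frozen=True)
class AqueousState:
    """Species concentrations (mol/L) in the aqueous phase.

    ``c_neutral_solute`` is AH for an acid or B for a base;
    ``c_charged_solute`` is A- or BH+ respectively.
    """

    c_hydronium: float
    c_hydroxide: float
    c_neutral_solute: float = 0.0
    c_charged_solute: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_hydronium", "c_hydroxide", "c_neutral_solute", "c_charged_solute"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        prod = self.c_hydronium * self.c_hydroxide
        if prod > 0.0 and abs(prod - K_W) > 1e-9 * K_W:
            raise ValueError(
                f"c_H3O+ * c_OH- = {prod:.6e} violates the water ion product {K_W:.1e}"
            )

    @property
    def pH(self) -> float:
        return ph_from_hydronium(self.c_hydronium)


def ph_from_hydronium(c_hydronium: float) -> float:
    """pH from the hydronium concentration, ``pH = -log10(c_H3O+)``."""
    if c_hydronium <= 0.0:
        raise ValueError(f"hydronium concentration must be > 0, got {c_hydronium}")
    return -math.log10(c_hydronium)


def hydronium_from_ph(pH: float) -> float:
    """Inverse of :func:`ph_from_hydronium`, ``c_H3O+ = 10**-pH``."""
    return 10.0 ** (-pH)


def fraction_ionized(solute: Solute, pH: float) -> float:
    """Degree of ionization of a monoprotic solute at a given aqueous pH.

    For an acid this is ``1 / (1 + 10**(pKa - pH))`` (the fraction present
    as A-), for a base ``1 / (1 + 10**(pH - pKa))`` (the fraction present
    as BH+). The neutral fraction is the complement in either case.
    """
    if not solute.is_ionizable:
        raise UnsupportedSoluteError(
            f"{solute.name} is neutral; fraction ionized is undefined"
        )
    if solute.ionization_class is IonizationClass.ACID:
        return 1.0 / (1.0 + 10.0 ** (solute.pKa - pH))
    return 1.0 / (1.0 + 10.0 ** (pH - solute.pKa))


def dissociation_quotient(
    state: AqueousState,
    ionization_class: IonizationClass = IonizationClass.ACID,
) -> float:
    """Apparent pKa implied by a speciated aqueous state.

    The dissociation quotient of the conjugate acid is
    ``c_deprotonated * c_H3O+ / c_protonated``. For an acid the
    deprotonated species is the charged pool (A-) and the protonated one
    the neutral pool (AH), so this evaluates
    ``-log10(c_charged * c_H3O+ / c_neutral)``; for a base the roles of
    the pools swap (B is deprotonated, BH+ protonated).

    For any equilibrium state produced by the forward simulator this
    recovers the solute pKa to high precision.
    """
    if state.c_neutral_solute <= 0.0:
        raise ValueError("neutral-species concentration must be > 0")
    if state.c_charged_solute <= 0.0:
        raise ValueError("charged-species concentration must be > 0")
    if state.c_hydronium <= 0.0:
        raise ValueError("hydronium concentration must be > 0")
    cls = IonizationClass(ionization_class)
    if cls is IonizationClass.NEUTRAL:
        raise UnsupportedSoluteError("neutral solutes have no dissociation quotient")
    if cls is IonizationClass.ACID:
        quotient = state.c_charged_solute * state.c_hydronium / state.c_neutral_solute
    else:
        quotient = state.c_neutral_solute * state.c_hydronium / state.c_charged_solute
    return -math.log10(quotient)
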