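"""Partition and distribution quantities and their interconversions.

Definitions
-----------
log P
    Decadic log of the neutral-species concentration ratio
    organic/aqueous at finite solute concentration.
log D
    Same ratio but with total (neutral + charged) concentrations; for
    nonionizable solutes log D and log P coincide.
K_OW / D_OW
    The zero-solute-concentration limits of P and D. At that limit an
    ionizable solute is fully ionized and the aqueous pH is 7.

The ionization correction connecting the two quantities for a
monoprotic acid is ``P = D * (1 + 10**(pH - pKa))``; for a base the
exponent is ``pKa - pH`` (conjugate-acid pKa convention). The relation
assumes dilute species concentrations and a charged species confined to
the aqueous phase.

Concentration/mole-fraction conversion uses the dilute-regime formula
``x_i = v_n * c_i`` with the molar volume of the respective phase.
Strictly these are the molar volumes of the water-saturated octanol
phase and the octanol-saturated water phase; pure-solvent values are an
approximation the caller must be aware of.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .chem_core import IonizationClass, Solute

__all__ = [
    "OECD_CONC_LIMIT",
    "PartitionMeasurement",
    "MeasurementSeries",
    "PhaseThermo",
    "QCFlag",
    "IdealActivity",
    "DebyeHuckelLimitingLaw",
    "log_partition",
    "mole_fraction_from_conc",
    "logp_from_logd",
    "logd_from_logp",
    "logp_sle",
    "kow_from_activity",
    "dow_from_activity",
    "oecd_qc",
    "read_measurements_csv",
    "write_measurements_csv",
    "MEASUREMENT_COLUMNS",
]

#: OECD-recommended upper limit (mol/L) for the solute concentration in
#: each phase of a partition experiment; a quality-control annotation,
#: not an exclusion rule. The limit itself is acceptable (inclusive).
OECD_CONC_LIMIT: float = 0.01


@dataclass(frozen=True)
class PartitionMeasurement:
    """One biphasic equilibrium observation.

    ``c_total`` is the total solute amount divided by the *total* liquid
    volume (organic + aqueous); the phase concentrations are per-phase.
    ``pH_aq`` may be omitted only for neutral solutes.
    """

    c_total: float
    c_org: float
    c_aq: float
    pH_aq: Optional[float] = None
    temperature: float = 25.0
    c_org_sd: Optional[float] = None
    c_aq_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c_org < 0.0:
            raise ValueError("c_org must be >= 0")
        if self.c_aq <= 0.0:
            raise ValueError("c_aq must be > 0")
        if self.pH_aq is not None and not 0.0 < self.pH_aq < 14.0:
            raise ValueError(f"pH {self.pH_aq} outside (0, 14)")

    @property
    def logD(self) -> float:
        """Observed distribution coefficient log10(c_org / c_aq)."""
        return log_partition(self.c_org, self.c_aq)


@dataclass
class MeasurementSeries:
    """An ordered collection of measurements for one solute."""

    solute: Solute
    measurements: List[PartitionMeasurement]
    volume_ratio_org_to_aq: float = 1.0 / 3.0
    ionic_strength: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("a series needs at least one measurement")
        temps = [m.temperature for m in self.measurements]
        if max(temps) - min(temps) > 1.0:
            raise ValueError(
                f"measurement temperatures span {max(temps) - min(temps):.2f} degC "
                "(> 1 degC); split into separate series"
            )
        if self.volume_ratio_org_to_aq <= 0.0:
            raise ValueError("volume ratio must be > 0")
        if self.solute.is_ionizable:
            missing = [i for i, m in enumerate(self.measurements) if m.pH_aq is None]
            if missing:
                raise ValueError(
                    f"ionizable solute {self.solute.name}: measurements {missing} lack pH"
                )

    def __len__(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class PhaseThermo:
    """Molar volumes and infinite-dilution activity coefficients of the
    two equilibrium phases, as supplied by an external thermodynamic
    model or experiment.

    The activity-coefficient route to the partition coefficients is

    ``K_OW = (v_aq / v_org) * (gamma_neutral_aq / gamma_neutral_org)``

    and, for the fully-ionized zero-concentration limit,

    ``D_OW = (v_aq / v_org) * (gamma_charged_aq / gamma_charged_org)
            * (gamma_hydronium_aq / gamma_hydronium_org)``.

    D_OW is independent of the neutral-species coefficients because the
    neutral species vanishes at infinite dilution of an ionizable solute.
    """

    molar_volume_aq: float
    molar_volume_org: float
    gamma_inf_neutral_aq: float = 1.0
    gamma_inf_neutral_org: float = 1.0
    gamma_inf_charged_aq: float = 1.0
    gamma_inf_charged_org: float = 1.0
    gamma_inf_hydronium_aq: float = 1.0
    gamma_inf_hydronium_org: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "molar_volume_aq",
            "molar_volume_org",
            "gamma_inf_neutral_aq",
            "gamma_inf_neutral_org",
            "gamma_inf_charged_aq",
            "gamma_inf_charged_org",
            "gamma_inf_hydronium_aq",
            "gamma_inf_hydronium_org",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")


class IdealActivity:
    """Ideal-solution activity model: every coefficient is unity."""

    def gamma_inf(self, charge: int, ionic_strength: float = 0.0) -> float:
        return 1.0


class DebyeHuckelLimitingLaw:
    """Debye-Hueckel limiting law for aqueous ionic activity coefficients,
    ``log10 gamma = -A * z**2 * sqrt(I)`` with A = 0.509 (25 degC, water).

    Valid only for very dilute aqueous electrolytes (I below ~0.01 mol/L);
    neutral species get gamma = 1.
    """

    A: float = 0.509

    def gamma_inf(self, charge: int, ionic_strength: float = 0.0) -> float:
        if ionic_strength < 0.0:
            raise ValueError("ionic strength must be >= 0")
        if charge == 0:
            return 1.0
        return 10.0 ** (-self.A * charge * charge * math.sqrt(ionic_strength))


def log_partition(c_org: float, c_aq: float) -> float:
    """log10 of the organic/aqueous concentration ratio.

    Serves both log P (species-resolved concentrations) and log D (total
    concentrations): routine analytics cannot distinguish neutral from
    charged species, so the same arithmetic applies to whichever
    concentrations were measured.
    """
    if c_org <= 0.0 or c_aq <= 0.0:
        raise ValueError(f"concentrations must be > 0, got org={c_org}, aq={c_aq}")
    return math.log10(c_org / c_aq)


def mole_fraction_from_conc(molar_volume: float, c: float) -> float:
    """Dilute-regime conversion ``x = v_n * c`` (v_n in L/mol, c in mol/L)."""
    if molar_volume <= 0.0:
        raise ValueError("molar volume must be > 0")
    if c < 0.0:
        raise ValueError("concentration must be >= 0")
    x = molar_volume * c
    if x > 1.0:
        raise ValueError(f"x = {x:.4g} > 1; dilute formula outside its validity")
    if x > 0.1:
        warnings.warn(
            f"mole fraction {x:.3g} > 0.1: the linear conversion x = v_n*c "
            "is a dilute-regime approximation",
            stacklevel=2,
        )
    return x


def _ionization_correction(pH: float, solute: Solute) -> float:
    """log10(1 + 10**(pH-pKa)) for acids, log10(1 + 10**(pKa-pH)) for bases."""
    if solute.ionization_class is IonizationClass.ACID:
        expo = pH - solute.pKa
    else:
        expo = solute.pKa - pH
    # log10(1 + 10**expo) via log1p for accuracy at small 10**expo
    return math.log1p(10.0**expo) / math.log(10.0)


def logp_from_logd(logD: float, pH: float, solute: Solute) -> float:
    """Convert a distribution coefficient to a partition coefficient.

    Acid: ``logP = logD + log10(1 + 10**(pH - pKa))``;
    base: ``logP = logD + log10(1 + 10**(pKa - pH))``.
    The correction is nonnegative, so log P is always an upper limit of
    log D. For a neutral solute log D and log P are the same quantity;
    the value is returned unchanged with a warning.
    """
    if not solute.is_ionizable:
        warnings.warn(
            f"{solute.name} is neutral: log D and log P are identical",
            stacklevel=2,
        )
        return logD
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    return logD + _ionization_correction(pH, solute)


def logd_from_logp(logP: float, pH: float, solute: Solute) -> float:
    """Inverse of :func:`logp_from_logd`."""
    if not solute.is_ionizable:
        warnings.warn(
            f"{solute.name} is neutral: log D and log P are identical",
            stacklevel=2,
        )
        return logP
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    return logP - _ionization_correction(pH, solute)


def logp_sle(c_sle_org: float, c_sle_aq: float) -> float:
    """Solubility-ratio pseudo partition coefficient
    ``log10(c_sat_org / c_sat_aq)`` from the solubilities in the *pure*
    solvents.

    Diagnostic only: the saturated binaries are not the ternary
    liquid-liquid system and the value does not approximate K_OW.
    """
    if c_sle_org <= 0.0 or c_sle_aq <= 0.0:
        raise ValueError("solubilities must be > 0")
    return math.log10(c_sle_org / c_sle_aq)


def kow_from_activity(thermo: PhaseThermo) -> float:
    """K_OW from phase molar volumes and neutral-species activity
    coefficients at infinite dilution (see :class:`PhaseThermo`)."""
    return (
        thermo.molar_volume_aq
        / thermo.molar_volume_org
        * thermo.gamma_inf_neutral_aq
        / thermo.gamma_inf_neutral_org
    )


def dow_from_activity(thermo: PhaseThermo) -> float:
    """D_OW from phase molar volumes and the charged-species and
    hydronium activity-coefficient ratios; the neutral species plays no
    role at infinite dilution (see :class:`PhaseThermo`)."""
    return (
        thermo.molar_volume_aq
        / thermo.molar_volume_org
        * thermo.gamma_inf_charged_aq
        / thermo.gamma_inf_charged_org
        * thermo.gamma_inf_hydronium_aq
        / thermo.gamma_inf_hydronium_org
    )


@dataclass(frozen=True)
class QCFlag:
    """Advisory quality-control annotation for one measurement."""

    measurement_index: int
    phase: str  # "org" or "aq"
    concentration: float
    message: str


def oecd_qc(series: MeasurementSeries) -> List[QCFlag]:
    """Flag measurements whose per-phase concentration exceeds the OECD
    recommended ceiling of 0.01 mol/L (inclusive: exactly 0.01 passes).

    Flags annotate, they never exclude data.
    """
    flags: List[QCFlag] = []
    for i, m in enumerate(series.measurements):
        for phase, c in (("org", m.c_org), ("aq", m.c_aq)):
            if c > OECD_CONC_LIMIT:
                flags.append(
                    QCFlag(
                        measurement_index=i,
                        phase=phase,
                        concentration=c,
                        message=(
                            f"c_{phase} = {c:.4g} mol/L exceeds the OECD "
                            f"limit of {OECD_CONC_LIMIT} mol/L"
                        ),
                    )
                )
    return flags


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "substance",
    "ionization_class",
    "pka",
    "c_total_mol_L",
    "c_org_mol_L",
    "c_aq_mol_L",
    "ph_aq",
    "temp_C",
    "c_org_sd",
    "c_aq_sd",
    "volume_ratio_org_aq",
    "ionic_strength_mol_L",
]


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_measurements_csv(path: Union[str, Path]) -> List[MeasurementSeries]:
    """Read measurement series from the package CSV schema.

    One row per measurement; rows are grouped into series by substance.
    Lines starting with ``#`` are metadata comments and are skipped.
    Missing pH is permitted only for neutral solutes.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    series_list: List[MeasurementSeries] = []
    for substance, group in df.groupby("substance", sort=False):
        first = group.iloc[0]
        cls = IonizationClass(str(first["ionization_class"]).strip().lower())
        solute = Solute(
            name=str(substance),
            ionization_class=cls,
            pKa=_opt(first["pka"]) if cls is not IonizationClass.NEUTRAL else None,
        )
        measurements = [
            PartitionMeasurement(
                c_total=float(row["c_total_mol_L"]),
                c_org=float(row["c_org_mol_L"]),
                c_aq=float(row["c_aq_mol_L"]),
                pH_aq=_opt(row["ph_aq"]),
                temperature=float(row["temp_C"]),
                c_org_sd=_opt(row.get("c_org_sd")),
                c_aq_sd=_opt(row.get("c_aq_sd")),
            )
            for _, row in group.iterrows()
        ]
        vratio = _opt(first.get("volume_ratio_org_aq"))
        series_list.append(
            MeasurementSeries(
                solute=solute,
                measurements=measurements,
                volume_ratio_org_to_aq=vratio if vratio is not None else 1.0 / 3.0,
                ionic_strength=_opt(first.get("ionic_strength_mol_L")),
            )
        )
    return series_list


def write_measurements_csv(
    series_list: Sequence[MeasurementSeries],
    path: Union[str, Path],
    header_comments: Optional[Sequence[str]] = None,
) -> None:
    """Write measurement series in the package CSV schema.

    ``header_comments`` (e.g. provenance metadata) are emitted as ``#``
    lines before the header row; full float precision is preserved.
    """
    rows = []
    for series in series_list:
        for m in series.measurements:
            rows.append(
                {
                    "substance": series.solute.name,
                    "ionization_class": series.solute.ionization_class.value,
                    "pka": series.solute.pKa,
                    "c_total_mol_L": m.c_total,
                    "c_org_mol_L": m.c_org,
                    "c_aq_mol_L": m.c_aq,
                    "ph_aq": m.pH_aq,
                    "temp_C": m.temperature,
                    "c_org_sd": m.c_org_sd,
                    "c_aq_sd": m.c_aq_sd,
                    "volume_ratio_org_aq": series.volume_ratio_org_to_aq,
                    "ionic_strength_mol_L": series.ionic_strength,
                }
            )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in header_comments or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
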