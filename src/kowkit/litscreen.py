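"""Screening statistics over curated literature partition values.

The package ships two small curated tables:

* ``literature_values.csv`` - octanol/water log P / log D / log K_OW /
  log D_OW values for 18 active pharmaceutical ingredients collected
  from the primary literature, with the property the original authors
  *stated*, the property their described experiment actually *reported*,
  the determination route (experimental, converted, calculated), and pH,
  concentration and ionic-strength metadata where available.
* ``method_comparison.csv`` - log K_OW values for four example drugs
  (naproxen, ibuprofen, lidocaine, griseofulvin) obtained by the
  pH-extrapolation route (method 1), the concentration-extrapolation
  route (method 2) and an activity-coefficient model (method 3),
  alongside the solubility-ratio value and a reference literature value.

The headline screening statistic is the per-substance *spread* - the
difference between the highest and lowest published value - which for
ionizable drugs routinely reaches several log units because reported
"log P" values are frequently uncorrected log D values measured at
unstated pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .chem_core import IonizationClass, Solute
from .partition import logd_from_logp, logp_from_logd

__all__ = [
    "LiteratureEntry",
    "load_literature_table",
    "load_method_comparison",
    "entries_from_dataframe",
    "spread",
    "class_spread_summary",
    "method_gaps",
    "consistency_check",
    "REFERENCE_SOLUTES",
]

#: The four example drugs of the method-comparison study, with their
#: conjugate-acid pKa values (temperature and ionic strength of the pKa
#: determination recorded as metadata).
REFERENCE_SOLUTES: Dict[str, Solute] = {
    "naproxen": Solute(
        "naproxen", IonizationClass.ACID, pKa=4.18,
        pKa_temperature=25.0, pKa_ionic_strength=0.15,
    ),
    "ibuprofen": Solute(
        "ibuprofen", IonizationClass.ACID, pKa=4.42,
        pKa_temperature=25.0, pKa_ionic_strength=0.15,
    ),
    "lidocaine": Solute(
        "lidocaine", IonizationClass.BASE, pKa=7.92,
        pKa_temperature=22.5, pKa_ionic_strength=0.1,
    ),
    "griseofulvin": Solute("griseofulvin", IonizationClass.NEUTRAL),
}


@dataclass(frozen=True)
class LiteratureEntry:
    """One published partition/distribution value with provenance."""

    substance: str
    ionizable: bool
    property_stated: str  # logP | logD | logKow | logDow
    property_reported: str  # as above, or "unknown"
    determination: str  # exp | conv | calc | exp&conv | unknown
    value: float
    pH: Optional[float] = None
    conc_range: Optional[str] = None
    ionic_strength: Optional[float] = None
    reliable: bool = False
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not self.substance:
            raise ValueError("substance must be non-empty")
        if not math.isfinite(self.value):
            raise ValueError("value must be finite")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("kowkit").joinpath("data", name).open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def load_literature_table(path=None) -> pd.DataFrame:
    """The curated literature-value table ("N/A" cells are stored as missing values)."""
    return pd.read_csv(path) if path is not None else _read_packaged("literature_values.csv")


def load_method_comparison(path=None) -> pd.DataFrame:
    """The four-drug method-comparison table."""
    return pd.read_csv(path) if path is not None else _read_packaged("method_comparison.csv")


def entries_from_dataframe(df: pd.DataFrame) -> List[LiteratureEntry]:
    entries = []
    for _, row in df.iterrows():
        entries.append(
            LiteratureEntry(
                substance=str(row["substance"]),
                ionizable=bool(row["ionizable"]),
                property_stated=str(row["property_stated"]),
                property_reported=str(row["property_reported"]),
                determination=str(row["determination"]),
                value=float(row["value"]),
                pH=None if pd.isna(row["ph"]) else float(row["ph"]),
                conc_range=None if pd.isna(row["conc_mmol_L"]) else str(row["conc_mmol_L"]),
                ionic_strength=(
                    None
                    if pd.isna(row["ionic_strength_mmol_L"])
                    else _parse_strength(row["ionic_strength_mmol_L"])
                ),
                reliable=bool(row["reliable"]),
                reference_id=str(row["reference_id"]),
            )
        )
    return entries


def _parse_strength(raw) -> Optional[float]:
    try:
        return float(raw)
    except (TypeError, ValueError):
        return None


def spread(values: Sequence[float]) -> float:
    """Max minus min of a collection of published values (0 for a singleton)."""
    vals = list(values)
    if not vals:
        raise ValueError("spread of an empty collection is undefined")
    return max(vals) - min(vals)


def class_spread_summary(
    entries: Iterable[LiteratureEntry],
    experimental_only: bool = False,
) -> dict:
    """Mean per-substance spread, split by ionizability.

    Pools all reported values per substance regardless of determination
    route unless ``experimental_only`` restricts to entries whose
    determination involves an experiment (``exp`` / ``exp&conv``).
    Returns a dict with the per-substance table (a DataFrame) and the
    mean spread per class; classes without substances are omitted.
    """
    rows = []
    by_substance: Dict[str, List[LiteratureEntry]] = {}
    for e in entries:
        if experimental_only and not e.determination.startswith("exp"):
            continue
        by_substance.setdefault(e.substance, []).append(e)
    for substance, group in by_substance.items():
        rows.append(
            {
                "substance": substance,
                "ionizable": group[0].ionizable,
                "n_values": len(group),
                "min": min(e.value for e in group),
                "max": max(e.value for e in group),
                "spread": spread([e.value for e in group]),
            }
        )
    table = pd.DataFrame(rows)
    means: Dict[str, float] = {}
    for flag, label in ((False, "nonionizable"), (True, "ionizable")):
        sub = table[table["ionizable"] == flag] if len(table) else table
        if len(sub):
            means[label] = float(sub["spread"].mean())
    return {"per_substance": table, "mean_spread": means}


def method_gaps(comparison: Optional[pd.DataFrame] = None) -> Dict[str, float]:
    """Absolute method-1 vs method-2 disagreement per drug.

    Drugs lacking one of the two estimates (the nonionizable
    griseofulvin has no pH-extrapolation value) are omitted.
    """
    df = comparison if comparison is not None else load_method_comparison()
    gaps: Dict[str, float] = {}
    for _, row in df.iterrows():
        if pd.isna(row["method1"]) or pd.isna(row["method2"]):
            continue
        gaps[str(row["api"])] = abs(float(row["method1"]) - float(row["method2"]))
    return gaps


def consistency_check(entry: LiteratureEntry, solute: Solute) -> dict:
    """Audit one literature entry against its solute's ionization data.

    Reports (a) whether the property the authors stated matches the
    property their experiment actually reported, and (b) where pH and
    pKa are available, the ionization-corrected companion value
    (log D -> log P or log P -> log D) for cross-source comparison.
    """
    report: dict = {
        "substance": entry.substance,
        "stated": entry.property_stated,
        "reported": entry.property_reported,
        "mismatch": (
            entry.property_reported != "unknown"
            and entry.property_stated != entry.property_reported
        ),
        "companion_value": None,
        "companion_property": None,
        "note": None,
    }
    if not solute.is_ionizable:
        report["note"] = "neutral substance: log D and log P are identical"
        return report
    if entry.pH is None:
        report["note"] = "conversion skipped: entry has no pH"
        return report
    basis = (
        entry.property_reported
        if entry.property_reported != "unknown"
        else entry.property_stated
    )
    if basis in ("logD", "logDow"):
        report["companion_value"] = logp_from_logd(entry.value, entry.pH, solute)
        report["companion_property"] = "logP"
    elif basis in ("logP", "logKow"):
        report["companion_value"] = logd_from_logp(entry.value, entry.pH, solute)
        report["companion_property"] = "logD"
    else:
        report["note"] = f"conversion skipped: cannot interpret property {basis!r}"
    return report
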