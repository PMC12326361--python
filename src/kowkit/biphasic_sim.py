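"""Forward model of the solute/octanol/water biphasic equilibrium.

The simulator solves, for a given total solute amount, the coupled
system of

* acid-base dissociation in the aqueous phase (concentration-based
  conjugate-acid pKa),
* water autoprotolysis (``c_H3O+ * c_OH- = K_W``),
* aqueous electroneutrality, and
* neutral-species (and optionally charged-species) partitioning
  between the phases,

and returns the full speciation, from which the observable quantities
log D, pH and the species-resolved apparent log P follow.

Species ledger and charge balances
----------------------------------
Acid AH:   ``AH + H2O <-> A- + H3O+``; aqueous charge balance
``c_H3O+ = c_A- + c_OH-``, which forces pH < 7.

Base B:    ``B + H2O <-> BH+ + OH-`` (pKa refers to BH+); charge balance
``c_BH+ + c_H3O+ = c_OH-``, which forces pH > 7.

No counterions are present (no added salt); the two phase volumes are
fixed, with no mutual octanol/water solubility and no volume of mixing.
Only the dilute-solute corner of the ternary system is modelled.

Concentration dependence of the neutral-species partition coefficient
enters through ``log10 P_N = log10 P_N0 + s * c_total`` with a linear
slope ``s`` (default 0), emulating the near-linear trend of apparent
log P with overall concentration seen in shake-flask data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .chem_core import (
    K_W,
    AqueousState,
    IonizationClass,
    Solute,
)
from .partition import MeasurementSeries, PartitionMeasurement

__all__ = [
    "BiphasicSystem",
    "EquilibriumState",
    "NoiseModel",
    "SolverError",
    "solve_equilibrium",
    "simulate_series",
    "closed_form_dow",
    "DEFAULT_CONC_GRID",
]

#: Default overall-concentration grid (mol/L): four points straddling the
#: OECD per-phase ceiling, the typical design of a shake-flask study.
DEFAULT_CONC_GRID: tuple = (1e-3, 2.5e-3, 5e-3, 1e-2)


class SolverError(RuntimeError):
    """Raised when the equilibrium root-finder cannot bracket a solution."""


@dataclass(frozen=True)
class BiphasicSystem:
    """Geometry and partitioning parameters of the two-phase system.

    Parameters
    ----------
    volume_org, volume_aq:
        Phase volumes in litres. The default 1:3 organic:aqueous ratio
        mirrors a common shake-flask design.
    P_neutral_0:
        Infinite-dilution partition coefficient (c_org/c_aq) of the
        neutral species.
    conc_slope_s:
        Linear concentration dependence of the neutral-species partition
        coefficient, ``log10 P_N = log10 P_neutral_0 + s * c_total``
        (L/mol). Zero by default.
    P_ion:
        Partition coefficient of the charged species. Ionization is
        strongly suppressed in octanol, so the default confines the ion
        to the aqueous phase (P_ion = 0).
    """

    volume_org: float = 0.25
    volume_aq: float = 0.75
    P_neutral_0: float = 1000.0
    conc_slope_s: float = 0.0
    P_ion: float = 0.0
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.volume_org <= 0.0 or self.volume_aq <= 0.0:
            raise ValueError("phase volumes must be > 0")
        if self.P_neutral_0 <= 0.0:
            raise ValueError("P_neutral_0 must be > 0")
        if self.P_ion < 0.0:
            raise ValueError("P_ion must be >= 0")

    def p_neutral(self, c_total: float) -> float:
        """Neutral-species partition coefficient at an overall concentration."""
        return 10.0 ** (math.log10(self.P_neutral_0) + self.conc_slope_s * c_total)


@dataclass(frozen=True)
class EquilibriumState:
    """Full speciation of one solved biphasic equilibrium."""

    aqueous: AqueousState
    c_neutral_org: float
    c_charged_org: float
    pH: float
    logD: float
    logP_apparent: float
    degree_of_ionization_aq: float

    @property
    def c_total_org(self) -> float:
        return self.c_neutral_org + self.c_charged_org

    @property
    def c_total_aq(self) -> float:
        return self.aqueous.c_neutral_solute + self.aqueous.c_charged_solute


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic series.

    ``rel_conc_sigma`` is the sigma of multiplicative lognormal noise on
    both phase concentrations (default 5%, the typical scatter of
    triplicate shake-flask analyses); ``ph_sigma`` is additive Gaussian
    noise on the measured pH (default 0.02, a routine pH-electrode
    precision). Equal seeds reproduce identical series bit for bit.
    """

    rel_conc_sigma: float = 0.05
    ph_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_conc_sigma < 0.0 or self.ph_sigma < 0.0:
            raise ValueError("noise sigmas must be >= 0")


def _hydronium_from_net_charge(t: float) -> float:
    """Hydronium concentration given the net solute charge in water.

    ``t = c_H3O+ - c_OH-`` is positive for an acid (where it equals
    c_A-) and negative for a base (where -t equals c_BH+). Solving
    ``h - K_W/h = t`` for h gives a quadratic whose stable root is used
    on either side of neutrality to avoid catastrophic cancellation.
    """
    disc = math.sqrt(t * t + 4.0 * K_W)
    if t >= 0.0:
        return 0.5 * (t + disc)
    return 2.0 * K_W / (disc - t)


def _speciation_from_charge(
    solute: Solute, system: BiphasicSystem, P_N: float, c_charged: float
) -> tuple:
    """Full speciation implied by the aqueous charged-solute concentration.

    Electroneutrality fixes the hydronium concentration, the dissociation
    law then gives the neutral pool, and the partition coefficients give
    the organic-phase pools. Returns
    ``(n_model, c_neutral_aq, c_charged_aq, h)`` where ``n_model`` is the
    total solute amount (mol) consistent with this state. ``n_model`` is
    strictly increasing in ``c_charged``, which makes the bracketed root
    search monotone. Working in the charged-species variable (rather
    than pH) avoids the cancellation in ``h - K_W/h`` that would
    otherwise ruin the mass balance for weakly ionized solutes.
    """
    Ka = solute.Ka
    if solute.ionization_class is IonizationClass.ACID:
        h = _hydronium_from_net_charge(c_charged)
        c_neutral = c_charged * h / Ka  # from Ka = c_A- * c_H3O+ / c_AH
    else:
        h = _hydronium_from_net_charge(-c_charged)
        c_neutral = c_charged * Ka / h  # from Ka = c_B * c_H3O+ / c_BH+
    n_model = system.volume_aq * (c_neutral + c_charged) + system.volume_org * (
        P_N * c_neutral + system.P_ion * c_charged
    )
    return n_model, c_neutral, c_charged, h


def solve_equilibrium(
    solute: Solute, system: BiphasicSystem, n_total: float
) -> EquilibriumState:
    """Solve the biphasic ionization/partition equilibrium.

    The aqueous speciation is found by guaranteed bisection on the
    combined mass-balance/charge-balance residual, parametrized by the
    charged-solute concentration (equivalent to scanning hydronium over
    [1e-14, 1] mol/L, but numerically stable for weakly ionized
    solutes). The returned state satisfies mass balance and
    electroneutrality to better than 1e-9 relative.

    For a neutral solute there is nothing to solve: the solute
    distributes between two pools and the pH stays at 7.
    """
    if n_total < 0.0:
        raise ValueError("n_total must be >= 0")
    c_total = n_total / (system.volume_org + system.volume_aq)
    P_N = system.p_neutral(c_total)

    if not solute.is_ionizable:
        c_aq = n_total / (system.volume_aq + P_N * system.volume_org)
        c_org = P_N * c_aq
        logP = math.log10(P_N)
        return EquilibriumState(
            aqueous=AqueousState(
                c_hydronium=1e-7,
                c_hydroxide=1e-7,
                c_neutral_solute=c_aq,
                c_charged_solute=0.0,
            ),
            c_neutral_org=c_org,
            c_charged_org=0.0,
            pH=7.0,
            logD=logP if n_total > 0 else float("nan"),
            logP_apparent=logP if n_total > 0 else float("nan"),
            degree_of_ionization_aq=0.0,
        )

    if n_total == 0.0:
        return EquilibriumState(
            aqueous=AqueousState(1e-7, 1e-7, 0.0, 0.0),
            c_neutral_org=0.0,
            c_charged_org=0.0,
            pH=7.0,
            logD=float("nan"),
            logP_apparent=float("nan"),
            degree_of_ionization_aq=float("nan"),
        )

    def residual(log10_charged: float) -> float:
        n_model, _, _, _ = _speciation_from_charge(
            solute, system, P_N, 10.0**log10_charged
        )
        return n_model - n_total

    # The charged-species bracket (1e-40, 1] mol/L covers the hydronium
    # range [1e-14, 1] mol/L with margin for weakly ionized solutes. The
    # residual is monotone in the (log-scaled) charged concentration, so
    # bisection is guaranteed; it is driven to floating-point resolution
    # so mass balance closes to ~1e-12 relative even for vanishingly
    # small solute amounts.
    lo, hi = -40.0, 0.0
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        root = lo
    elif r_hi == 0.0:
        root = hi
    elif (r_lo < 0.0) == (r_hi < 0.0):
        raise SolverError(
            f"no sign change in charged-species bracket [1e-40, 1] mol/L: "
            f"residual(lo)={r_lo:.3e}, residual(hi)={r_hi:.3e}; "
            f"solute={solute.name}, n_total={n_total:.3e} mol, P_N={P_N:.3e}"
        )
    else:
        a, b, fa, fb = lo, hi, r_lo, r_hi
        for _ in range(200):
            mid = 0.5 * (a + b)
            if mid == a or mid == b:
                break
            fm = residual(mid)
            if fm == 0.0:
                a = b = mid
                fa = fb = 0.0
                break
            if (fm < 0.0) == (fa < 0.0):
                a, fa = mid, fm
            else:
                b, fb = mid, fm
        root = a if abs(fa) <= abs(fb) else b

    n_model, c_neutral_aq, c_charged_aq, h = _speciation_from_charge(
        solute, system, P_N, 10.0**root
    )
    rel_residual = abs(n_model - n_total) / n_total
    if rel_residual > 1e-9:
        raise SolverError(
            f"converged root violates mass balance: relative residual "
            f"{rel_residual:.3e} for {solute.name} at n_total={n_total:.3e} mol"
        )

    ph_root = -math.log10(h)
    c_neutral_org = P_N * c_neutral_aq
    c_charged_org = system.P_ion * c_charged_aq
    c_aq_total = c_neutral_aq + c_charged_aq
    c_org_total = c_neutral_org + c_charged_org
    logD = (
        math.log10(c_org_total / c_aq_total)
        if c_aq_total > 0.0 and c_org_total > 0.0
        else float("nan")
    )
    logP = (
        math.log10(c_neutral_org / c_neutral_aq)
        if c_neutral_aq > 0.0 and c_neutral_org > 0.0
        else float("nan")
    )
    ionized = c_charged_aq / c_aq_total if c_aq_total > 0.0 else float("nan")
    return EquilibriumState(
        aqueous=AqueousState(
            c_hydronium=h,
            c_hydroxide=K_W / h,
            c_neutral_solute=c_neutral_aq,
            c_charged_solute=c_charged_aq,
        ),
        c_neutral_org=c_neutral_org,
        c_charged_org=c_charged_org,
        pH=ph_root,
        logD=logD,
        logP_apparent=logP,
        degree_of_ionization_aq=ionized,
    )


def closed_form_dow(solute: Solute, P_neutral_0: float) -> float:
    """Distribution coefficient at the zero-concentration limit.

    At infinite dilution the aqueous pH is 7, so
    ``D_OW = P_N0 / (1 + 10**(7 - pKa))`` for an acid,
    ``D_OW = P_N0 / (1 + 10**(pKa - 7))`` for a base, and simply
    ``P_N0`` for a neutral solute (assuming the charged species does not
    partition into the organic phase).
    """
    if P_neutral_0 <= 0.0:
        raise ValueError("P_neutral_0 must be > 0")
    if not solute.is_ionizable:
        return P_neutral_0
    if solute.ionization_class is IonizationClass.ACID:
        return P_neutral_0 / (1.0 + 10.0 ** (7.0 - solute.pKa))
    return P_neutral_0 / (1.0 + 10.0 ** (solute.pKa - 7.0))


def simulate_series(
    solute: Solute,
    system: BiphasicSystem,
    c_total_grid: Sequence[float] = DEFAULT_CONC_GRID,
    noise: Optional[NoiseModel] = None,
) -> MeasurementSeries:
    """Generate a synthetic measurement series over a concentration grid.

    For each overall concentration the equilibrium is solved exactly,
    then multiplicative lognormal noise is applied to both phase
    concentrations and additive Gaussian noise to the pH, emulating the
    scatter of triplicate shake-flask analyses. With zero sigmas the
    measurements equal the noiseless equilibrium bit for bit. The output
    is directly consumable by the data-reduction fits.
    """
    if noise is None:
        noise = NoiseModel(rel_conc_sigma=0.0, ph_sigma=0.0, seed=0)
    grid = [float(c) for c in c_total_grid]
    if any(c <= 0.0 for c in grid):
        raise ValueError("grid concentrations must be > 0")
    rng = np.random.default_rng(noise.seed)
    v_total = system.volume_org + system.volume_aq
    measurements: List[PartitionMeasurement] = []
    for c_total in grid:
        state = solve_equilibrium(solute, system, c_total * v_total)
        c_org, c_aq = state.c_total_org, state.c_total_aq
        pH = state.pH
        if noise.rel_conc_sigma > 0.0:
            c_org = c_org * math.exp(noise.rel_conc_sigma * rng.standard_normal())
            c_aq = c_aq * math.exp(noise.rel_conc_sigma * rng.standard_normal())
        if noise.ph_sigma > 0.0:
            pH = pH + noise.ph_sigma * rng.standard_normal()
        measurements.append(
            PartitionMeasurement(
                c_total=c_total,
                c_org=c_org,
                c_aq=c_aq,
                pH_aq=pH,
                temperature=system.temperature,
                c_org_sd=noise.rel_conc_sigma * c_org if noise.rel_conc_sigma else None,
                c_aq_sd=noise.rel_conc_sigma * c_aq if noise.rel_conc_sigma else None,
            )
        )
    return MeasurementSeries(
        solute=solute,
        measurements=measurements,
        volume_ratio_org_to_aq=system.volume_org / system.volume_aq,
        ionic_strength=0.0,
    )


def equilibrium_states_for_grid(
    solute: Solute,
    system: BiphasicSystem,
    c_total_grid: Sequence[float],
) -> List[EquilibriumState]:
    """Noiseless species-resolved states for each grid concentration."""
    v_total = system.volume_org + system.volume_aq
    return [
        solve_equilibrium(solute, system, float(c) * v_total) for c in c_total_grid
    ]
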