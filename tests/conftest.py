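import pytest

from kowkit import BiphasicSystem, IonizationClass, Solute

#: Four-point dilute concentration grid (mol/L) used for recovery
#: validation: deep inside the regime where both extrapolation methods
#: are exact (solute nearly fully ionized, pH close to 7).
DILUTE_GRID = (1e-9, 1e-8, 1e-7, 1e-6)

#: Lab-style grid straddling the OECD per-phase ceiling.
LAB_GRID = (1e-3, 2.5e-3, 5e-3, 1e-2)


@pytest.fixture
def naproxen() -> Solute:
    return Solute("naproxen", IonizationClass.ACID, pKa=4.18)


@pytest.fixture
def ibuprofen() -> Solute:
    return Solute("ibuprofen", IonizationClass.ACID, pKa=4.42)


@pytest.fixture
def lidocaine() -> Solute:
    return Solute("lidocaine", IonizationClass.BASE, pKa=7.92)


@pytest.fixture
def griseofulvin() -> Solute:
    return Solute("griseofulvin", IonizationClass.NEUTRAL)


@pytest.fixture
def default_system() -> BiphasicSystem:
    """1:3 organic:aqueous volumes, log K_OW = 3, ideal behaviour."""
    return BiphasicSystem(volume_org=0.25, volume_aq=0.75, P_neutral_0=1000.0)
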