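import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kowkit import (
    BiphasicSystem,
    IonizationClass,
    K_W,
    NoiseModel,
    Solute,
    SolverError,
    closed_form_dow,
    dissociation_quotient,
    logp_from_logd,
    simulate_series,
    solve_equilibrium,
)
from conftest import DILUTE_GRID, LAB_GRID


# ---------------------------------------------------------------------------
# Independent grid-scan oracle: locate the equilibrium by brute force over
# hydronium concentration, using its own speciation arithmetic.
# ---------------------------------------------------------------------------

def _oracle_residual(h, Ka, P_N, P_ion, v_aq, v_org, n_total, is_acid):
    oh = K_W / h
    if is_acid:
        c_charged = h - oh
        c_neutral = c_charged * h / Ka
    else:
        c_charged = oh - h
        c_neutral = c_charged * Ka / h
    n = v_aq * (c_neutral + c_charged) + v_org * (P_N * c_neutral + P_ion * c_charged)
    return n - n_total


def _oracle_solve(solute, system, n_total, n_grid=1_000_000):
    """Scan c_H3O+ over a dense log grid, then refine by bisection."""
    Ka = 10.0**-solute.pKa
    is_acid = solute.ionization_class is IonizationClass.ACID
    args = (Ka, system.P_neutral_0, system.P_ion, system.volume_aq,
            system.volume_org, n_total, is_acid)
    hs = np.logspace(-14, 0, n_grid)
    res = np.array([_oracle_residual(h, *args) for h in hs])
    sign = np.sign(res)
    (idx,) = np.nonzero(sign[:-1] * sign[1:] < 0)
    a, b = hs[idx[0]], hs[idx[0] + 1]
    fa = _oracle_residual(a, *args)
    for _ in range(200):
        m = 0.5 * (a + b)
        if m == a or m == b:
            break
        fm = _oracle_residual(m, *args)
        if (fm < 0) == (fa < 0):
            a, fa = m, fm
        else:
            b = m
    h = 0.5 * (a + b)
    oh = K_W / h
    c_charged = (h - oh) if is_acid else (oh - h)
    c_neutral = c_charged * h / Ka if is_acid else c_charged * Ka / h
    logd = math.log10(
        system.P_neutral_0 * c_neutral / (c_neutral + c_charged)
    )
    return -math.log10(h), logd


class TestSolverAgainstOracle:
    def test_acid_equal_volumes_dense_scan(self, naproxen):
        system = BiphasicSystem(
            volume_org=0.5, volume_aq=0.5, P_neutral_0=1e3, P_ion=0.0
        )
        n_total = 1e-2 * (system.volume_org + system.volume_aq)
        ph_ref, logd_ref = _oracle_solve(naproxen, system, n_total)
        state = solve_equilibrium(naproxen, system, n_total)
        assert state.pH == pytest.approx(ph_ref, abs=1e-6)
        assert state.logD == pytest.approx(logd_ref, abs=1e-6)

    def test_base_against_scan(self, lidocaine, default_system):
        n_total = 1e-3
        ph_ref, logd_ref = _oracle_solve(lidocaine, default_system, n_total)
        state = solve_equilibrium(lidocaine, default_system, n_total)
        assert state.pH == pytest.approx(ph_ref, abs=1e-6)
        assert state.logD == pytest.approx(logd_ref, abs=1e-6)


class TestConservation:
    @given(
        pka=st.floats(min_value=2.5, max_value=11.5),
        log_p0=st.floats(min_value=-1.0, max_value=5.0),
        log_n=st.floats(min_value=-10.0, max_value=-2.0),
        v_org=st.floats(min_value=0.05, max_value=1.0),
        v_aq=st.floats(min_value=0.05, max_value=1.0),
        is_acid=st.booleans(),
        p_ion=st.floats(min_value=0.0, max_value=0.1),
    )
    @settings(max_examples=150, deadline=None)
    def test_mass_and_charge_balance(
        self, pka, log_p0, log_n, v_org, v_aq, is_acid, p_ion
    ):
        cls = IonizationClass.ACID if is_acid else IonizationClass.BASE
        solute = Solute("x", cls, pKa=pka)
        system = BiphasicSystem(
            volume_org=v_org, volume_aq=v_aq, P_neutral_0=10.0**log_p0, P_ion=p_ion
        )
        n_total = 10.0**log_n
        state = solve_equilibrium(solute, system, n_total)
        n_back = system.volume_aq * state.c_total_aq + system.volume_org * (
            state.c_neutral_org + state.c_charged_org
        )
        assert abs(n_back - n_total) / n_total < 1e-9
        aq = state.aqueous
        if is_acid:
            charge_gap = aq.c_hydronium - (aq.c_charged_solute + aq.c_hydroxide)
        else:
            charge_gap = (aq.c_charged_solute + aq.c_hydronium) - aq.c_hydroxide
        assert abs(charge_gap) <= 1e-9 * max(aq.c_hydronium, aq.c_hydroxide)

    @given(
        pka=st.floats(min_value=2.5, max_value=11.5),
        log_p0=st.floats(min_value=-1.0, max_value=5.0),
        log_n=st.floats(min_value=-10.0, max_value=-2.0),
        is_acid=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_solver_state_reproduces_pka(self, pka, log_p0, log_n, is_acid):
        cls = IonizationClass.ACID if is_acid else IonizationClass.BASE
        solute = Solute("x", cls, pKa=pka)
        system = BiphasicSystem(P_neutral_0=10.0**log_p0)
        state = solve_equilibrium(solute, system, 10.0**log_n)
        assert dissociation_quotient(state.aqueous, cls) == pytest.approx(
            pka, abs=1e-9
        )


class TestLimitsAndMonotonicity:
    def test_infinite_dilution_acid(self, naproxen, default_system):
        state = solve_equilibrium(naproxen, default_system, 1e-12)
        assert state.pH == pytest.approx(7.0, abs=1e-3)
        assert state.pH < 7.0
        expected = math.log10(closed_form_dow(naproxen, 1000.0))
        assert state.logD == pytest.approx(expected, abs=1e-3)

    def test_infinite_dilution_base(self, lidocaine, default_system):
        state = solve_equilibrium(lidocaine, default_system, 1e-12)
        assert state.pH == pytest.approx(7.0, abs=1e-3)
        assert state.pH > 7.0
        expected = math.log10(closed_form_dow(lidocaine, 1000.0))
        assert state.logD == pytest.approx(expected, abs=1e-3)

    def test_ph_sides_and_logd_monotonicity(self, naproxen, lidocaine, default_system):
        grid = np.logspace(-7, -2, 12)
        for solute, side in ((naproxen, -1), (lidocaine, +1)):
            states = [solve_equilibrium(solute, default_system, c) for c in grid]
            phs = [s.pH for s in states]
            logds = [s.logD for s in states]
            assert all((p - 7.0) * side > 0 for p in phs)
            # log D rises with concentration; pH runs away from 7
            assert all(a < b for a, b in zip(logds, logds[1:]))
            assert all((b - a) * side > 0 for a, b in zip(phs, phs[1:]))
            # apparent log P stays at the configured value when s = 0
            for s in states:
                assert s.logP_apparent == pytest.approx(3.0, abs=1e-12)

    def test_neutral_trivial_partition(self, griseofulvin):
        system = BiphasicSystem(P_neutral_0=10**1.34, conc_slope_s=0.0)
        state = solve_equilibrium(griseofulvin, system, 5e-3)
        assert state.logD == state.logP_apparent == pytest.approx(1.34)
        assert state.pH == 7.0
        assert state.degree_of_ionization_aq == 0.0


class TestIonizationCorrectionConsistency:
    @pytest.mark.parametrize("pka", [3.0, 4.18, 7.92, 10.0])
    @pytest.mark.parametrize("cls", [IonizationClass.ACID, IonizationClass.BASE])
    @pytest.mark.parametrize("c_total", [1e-6, 1e-4, 1e-2])
    def test_species_resolved_logp_matches_correction(self, pka, cls, c_total):
        """With the ion confined to water, the species-resolved apparent
        log P must equal the ionization-corrected log D from first
        principles, at any concentration."""
        solute = Solute("x", cls, pKa=pka)
        system = BiphasicSystem(P_neutral_0=10**2.5, P_ion=0.0)
        state = solve_equilibrium(solute, system, c_total)
        converted = logp_from_logd(state.logD, state.pH, solute)
        assert converted == pytest.approx(state.logP_apparent, abs=1e-9)


class TestClosedFormDow:
    def test_neutral_identity(self, griseofulvin):
        assert closed_form_dow(griseofulvin, 123.4) == 123.4

    def test_acid_value(self, naproxen):
        assert closed_form_dow(naproxen, 1000.0) == pytest.approx(
            1.5112738, rel=1e-6
        )

    def test_base_value(self, lidocaine):
        assert closed_form_dow(lidocaine, 1000.0) == pytest.approx(
            107.32334, rel=1e-6
        )


class TestSimulateSeries:
    def test_zero_noise_matches_equilibrium_exactly(self, naproxen, default_system):
        series = simulate_series(
            naproxen, default_system, LAB_GRID, NoiseModel(0.0, 0.0, 0)
        )
        for c, m in zip(LAB_GRID, series.measurements):
            state = solve_equilibrium(naproxen, default_system, c * 1.0)
            assert m.c_org == state.c_total_org
            assert m.c_aq == state.c_total_aq
            assert m.pH_aq == state.pH

    def test_seed_determinism(self, naproxen, default_system):
        a = simulate_series(naproxen, default_system, LAB_GRID, NoiseModel(seed=42))
        b = simulate_series(naproxen, default_system, LAB_GRID, NoiseModel(seed=42))
        c = simulate_series(naproxen, default_system, LAB_GRID, NoiseModel(seed=43))
        assert [m.c_org for m in a.measurements] == [m.c_org for m in b.measurements]
        assert [m.c_org for m in a.measurements] != [m.c_org for m in c.measurements]

    def test_noise_scale(self, naproxen, default_system):
        """5% lognormal noise perturbs concentrations by a few percent."""
        noisy = simulate_series(
            naproxen, default_system, DILUTE_GRID, NoiseModel(0.05, 0.02, seed=7)
        )
        clean = simulate_series(
            naproxen, default_system, DILUTE_GRID, NoiseModel(0.0, 0.0, seed=7)
        )
        ratios = [
            n.c_org / c.c_org for n, c in zip(noisy.measurements, clean.measurements)
        ]
        assert all(0.7 < r < 1.4 for r in ratios)
        assert any(abs(r - 1.0) > 1e-4 for r in ratios)

    def test_rejects_nonpositive_grid(self, naproxen, default_system):
        with pytest.raises(ValueError):
            simulate_series(naproxen, default_system, [1e-3, 0.0])


class TestSolverErrors:
    def test_negative_amount_rejected(self, naproxen, default_system):
        with pytest.raises(ValueError):
            solve_equilibrium(naproxen, default_system, -1.0)

    def test_unbracketable_amount_raises_with_diagnostics(self, naproxen):
        system = BiphasicSystem(volume_org=0.25, volume_aq=0.75, P_neutral_0=1.0)
        with pytest.raises(SolverError, match="sign change"):
            solve_equilibrium(naproxen, system, 1e18)
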