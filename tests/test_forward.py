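"""Forward transport model: elementary relations, flows and the steady solver.

The steady solver is checked against a closed-form solution derived
independently here: with zero ISF advection the ISF concentration field is
spatially uniform (its equation reduces to a 0-D balance) and the gland is
a constant-coefficient advection–diffusion–reaction ODE solvable in
exponentials; the coupling reduces to one scalar balance solved by
bracketing.  The oracle shares no code with the finite-volume path.
"""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from sweatkin import (
    SimulationGrid,
    capillary_filtration,
    dilute,
    gland_flow,
    hydraulic_resistance,
    isf_velocity,
    plasma_to_isf_flux,
    simulate,
    solve_pressure_balance,
    wall_flux_density,
)
from sweatkin.forward import DomainError, NumericalError


class TestHydraulicResistance:
    def test_reference_value(self, defaults):
        # 128 · 1e-3 · 4e-3 / (π · (5e-6)^4), evaluated by hand
        r = hydraulic_resistance(defaults.mu, defaults.L, defaults.d)
        assert r == pytest.approx(2.6076e17, rel=1e-4)

    def test_diameter_fourth_power(self, defaults):
        r1 = hydraulic_resistance(defaults.mu, defaults.L, defaults.d)
        r2 = hydraulic_resistance(defaults.mu, defaults.L, 2 * defaults.d)
        assert r2 / r1 == pytest.approx(1 / 16)

    def test_linear_in_viscosity(self, defaults):
        r1 = hydraulic_resistance(defaults.mu, defaults.L, defaults.d)
        r2 = hydraulic_resistance(2 * defaults.mu, defaults.L, defaults.d)
        assert r2 / r1 == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [(0, 4e-3, 5e-6), (1e-3, -1, 5e-6), (1e-3, 4e-3, 0)])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            hydraulic_resistance(*bad)


class TestWaterFlows:
    def test_starling_reference_value(self, defaults):
        # 6.5e-10 · 1.5e-8 · (30 − (−3)) mmHg
        assert capillary_filtration(defaults) == pytest.approx(3.2175e-16, rel=1e-12)

    def test_zero_driving_pressure(self, defaults):
        assert capillary_filtration(defaults.replace(Pc=defaults.PISF)) == 0.0

    def test_reverse_filtration_not_clamped(self, defaults):
        assert capillary_filtration(defaults.replace(Pc=-10.0)) < 0

    def test_linear_in_conductivity(self, defaults):
        assert capillary_filtration(
            defaults.replace(Lpc=2 * defaults.Lpc)
        ) == pytest.approx(2 * capillary_filtration(defaults))

    def test_isf_velocity_reference(self):
        assert isf_velocity(3.2175e-16, 2.2e-8) == pytest.approx(1.4625e-8)

    def test_isf_velocity_edge_cases(self):
        assert isf_velocity(0.0, 2.2e-8) == 0.0
        assert isf_velocity(1e-16, 1.1e-8) == pytest.approx(2 * isf_velocity(1e-16, 2.2e-8))
        with pytest.raises(DomainError):
            isf_velocity(1e-16, 0.0)


class TestGlandFlow:
    def test_passive_calibration(self, defaults):
        # deltaP chosen so the passive Darcy velocity equals u_passive
        R = hydraulic_resistance(defaults.mu, defaults.L, defaults.d)
        fs = gland_flow(defaults, 1.5333e3, R)
        assert fs.u_sg == pytest.approx(3e-4, rel=1e-4)
        assert fs.u_sg_n == pytest.approx(1.0, rel=1e-4)

    def test_zero_pressure(self, defaults):
        fs = gland_flow(defaults, 0.0, 2.6076e17)
        assert fs.Q_water_sg == fs.u_sg == fs.u_sg_n == 0.0

    def test_sweat_velocity_scaling(self, defaults):
        R = 2.6076e17
        base = gland_flow(defaults, 1.5e3, R)
        fast = gland_flow(defaults.replace(u_sweat_n=2.0), 1.5e3, R)
        assert fast.u_sg == pytest.approx(2 * base.u_sg)
        assert fast.u_sg_n == pytest.approx(2 * base.u_sg_n)

    def test_invalid_resistance(self, defaults):
        with pytest.raises(DomainError):
            gland_flow(defaults, 1.0, 0.0)


class TestFluxes:
    def test_plasma_flux_reference(self, defaults):
        # 1.2e-3 · (10 − 2) · 3.02e-13
        assert plasma_to_isf_flux(10.0, 2.0, defaults) == pytest.approx(2.8992e-15)

    def test_plasma_flux_sign(self, defaults):
        assert plasma_to_isf_flux(5.0, 5.0, defaults) == 0.0
        assert plasma_to_isf_flux(2.0, 10.0, defaults) == -plasma_to_isf_flux(
            10.0, 2.0, defaults
        )

    def test_wall_flux_reference(self, defaults):
        # 3.01e-10 · 10 / 5e-5
        assert wall_flux_density(10.0, 0.0, defaults) == pytest.approx(6.02e-5)

    def test_wall_flux_properties(self, defaults):
        assert wall_flux_density(4.0, 4.0, defaults) == 0.0
        thick = defaults.replace(hsg=2 * defaults.hsg)
        assert wall_flux_density(10.0, 0.0, thick) == pytest.approx(
            wall_flux_density(10.0, 0.0, defaults) / 2
        )


class TestDilute:
    def test_direct_substitution(self):
        assert dilute(7.0, 2.5, 1.0) == pytest.approx(2.0)

    def test_no_water_excess_is_identity(self):
        assert dilute(3.3, 0.0, 0.7) == 3.3

    def test_monotone_in_velocity_with_limit(self):
        values = [dilute(7.0, 2.5, u) for u in (0.5, 1.0, 2.0, 10.0, 1e6)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(7.0, rel=1e-5)

    def test_invalid_velocity(self):
        with pytest.raises(DomainError):
            dilute(1.0, 2.5, 0.0)


class TestPressureBalance:
    def test_fixed_mode_calibrated_delta(self, defaults):
        pisf, deltaP = solve_pressure_balance(defaults, "fixed")
        assert pisf == defaults.PISF
        assert deltaP == pytest.approx(1.533e3, rel=1e-3)

    def test_balanced_mode_equates_flows(self, defaults):
        pisf, deltaP = solve_pressure_balance(defaults, "balanced")
        q_in = defaults.Lpc * defaults.Ac * (defaults.Pc - pisf)
        q_out = deltaP / hydraulic_resistance(defaults.mu, defaults.L, defaults.d)
        assert abs(q_in - q_out) / q_in < 1e-6
        assert defaults.PISF < pisf < defaults.Pc

    def test_blocked_gland_stops_filtration(self, defaults):
        # R → ∞ (huge viscosity): interstitial pressure rises to Pc
        blocked = defaults.replace(mu=1e9)
        pisf, _ = solve_pressure_balance(blocked, "balanced")
        assert pisf == pytest.approx(defaults.Pc, rel=1e-6)


# ---------------------------------------------------------------------------
# closed-form oracle (independent derivation)
# ---------------------------------------------------------------------------

def _analytic_steady(p, C_blood, s_gland):
    """Uniform-ISF / exponential-gland solution for zero ISF advection.

    Gland: D G'' − u G' + kw (x − G) + s = 0 with a Danckwerts inflow of
    pure water (u·G(0) − D·G'(0) = 0) and zero diffusive flux at the exit;
    ISF balance: kDE·Vp·(C_blood − x) = net wall flux.
    Returns (x, G(L)).
    """
    D, L = p.Dsw, p.L
    u = p.u_passive * p.u_sweat_n
    kw = math.pi * p.d * p.Dsg_wall / (p.hsg * p.Asg)
    kDEVp = p.kDE * p.Vp

    def gland(x):
        Gp = x + s_gland / kw
        disc = math.sqrt(u * u + 4 * D * kw)
        rp, rm = (u + disc) / (2 * D), (u - disc) / (2 * D)
        e1 = math.exp(-min(rp * L, 700.0))
        e2 = math.exp(rm * L)
        # unknowns: a = A e^{rp L} (exit-layer amplitude), B
        M = np.array([[(u - D * rp) * e1, u - D * rm], [rp, rm * e2]])
        a, B = np.linalg.solve(M, np.array([-u * Gp, 0.0]))
        exit_value = Gp + a + B * e2
        integral = Gp * L + a / rp * (1 - e1) + B / rm * (e2 - 1)
        return exit_value, integral

    def balance(x):
        _, integral = gland(x)
        wall = kw * p.Asg * (x * L - integral)
        return kDEVp * (C_blood - x) - wall

    x = brentq(balance, -1e3, 1e4, xtol=1e-14)
    exit_value, _ = gland(x)
    return x, exit_value


class TestSimulate:
    def test_no_source_means_no_sweat_urea(self, defaults, coarse_grid):
        res = simulate(0.0, defaults, coarse_grid)
        assert res.C_sweat == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.C_ISF_profile, 0.0, atol=1e-12)

    def test_passive_sweat_below_blood(self, defaults, coarse_grid):
        for blood in (0.5, 6.4, 20.0, 50.0):
            for u_n in (0.5, 1.0, 3.0):
                res = simulate(blood, defaults.replace(u_sweat_n=u_n), coarse_grid)
                assert 0 <= res.C_sweat < blood

    def test_monotone_in_blood_and_active_rate(self, defaults, coarse_grid):
        bloods = np.linspace(1.0, 40.0, 5)
        rates = np.linspace(0.0, 1.0, 5)
        sweat = np.array(
            [
                [simulate(b, defaults.replace(S=s), coarse_grid).C_sweat for s in rates]
                for b in bloods
            ]
        )
        assert np.all(np.diff(sweat, axis=0) > 0)  # strictly increasing in blood
        assert np.all(np.diff(sweat, axis=1) > 0)  # increasing in S (gland source)

    def test_grid_refinement_converged(self, defaults):
        p = defaults.replace(S=0.36, u_sweat_n=2.8)
        c1 = simulate(6.4, p, SimulationGrid(n_isf=40, n_sg=200)).C_sweat
        c2 = simulate(6.4, p, SimulationGrid(n_isf=80, n_sg=400)).C_sweat
        assert abs(c2 - c1) / c1 < 0.005

    def test_dilution_recomputation_bit_identical(self, defaults, coarse_grid):
        p = defaults.replace(S=0.2, u_sweat_n=1.7)
        res = simulate(10.0, p, coarse_grid)
        external = dilute(res.C_sg_profile[-1], p.Kwu, res.flows.u_sg_n)
        assert res.C_sweat == external

    @pytest.mark.parametrize("s_mode,S", [
        ("gland_source", 0.36), ("literal", 0.002), ("conservative", 0.002),
    ])
    def test_mass_balance_closes(self, defaults, coarse_grid, s_mode, S):
        res = simulate(6.4, defaults.replace(S=S), coarse_grid, s_mode=s_mode)
        assert res.converged
        assert res.mass_balance_residual < 1e-3

    def test_literal_mode_reports_transfer_imbalance(self, defaults, coarse_grid):
        S = 0.002
        res = simulate(6.4, defaults.replace(S=S), coarse_grid, s_mode="literal")
        expected = S * (defaults.Asg * defaults.L - defaults.VISF)
        assert res.active_transfer_imbalance == pytest.approx(expected, rel=1e-9)

    def test_literal_mode_rejects_unsupplyable_sink(self, defaults, coarse_grid):
        # an ISF sink of physiological magnitude exceeds the plasma supply
        with pytest.raises(NumericalError):
            simulate(6.4, defaults.replace(S=0.36), coarse_grid, s_mode="literal")

    def test_negative_blood_rejected(self, defaults):
        with pytest.raises(DomainError):
            simulate(-1.0, defaults)

    def test_invalid_params_rejected(self, defaults):
        with pytest.raises(DomainError, match="d "):
            simulate(1.0, defaults.replace(d=0.0))

    def test_closed_form_oracle_zero_isf_advection(self, defaults):
        # Pc = PISF shuts off capillary filtration, hence ISF advection;
        # the ISF field then has a uniform closed-form solution
        p = defaults.replace(Pc=defaults.PISF, S=0.36, u_sweat_n=2.8)
        x, exit_value = _analytic_steady(p, 6.4, p.S)
        res = simulate(6.4, p, SimulationGrid(n_isf=40, n_sg=200))
        assert np.ptp(res.C_ISF_profile) / x < 1e-6  # profile is uniform
        assert abs(res.C_ISF_profile.mean() - x) / x < 1e-3
        assert abs(res.C_sg_profile[-1] - exit_value) / exit_value < 1e-3

    def test_oracle_passive_limit(self, defaults):
        p = defaults.replace(Pc=defaults.PISF, u_sweat_n=1.0)
        x, exit_value = _analytic_steady(p, 10.0, 0.0)
        res = simulate(10.0, p, SimulationGrid(n_isf=40, n_sg=200))
        assert abs(res.C_ISF_profile.mean() - x) / x < 1e-3
        assert abs(res.C_sg_profile[-1] - exit_value) / exit_value < 1e-3

    def test_result_metadata(self, defaults, coarse_grid):
        res = simulate(6.4, defaults, coarse_grid)
        assert res.converged and res.steps == 1
        assert res.C_sweat == res.C_sg_dil_profile[-1]
        assert res.J_source > 0
        assert len(res.C_ISF_profile) == coarse_grid.n_isf
        assert len(res.C_sg_profile) == coarse_grid.n_sg


class TestGridValidation:
    def test_node_minimum(self):
        with pytest.raises(DomainError):
            SimulationGrid(n_isf=4)

    def test_tolerance_range(self):
        with pytest.raises(DomainError):
            SimulationGrid(convergence_tol=0.5)
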