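"""Steady-state simulator of urea transport along a single sweat gland.

The model chains three compartments:

1. a 0-D plasma (capillary) compartment at fixed urea concentration
   ``C_blood``, which exchanges urea with the ISF at rate
   ``kDE · (C_blood − mean C_ISF) · Vp`` and filters water by the Starling
   relation ``Lpc · Ac · (Pc − PISF)``;
2. a 1-D interstitial-fluid (ISF) domain carrying urea by
   convection–diffusion, fed by the plasma flux (distributed uniformly) and
   drained through the gland wall;
3. a 1-D sweat-gland lumen carrying urea by convection–diffusion toward the
   skin surface, receiving Fickian wall flux from the ISF and an active
   transport source ``S``; the water flow through the gland follows a
   Poiseuille (Darcy) law and dilutes the exiting urea by the water/urea
   flow ratio ``Kwu``.

The steady problem is linear in the two concentration fields, so the
finite-volume discretization (first-order upwind advection, central
diffusion) is solved directly as one linear system rather than by
pseudo-time marching; the solution is the exact steady state of the
discrete scheme and the discrete mass balance telescopes to machine
precision, which :func:`simulate` verifies and reports.

Active-transport bookkeeping (``s_mode``)
-----------------------------------------
``"gland_source"`` (default)
    ``S`` acts as a volumetric source in the gland lumen only.  Physically
    this treats actively transported urea as drawn from the epidermal /
    gland-wall cellular reservoir rather than from the ISF pool: with the
    default constants the plasma→ISF clearance (``kDE·Vp`` ≈ 3.6e-16 m³/s)
    cannot supply the molar rate ``S·V`` implied by physiological ``S``
    values, so an ISF-side sink of that size would drive the ISF
    concentration negative.  Concentrations stay non-negative for all
    ``S ≥ 0`` in this mode.
``"literal"``
    ``S`` is simultaneously a volumetric sink in the ISF and a volumetric
    source in the gland, both at the same rate.  Because the two domains
    have different volumes this does not conserve mass; the implied
    external gain/loss is reported as ``active_transfer_imbalance``.  Only
    usable for small ``S`` (the solver rejects negative concentrations).
``"conservative"``
    The ISF sink is ``S`` and the gland source is rescaled by
    ``VISF / (Asg·L)`` so the molar transfer balances exactly.  Also only
    usable for small ``S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import MMHG_TO_PA, ModelParameters, validate

S_MODES = ("gland_source", "literal", "conservative")
PRESSURE_MODES = ("fixed", "balanced")


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class NumericalError(ArithmeticError):
    """The discrete solution violates a physical invariant (e.g. negativity)."""


@dataclass(frozen=True)
class SimulationGrid:
    """Discretization of the ISF and gland domains.

    ``isf_length`` defaults to ``VISF / AISF`` (the length consistent with
    the tabulated ISF volume and cross-section) and ``sg_length`` to the
    gland length ``L``; both may be overridden.
    """

    n_isf: int = 40
    n_sg: int = 200
    isf_length: float | None = None
    sg_length: float | None = None
    convergence_tol: float = 1e-6
    max_steps: int = 500

    def __post_init__(self) -> None:
        if self.n_isf < 8 or self.n_sg < 8:
            raise DomainError("node counts must be >= 8")
        if not (0 < self.convergence_tol <= 1e-2):
            raise DomainError("convergence_tol must lie in (0, 1e-2]")
        for name in ("isf_length", "sg_length"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be positive")

    def resolved_lengths(self, params: ModelParameters) -> tuple[float, float]:
        l_isf = self.isf_length if self.isf_length is not None else params.VISF / params.AISF
        l_sg = self.sg_length if self.sg_length is not None else params.L
        return l_isf, l_sg


@dataclass(frozen=True)
class FlowState:
    """Water flows and velocities at the operating point."""

    Q_water: float  # capillary filtration rate (m³ s⁻¹)
    u_ISF: float  # ISF water velocity (m s⁻¹)
    R: float  # gland hydraulic resistance (Pa s m⁻³)
    deltaP: float  # gland driving pressure (Pa)
    Q_water_sg: float  # gland water flow (m³ s⁻¹)
    u_sg: float  # gland water velocity (m s⁻¹)
    u_sg_n: float  # u_sg normalized to the passive reference velocity


@dataclass(frozen=True)
class SimulationResult:
    """Steady-state concentration fields and derived readouts."""

    C_ISF_profile: np.ndarray  # mol m⁻³ per ISF node
    C_sg_profile: np.ndarray  # undiluted gland concentration per node
    C_sg_dil_profile: np.ndarray  # diluted gland concentration per node
    C_sweat: float  # diluted concentration at the gland exit (mol m⁻³)
    flows: FlowState
    J_source: float  # plasma → ISF urea flow (mol s⁻¹)
    converged: bool
    steps: int
    mass_balance_residual: float
    active_transfer_imbalance: float = 0.0  # mol s⁻¹ injected (+) by s_mode
    y_isf: np.ndarray = field(default=None, repr=False)  # node coordinates (m)
    y_sg: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

def hydraulic_resistance(mu: float, L: float, d: float) -> float:
    """Poiseuille resistance ``128 μ L / (π d⁴)`` of the gland duct (Pa s m⁻³)."""
    if mu <= 0 or L <= 0 or d <= 0:
        raise DomainError("mu, L and d must be strictly positive")
    return 128.0 * mu * L / (math.pi * d**4)


def capillary_filtration(params: ModelParameters) -> float:
    """Starling filtration ``Lpc · Ac · (Pc − PISF)`` (m³ s⁻¹).

    A negative pressure difference yields negative (reverse) flow; it is not
    clamped.
    """
    return params.Lpc * params.Ac * (params.Pc - params.PISF)


def isf_velocity(Q_water: float, AISF: float) -> float:
    """ISF water velocity, filtration rate over cross-sectional area (m s⁻¹)."""
    if AISF <= 0:
        raise DomainError("AISF must be strictly positive")
    return Q_water / AISF


def gland_flow(params: ModelParameters, deltaP: float, R: float) -> FlowState:
    """Darcy flow through the gland and the resulting sweat velocity.

    ``u_sg`` scales the passive Darcy velocity by the measured normalized
    sweat velocity ``u_sweat_n`` so stimulated sweating can be represented.
    """
    if R <= 0:
        raise DomainError("R must be strictly positive")
    if deltaP < 0:
        raise DomainError("deltaP must be non-negative")
    Q_water_sg = deltaP / R
    u_sg = Q_water_sg * params.u_sweat_n / params.Asg
    u_sg_n = u_sg / params.u_passive
    Q_water = capillary_filtration(params)
    return FlowState(
        Q_water=Q_water,
        u_ISF=isf_velocity(Q_water, params.AISF),
        R=R,
        deltaP=deltaP,
        Q_water_sg=Q_water_sg,
        u_sg=u_sg,
        u_sg_n=u_sg_n,
    )


def plasma_to_isf_flux(Cp: float, C_ISF: float, params: ModelParameters) -> float:
    """Plasma → ISF urea flow ``kDE · (Cp − C_ISF) · Vp`` (mol s⁻¹)."""
    return params.kDE * (Cp - C_ISF) * params.Vp


def wall_flux_density(C_ISF: float, C_sg: float, params: ModelParameters) -> float:
    """Fickian trans-wall urea flux density (mol m⁻² s⁻¹).

    The caller multiplies by the local exchange area (gland perimeter π·d
    times node length) to obtain a molar flow.
    """
    if params.hsg <= 0:
        raise DomainError("hsg must be strictly positive")
    return params.Dsg_wall * (C_ISF - C_sg) / params.hsg


def dilute(C_sg: float, Kwu: float, u_sg_n: float):
    """Dilution of gland urea by co-transported water: ``C / (1 + Kwu/u_sg_n)``."""
    if np.any(np.asarray(u_sg_n) <= 0):
        raise DomainError("u_sg_n must be strictly positive")
    if np.any(np.asarray(Kwu) < 0):
        raise DomainError("Kwu must be non-negative")
    return C_sg / (1.0 + Kwu / u_sg_n)


def solve_pressure_balance(
    params: ModelParameters, mode: str = "fixed"
) -> tuple[float, float]:
    """Interstitial pressure and gland driving pressure, per *mode*.

    ``"fixed"`` (default)
        ``PISF`` keeps its tabulated value and ``deltaP`` is calibrated so
        the passive Darcy velocity equals the reference passive sweat
        velocity: ``deltaP = u_passive · Asg · R``.
    ``"balanced"``
        Solves for the interstitial pressure at which capillary Starling
        inflow equals gland Darcy outflow (skin surface at 0 mmHg), the
        feedback by which a blocked gland shuts down filtration.

    Returns ``(PISF_effective [mmHg], deltaP [Pa])``.
    """
    R = hydraulic_resistance(params.mu, params.L, params.d)
    if mode == "fixed":
        deltaP = params.u_passive * params.Asg * R
        return params.PISF, deltaP
    if mode != "balanced":
        raise DomainError(f"unknown pressure mode: {mode!r}")

    def net_inflow(P: float) -> float:
        q_in = params.Lpc * params.Ac * (params.Pc - P)
        q_out = P * MMHG_TO_PA / R
        return q_in - q_out

    lo, hi = params.PISF, params.Pc
    f_lo, f_hi = net_inflow(lo), net_inflow(hi)
    if f_lo * f_hi > 0:
        raise NumericalError(
            "no pressure balance in (PISF, Pc): "
            f"net inflow at {lo} mmHg = {f_lo:.3e}, at {hi} mmHg = {f_hi:.3e}"
        )
    P = brentq(net_inflow, lo, hi, xtol=1e-12, rtol=1e-14)
    deltaP = max(P, 0.0) * MMHG_TO_PA
    return P, deltaP


# ---------------------------------------------------------------------------
# Steady-state solve
# ---------------------------------------------------------------------------

def _active_rates(params: ModelParameters, s_mode: str, v_sg: float) -> tuple[float, float]:
    """Volumetric (sink_in_isf, source_in_gland) rates for the chosen mode."""
    if s_mode == "gland_source":
        return 0.0, params.S
    if s_mode == "literal":
        return params.S, params.S
    if s_mode == "conservative":
        return params.S, params.S * params.VISF / v_sg
    raise DomainError(f"unknown s_mode: {s_mode!r}")


def simulate(
    C_blood: float,
    params: ModelParameters,
    grid: SimulationGrid | None = None,
    *,
    pressure_mode: str = "fixed",
    s_mode: str = "gland_source",
) -> SimulationResult:
    """Map a blood urea concentration to the sweat urea concentration.

    Solves the coupled steady convection–diffusion system on the ISF and
    gland domains and applies the water-dilution correction at the gland
    exit.  ``C_sweat`` is the diluted concentration at the last gland node
    (the skin-surface exit, the only collectable point).

    Raises
    ------
    DomainError
        for invalid inputs or parameter sets.
    NumericalError
        if the steady solution contains negative concentrations beyond
        round-off (possible in ``literal``/``conservative`` modes at large
        ``S``) or the linear solve fails.
    """
    if C_blood < 0:
        raise DomainError("C_blood must be non-negative")
    violations = validate(params)
    if violations:
        raise DomainError("invalid parameters: " + "; ".join(violations))
    if grid is None:
        grid = SimulationGrid()

    pisf_eff, deltaP = solve_pressure_balance(params, pressure_mode)
    R = hydraulic_resistance(params.mu, params.L, params.d)
    p_eff = params if pisf_eff == params.PISF else params.replace(PISF=pisf_eff)
    flows = gland_flow(p_eff, deltaP, R)

    l_isf, l_sg = grid.resolved_lengths(params)
    n1, n2 = grid.n_isf, grid.n_sg
    d1, d2 = l_isf / n1, l_sg / n2
    v_sg = params.Asg * l_sg
    s_isf, s_gland = _active_rates(params, s_mode, v_sg)

    u1 = max(flows.u_ISF, 0.0)
    u2 = flows.u_sg
    kp = params.kDE * params.Vp / params.VISF  # plasma exchange rate (s⁻¹)
    # wall conductance per gland node, molar per unit concentration (m³ s⁻¹)
    g_wall = math.pi * params.d * d2 * params.Dsg_wall / params.hsg
    k_wall_sg = g_wall / (params.Asg * d2)  # gland-side volumetric rate (s⁻¹)

    n = n1 + n2
    M = np.zeros((n, n))
    c = np.zeros(n)
    isf = slice(0, n1)
    sg = slice(n1, n)

    # --- ISF cells: 0 = kp (C_blood − C̄) + D∇² − u∇ − s_isf − wall/VISF
    mean_row = np.full(n1, 1.0 / n1)
    for i in range(n1):
        row = M[i]
        # plasma source couples to the ISF spatial mean
        row[isf] -= kp * mean_row
        c[i] += kp * C_blood
        # diffusion, zero-flux ends
        a = params.DISF / d1**2
        if i > 0:
            row[i - 1] += a
            row[i] -= a
        if i < n1 - 1:
            row[i + 1] += a
            row[i] -= a
        # upwind advection, closed ends
        if u1 > 0:
            if i > 0:
                row[i - 1] += u1 / d1
            if i < n1 - 1:
                row[i] -= u1 / d1
        # active-transport sink
        c[i] -= s_isf
        # wall drain, distributed uniformly over the ISF volume
        row[isf] -= (n2 * g_wall / params.VISF) * mean_row
        for j in range(n2):
            row[n1 + j] += g_wall / params.VISF

    # --- gland cells: 0 = D∇² − u∇ + s_gland + k_wall (C̄ − G)
    a2 = params.Dsw / d2**2
    for j in range(n2):
        i = n1 + j
        row = M[i]
        if j > 0:
            row[i - 1] += a2
            row[i] -= a2
        # inlet face: prescribed total flux u·C_in = 0 (pure water enters the
        # coil); no separate diffusive term — the Danckwerts inflow condition
        if j < n2 - 1:
            row[i + 1] += a2
            row[i] -= a2
        # upwind advection; inflow carries zero concentration, outflow advective
        if j > 0:
            row[i - 1] += u2 / d2
        row[i] -= u2 / d2
        c[i] += s_gland
        row[isf] += k_wall_sg * mean_row
        row[i] -= k_wall_sg

    try:
        x = np.linalg.solve(M, -c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"steady-state solve failed: {exc}") from exc

    scale = max(1.0, float(np.max(np.abs(x))))
    if np.min(x) < -1e-8 * scale:
        raise NumericalError(
            "steady state contains negative concentrations "
            f"(min {np.min(x):.4e}); the configured s_mode={s_mode!r} cannot "
            f"sustain S={params.S} from the available plasma supply"
        )
    x = np.clip(x, 0.0, None)

    C_isf = x[isf].copy()
    C_g = x[sg].copy()
    c_mean = float(np.mean(C_isf))
    J_source = params.kDE * (C_blood - c_mean) * params.Vp

    # discrete mass balance: plasma in + active source = active sink +
    # advective outflow at the gland exit
    outflow = u2 * params.Asg * C_g[-1]
    s_in = s_gland * v_sg
    s_out = s_isf * params.VISF
    total_in = J_source + s_in
    total_out = s_out + outflow
    denom = max(abs(total_in), abs(total_out), 1e-300)
    residual = abs(total_in - total_out) / denom

    C_dil = np.asarray(dilute(C_g, params.Kwu, flows.u_sg_n))
    y1 = (np.arange(n1) + 0.5) * d1
    y2 = (np.arange(n2) + 0.5) * d2

    return SimulationResult(
        C_ISF_profile=C_isf,
        C_sg_profile=C_g,
        C_sg_dil_profile=C_dil,
        C_sweat=float(C_dil[-1]),
        flows=flows,
        J_source=J_source,
        converged=bool(residual < max(grid.convergence_tol, 1e-6)),
        steps=1,
        mass_balance_residual=float(residual),
        active_transfer_imbalance=float(s_in - s_out),
        y_isf=y1,
        y_sg=y2,
    )
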