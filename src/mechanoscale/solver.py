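"""Shooting solver and self-consistency fixed point for the decay length.

The steady-state equation is integrated *inward* from the outer boundary —
the stable direction for capturing the decaying mode — starting from a
guessed boundary value ``phi(R)`` with the slope of a decaying exponential,
and the guess is root-found so the prescribed source flux ``-dphi/dr|_a = j``
is met.  Clamped problems are integrated in the shifted field
``psi = phi - phi_b`` which satisfies the same equation as the free case
(``psi'' = -(d-1)/r psi' + psi^2 + psi/lambda^2``) and decays to zero.

At fixed interaction strength ``|V0|`` the decay length must satisfy the
self-consistency condition ``lambda^-2 = |V0| phibar / lambda0^2`` with
``phibar`` the volume-averaged concentration of the profile solved *at that
lambda*; a damped fixed-point iteration on ``lambda^2`` converges to the
size-dependent ``lambda(R)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp
from scipy.optimize import brentq

from .errors import (
    InvalidParameterError,
    NonConvergenceError,
    NoSolutionError,
    OracleFailureError,
    SolverError,
)
from .model import (
    CLAMPED,
    FREE,
    LAMBDA0,
    ModelParams,
    Profile,
    STRONG,
    bulk_value,
    volume_average,
)

logger = logging.getLogger("mechanoscale")

#: Output grid resolution (points per decade of radius).
POINTS_PER_DECADE = 400

#: Excess-field cap signalling inner blow-up during inward integration.
_BLOWUP_CAP = 1.0e6


@dataclass(frozen=True)
class SolverSettings:
    """Numerical tolerances for the shooting and fixed-point iterations."""

    flux_rel_tol: float = 1e-6
    lambda_rel_tol: float = 1e-4
    max_fixed_point_iters: int = 100
    damping: float = 0.5
    integrator_rel_tol: float = 1e-9

    def __post_init__(self):
        for name in ("flux_rel_tol", "lambda_rel_tol", "integrator_rel_tol"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0 < self.damping <= 1:
            raise InvalidParameterError("damping must lie in (0, 1]")
        if self.max_fixed_point_iters < 1:
            raise InvalidParameterError("max_fixed_point_iters must be >= 1")


@dataclass
class SelfConsistentSolution:
    """Converged decay length with its profile and iteration history."""

    profile: Profile
    lambda_star: float
    mean_phi: float
    iterations: int
    consistency_residual: float
    trace: List[Tuple[float, float]] = field(default_factory=list)


def outer_bc_slope(phi_R: float, lambda_eff: float, params: ModelParams) -> float:
    """Slope paired with ``phi(R)`` for a decaying far-field solution.

    Free boundaries: ``-phi(R) (1/lambda + (d-1)/(2R))`` from the decaying
    form ``exp(-r/lambda)/r^((d-1)/2)``.  Clamped: ``-(phi(R)-phi_b)/lambda``
    on the excess over the bulk value.
    """
    if lambda_eff <= 0:
        raise InvalidParameterError("lambda_eff must be positive")
    phi_b = bulk_value(lambda_eff, params.boundary)
    if phi_R < phi_b:
        raise InvalidParameterError(
            f"phi(R) = {phi_R:g} is below the bulk value {phi_b:g}"
        )
    if params.boundary == FREE:
        curv = (params.dimension - 1) / (2.0 * params.system_size)
        return -phi_R * (1.0 / lambda_eff + curv)
    return -(phi_R - phi_b) / lambda_eff


def _excess_rhs_factory(dimension: int, lambda_eff: float, linear_only: bool):
    """RHS of the excess field psi (free-sign equation in every case)."""
    inv_l2 = 1.0 / lambda_eff**2
    dm1 = dimension - 1

    if linear_only:

        def rhs(r, y):
            return (y[1], -dm1 / r * y[1] + y[0] * inv_l2)

    else:

        def rhs(r, y):
            psi = y[0]
            return (y[1], -dm1 / r * y[1] + psi * psi / LAMBDA0**2 + psi * inv_l2)

    return rhs


def _outer_psi_slope(psi_R, lambda_eff, params):
    if params.boundary == FREE:
        curv = (params.dimension - 1) / (2.0 * params.system_size)
        return -psi_R * (1.0 / lambda_eff + curv)
    return -psi_R / lambda_eff


def _integrate_inward(
    lambda_eff, params, psi_R, settings, *, t_eval=None, linear_only=False
):
    """Integrate from R down to a; returns the solve_ivp result."""
    a, R = params.source_size, params.system_size
    rhs = _excess_rhs_factory(params.dimension, lambda_eff, linear_only)
    y0 = [psi_R, _outer_psi_slope(psi_R, lambda_eff, params)]

    def blowup(r, y):
        return _BLOWUP_CAP - y[0]

    blowup.terminal = True
    blowup.direction = -1
    return solve_ivp(
        rhs,
        (R, a),
        y0,
        method="LSODA",
        rtol=settings.integrator_rel_tol,
        atol=max(psi_R, 1e-290) * 1e-10,
        t_eval=t_eval,
        events=blowup,
    )


def _flux_at_source(lambda_eff, params, psi_R, settings, linear_only):
    """Source flux -psi'(a) produced by the boundary value psi_R.

    Returns +inf when the inward integration blows up before reaching the
    source (boundary value too large).
    """
    sol = _integrate_inward(
        lambda_eff, params, psi_R, settings, linear_only=linear_only
    )
    if not sol.success or sol.t[-1] > params.source_size * (1 + 1e-9):
        return math.inf
    return -sol.y[1, -1]


def output_grid(params: ModelParams) -> np.ndarray:
    """Geometric output grid, ~400 points per decade from a to R."""
    a, R = params.source_size, params.system_size
    n = int(math.ceil(POINTS_PER_DECADE * math.log10(R / a))) + 1
    return np.geomspace(a, R, max(n, 8))


def shoot(
    lambda_eff: float,
    params: ModelParams,
    settings: Optional[SolverSettings] = None,
    *,
    linear_only: bool = False,
    psi_R_guess: Optional[float] = None,
) -> Profile:
    """Solve the boundary-value problem at fixed lambda by inward shooting.

    Root-finds the outer boundary value so the source flux matches
    ``params.source_flux`` to ``settings.flux_rel_tol``, then returns the
    profile on a geometric grid.  Raises :class:`NoSolutionError` when no
    boundary value in a generous log-range can produce the flux and
    :class:`SolverError` when the converged profile is not monotone.
    """
    settings = settings or SolverSettings()
    if lambda_eff <= 0:
        raise InvalidParameterError("lambda_eff must be positive")
    a, R = params.source_size, params.system_size
    j = params.source_flux
    decay = (R - a) / lambda_eff
    if decay > 600:
        raise NoSolutionError(
            f"system spans {decay:.0f} decay lengths; the outer boundary "
            "value underflows double precision"
        )

    # Linear closed form as the starting guess for the boundary value.
    half = (params.dimension - 1) / 2.0
    amp = j * a**half / (1.0 / lambda_eff + half / a)
    guess = psi_R_guess if psi_R_guess else amp * math.exp(-decay) / R**half
    guess = min(max(guess, 1e-280), _BLOWUP_CAP / 10)

    def g(z):
        flux = _flux_at_source(lambda_eff, params, math.exp(z), settings, linear_only)
        if math.isinf(flux):
            return 60.0
        if flux <= 0:
            return -60.0
        return math.log(flux / j)

    z = math.log(guess)
    gz = g(z)
    step = math.log(4.0)
    z_lo = z_hi = z
    g_lo = g_hi = gz
    for _ in range(120):
        if g_lo > 0:
            z_lo -= step
            g_lo = g(z_lo)
        elif g_hi < 0:
            z_hi += step
            g_hi = g(z_hi)
        else:
            break
        if z_hi - z_lo > 140 * step:
            break
    if not (g_lo <= 0 <= g_hi):
        raise NoSolutionError(
            f"no boundary value brackets the flux {j:g} "
            f"(achievable log-flux offsets in [{g_lo:.3g}, {g_hi:.3g}])"
        )
    z_star = brentq(g, z_lo, z_hi, xtol=1e-13, rtol=8.9e-16)
    psi_R = math.exp(z_star)

    grid = output_grid(params)
    sol = _integrate_inward(
        lambda_eff, params, psi_R, settings, t_eval=grid[::-1], linear_only=linear_only
    )
    if not sol.success or sol.t.size != grid.size:
        raise SolverError("final inward integration failed")
    psi = sol.y[0][::-1]
    flux = -sol.y[1, -1]
    if abs(flux - j) / j > settings.flux_rel_tol:
        raise SolverError(
            f"flux condition missed: got {flux:g}, wanted {j:g} "
            f"(rel err {abs(flux - j) / j:.3g})"
        )
    phi_b = bulk_value(lambda_eff, params.boundary)
    return Profile(
        grid=grid, values=psi + phi_b, lambda_used=lambda_eff, params=params
    )


def degradation_balance(profile: Profile) -> float:
    """Relative imbalance between injected flux and integrated degradation.

    At steady state ``j a^(d-1)`` equals the integral of the net degradation
    density ``phi^2/lambda0^2 + s phi/lambda^2`` over the domain (the
    outflux through the far boundary is exponentially small).  Returns the
    relative mismatch; converged profiles stay well under 0.5%.
    """
    p = profile.params
    lam = profile.lambda_used
    phi = profile.values
    r = profile.grid
    dens = phi**2 / LAMBDA0**2 + p.sign * phi / lam**2
    integral = np.trapezoid(dens * r ** (p.dimension - 1), r)
    injected = p.source_flux * p.source_size ** (p.dimension - 1)
    return float(abs(integral - injected) / injected)


def self_consistent_solve(
    params: ModelParams,
    settings: Optional[SolverSettings] = None,
    lambda_init: Optional[float] = None,
) -> SelfConsistentSolution:
    """Damped fixed point for the self-consistent decay length lambda(R).

    Iterates ``lambda_{n+1}^2 = (1-damping) lambda_n^2 +
    damping * lambda0^2 / (|V0| phibar(lambda_n))`` and stops when the
    consistency residual ``|lambda^-2 - |V0| phibar| / lambda^-2`` drops
    below ``lambda_rel_tol`` (which also bounds the successive lambda
    change).  After the first two damped steps a safeguarded secant update
    on the fixed-point defect accelerates the iteration — essential for
    clamped problems, where the bulk contribution makes the plain map's
    contraction factor approach 1.
    """
    settings = settings or SolverSettings()
    if params.coupling_case != STRONG:
        raise InvalidParameterError(
            "self_consistent_solve requires coupling_case='strong'"
        )
    v0 = params.interaction_mag
    lam = lambda_init if lambda_init else params.system_size / 20.0
    if lam <= 0:
        raise InvalidParameterError("lambda_init must be positive")
    gamma = settings.damping
    trace: List[Tuple[float, float]] = []
    psi_R_guess = None
    profile = None
    u_prev = defect_prev = None  # secant memory on u = lambda^2
    u_max = (0.5 * params.system_size) ** 2
    for it in range(1, settings.max_fixed_point_iters + 1):
        profile = shoot(lam, params, settings, psi_R_guess=psi_R_guess)
        phibar = volume_average(profile)
        trace.append((lam, phibar))
        u = lam**2
        target_sq = LAMBDA0**2 / (v0 * phibar)
        residual = abs(1.0 / lam**2 - v0 * phibar / LAMBDA0**2) * lam**2
        if residual < settings.lambda_rel_tol:
            return SelfConsistentSolution(
                profile=profile,
                lambda_star=lam,
                mean_phi=phibar,
                iterations=it,
                consistency_residual=residual,
                trace=trace,
            )
        defect = target_sq - u
        u_new = None
        if defect_prev is not None and defect != defect_prev:
            u_sec = u - defect * (u - u_prev) / (defect - defect_prev)
            if 0 < u_sec < u_max:
                u_new = u_sec
        if u_new is None:
            u_new = (1 - gamma) * u + gamma * target_sq
        u_prev, defect_prev = u, defect
        lam_new = math.sqrt(u_new)
        # Warm-start the next shoot: rescale the outer boundary value for the
        # change in the exponential factor.
        phi_b = bulk_value(lam, params.boundary)
        psi_R_prev = max(profile.values[-1] - phi_b, 0.0)
        shiftexp = params.system_size * (1.0 / lam - 1.0 / lam_new)
        if psi_R_prev > 0 and abs(shiftexp) < 600:
            psi_R_guess = psi_R_prev * math.exp(shiftexp)
        else:
            psi_R_guess = None
        lam = lam_new
    lams = [t[0] for t in trace[-4:]]
    oscillating = len(lams) == 4 and (lams[0] - lams[1]) * (lams[1] - lams[2]) < 0
    hint = "; trace oscillates, retry with smaller damping" if oscillating else ""
    raise NonConvergenceError(
        f"self-consistency not reached in {settings.max_fixed_point_iters} "
        f"iterations (last lambda {lam:g}){hint}",
        trace=trace,
    )


def calibrate_V0(
    anchor_size: float,
    target_lambda: float,
    params: ModelParams,
    settings: Optional[SolverSettings] = None,
) -> float:
    """Interaction magnitude that anchors lambda(anchor_size) = target_lambda.

    Inverts the self-consistency convention: ``|V0| = lambda0^2 /
    (target_lambda^2 phibar)`` with ``phibar`` from the fixed-lambda solve at
    the anchor size.  By construction :func:`self_consistent_solve` at the
    anchor then returns ``target_lambda`` within tolerance.
    """
    settings = settings or SolverSettings()
    if target_lambda >= anchor_size:
        raise InvalidParameterError("target_lambda must be below anchor_size")
    anchored = params.replace(system_size=float(anchor_size))
    profile = shoot(target_lambda, anchored, settings)
    phibar = volume_average(profile)
    v0 = LAMBDA0**2 / (target_lambda**2 * phibar)
    if v0 <= 0:
        raise SolverError("calibration produced a non-positive |V0|")
    return float(v0)


def solve_bvp_collocation(
    lambda_eff: float,
    params: ModelParams,
    settings: Optional[SolverSettings] = None,
    *,
    linear_only: bool = False,
    n_mesh: int = 801,
    max_nodes: int = 200_000,
) -> Profile:
    """Independent global collocation solve of the same two-point BVP.

    Uses :func:`scipy.integrate.solve_bvp` on a geometric mesh with the
    matched-asymptotic pieces as the initial guess.  Serves as the oracle
    cross-checking :func:`shoot` in tests; it is never on the production
    path.
    """
    settings = settings or SolverSettings()
    a, R = params.source_size, params.system_size
    j = params.source_flux
    d = params.dimension
    rhs = _excess_rhs_factory(d, lambda_eff, linear_only)
    x = np.geomspace(a, R, n_mesh)

    # Initial guess: min of the inner 1/(r r0), intermediate C_d/r^2 and
    # outer exponential pieces (all upper envelopes of the true solution).
    r0 = 1.0 / j
    half = (d - 1) / 2.0
    c_d = 8.0 - 2.0 * d
    with np.errstate(over="ignore", under="ignore"):
        inner = a**2 / (x * r0)
        inter = c_d * a**2 / x**2
        outer = (
            c_d
            * a**2
            / lambda_eff ** (2 - half)
            * np.exp(-(x - lambda_eff) / lambda_eff)
            / x**half
        )
        guess = np.minimum(np.minimum(inner, inter), outer)
    if linear_only:
        amp = j * a**half / (1.0 / lambda_eff + half / a)
        guess = amp * np.exp(-(x - a) / lambda_eff) / x**half
    guess = np.maximum(guess, 1e-280)
    dguess = np.gradient(guess, x)

    def fun(xv, yv):
        psi, dpsi = yv
        quad = 0.0 if linear_only else psi * psi / LAMBDA0**2
        return np.vstack(
            [dpsi, -(d - 1) / xv * dpsi + quad + psi / lambda_eff**2]
        )

    def bc(ya, yb):
        return np.array(
            [ya[1] + j, yb[1] - _outer_psi_slope(yb[0], lambda_eff, params)]
        )

    sol = solve_bvp(
        fun,
        bc,
        x,
        np.vstack([guess, dguess]),
        tol=max(settings.integrator_rel_tol, 1e-10),
        max_nodes=max_nodes,
    )
    if not sol.success:
        raise OracleFailureError(f"collocation failed: {sol.message}")
    grid = output_grid(params)
    psi = sol.sol(grid)[0]
    phi_b = bulk_value(lambda_eff, params.boundary)
    return Profile(
        grid=grid, values=psi + phi_b, lambda_used=lambda_eff, params=params
    )
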