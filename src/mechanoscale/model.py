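"""Dimensionless mechanochemical model core.

A diffusing signalling molecule ("mechanogen") is released at a small
spherical source of radius ``a`` and induces cytoskeletal contractility in
the surrounding cell assembly in proportion to its local concentration.
Contractile cells behave as elastic force dipoles whose interaction in a
finite medium is long-ranged and scales as the inverse system volume,
``V(x, x') = V0 / L^d``.  When mechanogen degradation is promoted by the
local strain, eliminating the strain yields a closed steady-state equation
for the dimensionless concentration ``phi(r)``::

    phi'' + (d-1)/r * phi' = phi^2 / lambda0^2  +  s * phi / lambda^2

with ``s = +1`` for free (zero-stress) and ``s = -1`` for clamped
(zero-displacement) boundaries, and an effective decay length ``lambda``
fixed self-consistently by the volume-averaged concentration.

All lengths in this module are expressed in units of the molecular length
``lambda0 = sqrt(D / degradation rate)``, and the source size is taken equal
to it (``a = lambda0 = 1``) unless stated otherwise.  The quadratic
degradation scale is always ``lambda0``; ``source_size`` only locates the
inner boundary where the flux condition ``-dphi/dr|_a = j`` is imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (
    InsufficientResolutionError,
    InvalidParameterError,
    OutOfDomainError,
    SingularPointError,
)

logger = logging.getLogger("mechanoscale")

#: Molecular decay length in solver units (the nondimensionalization choice).
LAMBDA0 = 1.0

FREE = "free"
CLAMPED = "clamped"
WEAK = "weak"
STRONG = "strong"

_BOUNDARIES = (FREE, CLAMPED)
_CASES = (WEAK, STRONG)


# ---------------------------------------------------------------------------
# Dimensional bookkeeping


@dataclass(frozen=True)
class DimensionalScales:
    """Physical scales used only to convert solver output to real units.

    Parameters
    ----------
    diffusion_const : float
        Mechanogen diffusion constant ``D`` (length^2 / time).
    susceptibility_chi : float
        Contractility susceptibility ``chi`` (volume); makes
        ``phi = chi * c`` dimensionless.
    modulus_Lambda : float
        Effective elastic modulus of the cell/matrix composite (stress).
    max_dipole_density : float
        Dipole density ``p_max`` of a fully contractile cell.
    degradation_rate : float
        Biochemical degradation rate (1 / time).
    """

    diffusion_const: float
    susceptibility_chi: float
    modulus_Lambda: float
    max_dipole_density: float
    degradation_rate: float

    def __post_init__(self):
        for name in (
            "diffusion_const",
            "susceptibility_chi",
            "modulus_Lambda",
            "max_dipole_density",
            "degradation_rate",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"DimensionalScales.{name} must be a positive finite "
                    f"number, got {value!r}"
                )


def molecular_length(scales: DimensionalScales) -> float:
    """Size-independent decay length ``lambda0 = sqrt(D / k_deg)``.

    This is the decay scale set purely by local biochemistry; the solver
    works in units where it equals 1.
    """
    return float(np.sqrt(scales.diffusion_const / scales.degradation_rate))


def diffusion_timescale(lambda_eff: float, scales: DimensionalScales) -> float:
    """Time ``lambda^2 / D`` to diffuse across the concentration gradient.

    When the decay length scales with system size this estimate grows as
    ``L^2 / D`` — minutes for typical tissue scales.
    """
    if lambda_eff <= 0:
        raise InvalidParameterError("lambda_eff must be positive")
    return float(lambda_eff**2 / scales.diffusion_const)


# ---------------------------------------------------------------------------
# Problem definition


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless steady-state problem definition.

    Lengths are in units of ``lambda0``.  ``source_flux`` is the flux ``j``
    per unit area imposed at ``r = source_size``; for the strongly nonlinear
    (large-flux) regime it is conveniently expressed through the crossover
    scale ``r0`` as ``j = 1/r0`` (see :meth:`with_source_scale`).
    """

    dimension: int
    boundary: str
    system_size: float
    source_flux: float
    interaction_mag: float = 0.0
    source_size: float = 1.0
    coupling_case: str = STRONG

    def __post_init__(self):
        if self.dimension not in (1, 2, 3):
            raise InvalidParameterError(
                f"dimension must be 1, 2 or 3, got {self.dimension!r}"
            )
        if self.boundary not in _BOUNDARIES:
            raise InvalidParameterError(
                f"boundary must be one of {_BOUNDARIES}, got {self.boundary!r}"
            )
        if self.coupling_case not in _CASES:
            raise InvalidParameterError(
                f"coupling_case must be one of {_CASES}, got {self.coupling_case!r}"
            )
        if self.source_size <= 0:
            raise InvalidParameterError("source_size must be positive")
        if self.system_size <= 10 * self.source_size:
            raise InvalidParameterError(
                "system_size must exceed 10 x source_size "
                f"({self.system_size} <= {10 * self.source_size})"
            )
        if self.source_flux <= 0:
            raise InvalidParameterError("source_flux must be positive")
        if self.dimension == 1 and self.boundary == FREE:
            # A free 1D chain of dipoles has no boundary-mediated interaction:
            # only the weak-coupling (case i) profile exists there.
            raise InvalidParameterError(
                "1D with free boundaries has no dipole-dipole interaction; "
                "use boundary='clamped' (or the weak-coupling profile)"
            )
        if self.coupling_case == STRONG and self.interaction_mag <= 0:
            raise InvalidParameterError(
                "interaction_mag must be positive for strong coupling"
            )
        if self.interaction_mag < 0:
            raise InvalidParameterError("interaction_mag must be non-negative")

    @property
    def sign(self) -> int:
        """Sign of the boundary-mediated interaction: +1 free, -1 clamped."""
        return 1 if self.boundary == FREE else -1

    @property
    def source_scale_r0(self) -> float:
        """Flux crossover length ``r0 = 1/j`` (inner/intermediate boundary)."""
        return 1.0 / self.source_flux

    @classmethod
    def with_source_scale(cls, r0: float, **kwargs) -> "ModelParams":
        """Build params with the flux set through ``r0``: ``j = 1/r0``."""
        if r0 <= 0:
            raise InvalidParameterError("r0 must be positive")
        return cls(source_flux=1.0 / r0, **kwargs)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


def _as_grid_values(grid, values):
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.ndim != 1 or values.shape != grid.shape:
        raise InvalidParameterError("grid and values must be 1-D and congruent")
    if grid.size < 2:
        raise InvalidParameterError("profile needs at least two grid points")
    if np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("grid coordinates must strictly increase")
    return grid, values


@dataclass
class Profile:
    """Discretized steady-state concentration ``phi(r)`` on a radial grid.

    The grid runs from the source radius to the system boundary; values are
    non-negative and monotonically non-increasing (small numerical slack is
    tolerated at the integrator-noise level).
    """

    grid: np.ndarray
    values: np.ndarray
    lambda_used: float
    params: ModelParams

    def __post_init__(self):
        self.grid, self.values = _as_grid_values(self.grid, self.values)
        if self.lambda_used <= 0:
            raise InvalidParameterError("lambda_used must be positive")
        a, R = self.params.source_size, self.params.system_size
        if not np.isclose(self.grid[0], a, rtol=1e-9, atol=0):
            raise InvalidParameterError(
                f"grid must start at the source radius {a}, got {self.grid[0]}"
            )
        if not np.isclose(self.grid[-1], R, rtol=1e-9, atol=0):
            raise InvalidParameterError(
                f"grid must end at the system size {R}, got {self.grid[-1]}"
            )
        scale = float(np.max(np.abs(self.values), initial=0.0))
        if np.any(self.values < -1e-12 * max(scale, 1.0)):
            raise InvalidParameterError("profile values must be non-negative")
        np.clip(self.values, 0.0, None, out=self.values)
        if np.any(np.diff(self.values) > 1e-9 * max(scale, 1e-300)):
            raise InvalidParameterError(
                "profile values must be monotonically non-increasing"
            )

    def __len__(self):
        return self.grid.size

    def interpolate(self, r):
        """Log-space linear interpolation of the profile (positive values)."""
        r = np.asarray(r, dtype=float)
        floor = 1e-300
        logv = np.log(np.maximum(self.values, floor))
        return np.exp(np.interp(r, self.grid, logv))


@dataclass
class StrainProfile:
    """Normalized strain trace ``u(r)`` with its uniform boundary term.

    ``u(r) = psi(r) + s |V0| psibar`` where ``psi = min(phi, 1)`` is the
    contractility, ``psibar`` its volume average, and ``s`` the boundary
    sign.  Compression is positive in this normalization.
    """

    grid: np.ndarray
    values: np.ndarray
    mean_contractility: float

    def __post_init__(self):
        self.grid, self.values = _as_grid_values(self.grid, self.values)


# ---------------------------------------------------------------------------
# Operations


def contractility_from_concentration(phi):
    """Contractility ``psi = min(phi, 1)``, the saturating dipole density.

    ``psi`` runs from 0 (non-contractile) to 1 (fully contractile).  The
    steady-state PDE assumes the linear regime ``phi <= 1``; saturation is
    reported through the package logger rather than raised, since the
    analysis remains meaningful near the source where ``phi`` may overshoot.
    """
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("concentration must be non-negative")
    if np.any(arr > 1):
        logger.warning(
            "concentration exceeds the saturation value (max phi = %.3g); "
            "the linear contractility-concentration relation is clipped",
            float(arr.max()),
        )
    clipped = np.minimum(arr, 1.0)
    return float(clipped) if np.isscalar(phi) else clipped


def _volume_average(grid, values, dimension, outer):
    integrand = values * grid ** (dimension - 1)
    return float(
        dimension * np.trapezoid(integrand, grid) / outer**dimension
    )


def volume_average(profile: Profile) -> float:
    """Volume average ``(d / R^d) * integral_a^R phi r^(d-1) dr``.

    The source region ``r < a`` is excluded; the resulting relative error is
    ``O((a/R)^d)``, negligible at the scale separation the model assumes.
    """
    if len(profile) < 4:
        raise InsufficientResolutionError(
            "volume_average needs at least 4 grid points"
        )
    p = profile.params
    return _volume_average(profile.grid, profile.values, p.dimension, p.system_size)


def strain_field(profile: Profile, interaction_mag: float, boundary: str) -> StrainProfile:
    """Strain trace induced by the contractility field plus its mean term.

    The local contribution is the clipped contractility ``psi(r)``; all other
    dipoles act through the separation-independent kernel ``V0 / L^d`` and
    contribute the spatially uniform term ``s |V0| psibar`` — positive
    (stretching) for free and negative for clamped boundaries.
    """
    if boundary not in _BOUNDARIES:
        raise InvalidParameterError(f"boundary must be one of {_BOUNDARIES}")
    if interaction_mag < 0:
        raise InvalidParameterError("interaction_mag must be non-negative")
    psi = np.minimum(profile.values, 1.0)
    p = profile.params
    psibar = _volume_average(profile.grid, psi, p.dimension, p.system_size)
    s = 1 if boundary == FREE else -1
    return StrainProfile(
        grid=profile.grid.copy(),
        values=psi + s * interaction_mag * psibar,
        mean_contractility=psibar,
    )


def bulk_value(lambda_eff: float, boundary: str) -> float:
    """Far-field concentration: 0 (free) or ``phi_b = lambda0^2/lambda^2``.

    With clamped boundaries the linear term is a *production*-like term and
    the profile decays to the finite value where quadratic degradation
    balances it.
    """
    if lambda_eff <= 0:
        raise InvalidParameterError("lambda_eff must be positive")
    if boundary not in _BOUNDARIES:
        raise InvalidParameterError(f"boundary must be one of {_BOUNDARIES}")
    if boundary == FREE:
        return 0.0
    return LAMBDA0**2 / lambda_eff**2


def ode_rhs(r, state, lambda_eff, params: ModelParams, *, linear_only=False):
    """First-order system for the steady-state equation.

    Returns ``(phi', phi'')`` with
    ``phi'' = -(d-1)/r phi' + phi^2/lambda0^2 + s phi/lambda^2``
    (``s = +1`` free, ``-1`` clamped).  ``linear_only`` drops the quadratic
    term (test hook for the closed-form linear regime).
    """
    if r <= 0:
        raise SingularPointError(
            "the radial ODE is singular at r = 0; the grid starts at the "
            "source radius"
        )
    if lambda_eff <= 0:
        raise InvalidParameterError("lambda_eff must be positive")
    phi, dphi = state
    quad = 0.0 if linear_only else phi * phi / LAMBDA0**2
    d2phi = (
        -(params.dimension - 1) / r * dphi
        + quad
        + params.sign * phi / lambda_eff**2
    )
    return dphi, d2phi


def weak_coupling_profile(r, params: ModelParams):
    """Case-(i) profile: purely biochemical degradation, decay length lambda0.

    ``phi(r) = A exp(-(r-a)/lambda0) / r^((d-1)/2)`` with the amplitude fixed
    by the source-flux condition ``-dphi/dr|_a = j``.  The decay length is
    independent of system size — only the strain offset carries any size
    dependence in this regime.
    """
    if params.coupling_case != WEAK:
        raise InvalidParameterError(
            "weak_coupling_profile requires coupling_case='weak'"
        )
    a = params.source_size
    d = params.dimension
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < a):
        raise OutOfDomainError(f"r must be >= source radius {a}")
    half = (d - 1) / 2.0
    amplitude = params.source_flux * a**half / (1.0 / LAMBDA0 + half / a)
    vals = amplitude * np.exp(-(r_arr - a) / LAMBDA0) / r_arr**half
    return float(vals) if np.isscalar(r) else vals


def linear_free_profile_3d(r, j, lambda_eff, source_size=1.0):
    """Small-flux closed form ``phi = j a^2 exp(-(r-a)/lambda) / r`` (3D free).

    Exact solution of the linearized equation (the 3D screened-Laplace
    Green-function form); it meets the flux condition at ``r = a`` to leading
    order in ``a/lambda``.
    """
    if j < 0 or lambda_eff <= 0 or source_size <= 0:
        raise InvalidParameterError("j must be >= 0 and lengths positive")
    a = source_size
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < a):
        raise OutOfDomainError(f"r must be >= source radius {a}")
    vals = j * a**2 * np.exp(-(r_arr - a) / lambda_eff) / r_arr
    return float(vals) if np.isscalar(r) else vals
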