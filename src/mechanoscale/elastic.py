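"""Elastic dipole interactions in finite media.

Two concrete realizations of the long-range, boundary-mediated interaction
between contractile force dipoles:

* a discrete 1D chain of identical springs carrying point-force dipoles,
  solved by direct linear statics — the pair interaction comes out
  independent of dipole separation, proportional to ``1/N`` and attractive
  only when the chain ends are clamped;
* a spherically symmetric continuum, where the strain trace splits into the
  local dipole term plus a spatially uniform boundary term proportional to
  the volume-averaged dipole density, with opposite signs for clamped and
  free outer surfaces.

Contractile dipoles are negative by convention; a local compression makes
the (un-normalized) strain trace negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InvalidConfigurationError, InvalidParameterError
from .model import CLAMPED, FREE, ModelParams

_BOUNDARIES = (FREE, CLAMPED)


@dataclass(frozen=True)
class SpringChain:
    """Chain of ``n_springs`` identical springs (nodes ``0..n_springs``).

    Clamped chains fix both end nodes; free chains fix only the rigid-body
    translation via a zero-mean-displacement gauge (energies are gauge
    invariant).
    """

    n_springs: int
    stiffness: float = 1.0
    boundary: str = CLAMPED

    def __post_init__(self):
        if self.n_springs < 4:
            raise InvalidParameterError("n_springs must be >= 4")
        if self.stiffness <= 0:
            raise InvalidParameterError("stiffness must be positive")
        if self.boundary not in _BOUNDARIES:
            raise InvalidParameterError(f"boundary must be one of {_BOUNDARIES}")


@dataclass(frozen=True)
class DipolePair:
    """Point-force dipole spanning the spring between nodes ``site, site+1``.

    ``magnitude`` is the dipole strength (force times spring length, with
    unit spring length); negative = contractile (the forces pull the two
    nodes toward each other).
    """

    site: int
    magnitude: float


def _check_dipole(chain: SpringChain, dipole: DipolePair):
    if not 1 <= dipole.site <= chain.n_springs - 1:
        raise InvalidConfigurationError(
            f"dipole site must lie in [1, {chain.n_springs - 1}], "
            f"got {dipole.site}"
        )


@dataclass
class ChainSolution:
    """Equilibrium of a loaded spring chain.

    ``elastic_energy`` is the stored energy ``1/2 sum k (extension)^2``;
    ``applied_work`` (= ``F . u``) is kept as separate bookkeeping.
    """

    displacements: np.ndarray
    elastic_energy: float
    applied_work: float


def _force_vector(chain: SpringChain, dipoles: Iterable[DipolePair]) -> np.ndarray:
    n = chain.n_springs
    forces = np.zeros(n + 1)
    for dp in dipoles:
        _check_dipole(chain, dp)
        # Contractile (magnitude < 0): left node pulled right, right node left.
        forces[dp.site] -= dp.magnitude
        forces[dp.site + 1] += dp.magnitude
    return forces


def _stiffness_matrix(chain: SpringChain) -> np.ndarray:
    n = chain.n_springs
    k = chain.stiffness
    K = np.zeros((n + 1, n + 1))
    for i in range(n):
        K[i, i] += k
        K[i + 1, i + 1] += k
        K[i, i + 1] -= k
        K[i + 1, i] -= k
    return K


def solve_chain(chain: SpringChain, dipoles: Sequence[DipolePair]) -> ChainSolution:
    """Linear statics of the chain under the dipole forces.

    Clamped: both end nodes are fixed and may absorb reaction forces.  Free:
    the applied forces must be self-balanced (dipoles always are) and the
    rigid-body mode is removed with a zero-mean constraint.
    """
    n = chain.n_springs
    forces = _force_vector(chain, dipoles)
    K = _stiffness_matrix(chain)
    u = np.zeros(n + 1)
    if chain.boundary == CLAMPED:
        interior = slice(1, n)
        u[interior] = np.linalg.solve(K[interior, interior], forces[interior])
    else:
        if abs(forces.sum()) > 1e-9 * max(np.abs(forces).max(), 1.0):
            raise InvalidConfigurationError(
                "free chain requires self-balanced forces (net force "
                f"{forces.sum():g}); the rigid-body mode is otherwise "
                "unconstrained"
            )
        aug = np.zeros((n + 2, n + 2))
        aug[: n + 1, : n + 1] = K
        aug[-1, : n + 1] = 1.0
        aug[: n + 1, -1] = 1.0
        rhs = np.concatenate([forces, [0.0]])
        u = np.linalg.solve(aug, rhs)[: n + 1]
    ext = np.diff(u)
    elastic = 0.5 * chain.stiffness * float(ext @ ext)
    work = float(forces @ u)
    return ChainSolution(displacements=u, elastic_energy=elastic, applied_work=work)


def pair_interaction_1d(
    n_springs: int,
    site_i: int,
    site_j: int,
    boundary: str = CLAMPED,
    stiffness: float = 1.0,
    magnitude: float = -1.0,
) -> float:
    """Interaction energy of two dipoles: ``E(i+j) - E(i) - E(j)``.

    For a clamped chain this is negative (attractive), independent of the
    separation ``|site_i - site_j|`` and proportional to ``1/n_springs`` —
    the discrete realization of the ``V0/L`` kernel.  For a free chain it
    vanishes identically: springs outside a dipole's span carry no force.
    """
    if site_i == site_j:
        raise InvalidConfigurationError("dipole sites must be distinct")
    if abs(site_i - site_j) < 2:
        raise InvalidConfigurationError(
            "dipoles must not overlap (sites must differ by at least 2)"
        )
    chain = SpringChain(n_springs=n_springs, stiffness=stiffness, boundary=boundary)
    d_i = DipolePair(site=site_i, magnitude=magnitude)
    d_j = DipolePair(site=site_j, magnitude=magnitude)
    e_both = solve_chain(chain, [d_i, d_j]).elastic_energy
    e_i = solve_chain(chain, [d_i]).elastic_energy
    e_j = solve_chain(chain, [d_j]).elastic_energy
    return e_both - e_i - e_j


def continuum_kernel(params: ModelParams) -> float:
    """Continuum interaction kernel ``s |V0| / size^d``.

    ``s = +1`` for free and ``-1`` for clamped boundaries in 2D/3D; in 1D
    only the clamped case interacts (the free value is 0, which
    :class:`~mechanoscale.model.ModelParams` forbids constructing for the
    strong-coupling solver — this helper accepts a weak-coupling 1D free
    parameter set and returns 0).
    """
    d = params.dimension
    v0 = params.interaction_mag
    size = params.system_size
    if d == 1:
        if params.boundary == FREE:
            return 0.0
        return -v0 / size
    return params.sign * v0 / size**d


@dataclass(frozen=True)
class SphericalDipoleField:
    """Spherically symmetric dipole density ``p(r)`` on ``[0, R]``.

    ``lame_lambda`` and ``shear_mu`` are the Lame constants of the medium;
    the reported strain is per unit ``p_max`` (the density should be supplied
    normalized).
    """

    dipole_density: Callable[[np.ndarray], np.ndarray]
    outer_radius: float
    boundary: str = CLAMPED
    lame_lambda: float = 1.0
    shear_mu: float = 1.0

    def __post_init__(self):
        if self.outer_radius <= 0:
            raise InvalidParameterError("outer_radius must be positive")
        if self.boundary not in _BOUNDARIES:
            raise InvalidParameterError(f"boundary must be one of {_BOUNDARIES}")
        if self.lame_lambda <= 0 or self.shear_mu <= 0:
            raise InvalidParameterError("Lame constants must be positive")


@dataclass
class StrainTraceResult:
    """Strain trace on a radial grid plus its uniform boundary-induced part."""

    grid: np.ndarray
    values: np.ndarray
    boundary_term: float


def spherical_strain_trace(
    field: SphericalDipoleField, n_grid: int = 2001
) -> StrainTraceResult:
    """Strain trace ``Tr(u) = du/dr + 2u/r`` of the dipole distribution.

    The radial equilibrium equation integrates to
    ``Tr(u) = p(r)/M + 3 c1`` with ``M = lambda + 2 mu`` and the homogeneous
    coefficient ``c1`` (regular solution ``u = c1 r``) fixed by the outer
    boundary condition: ``u(R) = 0`` (clamped) or zero total radial stress
    including the dipole eigenstress (free).  The boundary-induced part is
    spatially uniform, proportional to the volume-averaged dipole density
    and of opposite sign for the two boundary conditions.
    """
    R = field.outer_radius
    M = field.lame_lambda + 2.0 * field.shear_mu
    r = np.linspace(0.0, R, n_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.asarray(field.dipole_density(r), dtype=float)
    if p.shape != r.shape or not np.all(np.isfinite(p)):
        raise InvalidParameterError(
            "dipole_density must return finite values on the grid"
        )
    # Volume-averaged density (3/R^3) * int p r^2 dr
    pbar = 3.0 * np.trapezoid(p * r**2, r) / R**3
    if field.boundary == CLAMPED:
        boundary_term = -pbar / M
    else:
        mu = field.shear_mu
        boundary_term = (4.0 * mu / (3.0 * field.lame_lambda + 2.0 * mu)) * (pbar / M)
    values = p / M + boundary_term
    return StrainTraceResult(grid=r, values=values, boundary_term=float(boundary_term))
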