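"""Voxel-grid solute solvers.

Nutrients (glucose, oxygen, the independent substrates) are solved to a
pseudo-steady state each global step: growth is slow compared with
diffusion, so the field relaxes to D*lap(S) + r(S) = 0 with the bulk
concentration imposed above the boundary layer, zero flux at the
substratum, and periodic lateral boundaries.  Monod sinks are handled by
Picard iteration with a secant linearisation r(S) ~ (r(S_prev)/S_prev)*S,
which keeps the discrete operator an M-matrix and the solution within
[0, bulk].

Secreted products (inhibitor, surfactant) accumulate instead of being
washed out: they take an implicit-Euler transient step with zero-flux top
and bottom boundaries, which conserves mass exactly up to linear-solver
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .domain import DomainGrid, SoluteField

__all__ = ["SolverSettings", "ConvergenceError", "solve_steady",
           "step_transient"]

ReactionMap = Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]


class ConvergenceError(RuntimeError):
    """Steady-state iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class SolverSettings:
    """Numerical controls for the field solvers.

    ``tolerance`` is the maximum relative change of any voxel between
    successive Picard iterates (relative to the bulk concentration).
    ``transient_substep`` optionally subdivides the transient step; the
    implicit scheme is unconditionally stable so the default is a single
    step.
    """

    tolerance: float = 1e-6
    max_iterations: int = 10_000
    scheme: str = "splu"
    transient_substep: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _second_diff_periodic(n: int) -> sparse.csr_matrix:
    """Positive-semidefinite 1D -d2/dx2 stencil with periodic wrap (h=1)."""
    if n == 1:
        return sparse.csr_matrix((1, 1))
    main = 2.0 * np.ones(n)
    off = -np.ones(n - 1)
    A = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
    A[0, n - 1] += -1.0
    A[n - 1, 0] += -1.0
    return A.tocsr()


def _second_diff_z(n: int, dirichlet_top: bool) -> sparse.csr_matrix:
    """1D -d2/dz2 with zero-flux bottom; top either zero-flux or a Dirichlet
    ghost cell (whose RHS contribution is added by the caller)."""
    if n == 1:
        return sparse.csr_matrix(([1.0] if dirichlet_top else [0.0],
                                  ([0], [0])), shape=(1, 1))
    main = 2.0 * np.ones(n)
    main[0] = 1.0
    if not dirichlet_top:
        main[-1] = 1.0
    off = -np.ones(n - 1)
    return sparse.diags([off, main, off], [-1, 0, 1], format="csr")


_LAPLACIAN_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _neg_laplacian(nx: int, ny: int, nz: int,
                   dirichlet_top: bool) -> sparse.csr_matrix:
    """3D -lap operator (unit spacing) on C-ordered (nx, ny, nz) voxels."""
    key = (nx, ny, nz, dirichlet_top)
    K = _LAPLACIAN_CACHE.get(key)
    if K is None:
        Ax = _second_diff_periodic(nx)
        Ay = _second_diff_periodic(ny)
        Az = _second_diff_z(nz, dirichlet_top)
        Ix, Iy, Iz = (sparse.identity(n, format="csr") for n in (nx, ny, nz))
        K = (sparse.kron(Ax, sparse.kron(Iy, Iz))
             + sparse.kron(Ix, sparse.kron(Ay, Iz))
             + sparse.kron(Ix, sparse.kron(Iy, Az))).tocsr()
        if len(_LAPLACIAN_CACHE) > 64:
            _LAPLACIAN_CACHE.clear()
        _LAPLACIAN_CACHE[key] = K
    return K


def _spd_solve(A: sparse.csr_matrix, b: np.ndarray,
               x0: Optional[np.ndarray]) -> np.ndarray:
    """Solve the SPD Picard system: Jacobi-preconditioned CG with warm
    start, falling back to a direct solve if CG stalls."""
    diag = A.diagonal()
    M = sparse.diags(1.0 / diag)
    atol = 1e-12 * max(float(np.linalg.norm(b)), 1e-30)
    x, info = sparse.linalg.cg(A, b, x0=x0, M=M, rtol=1e-12, atol=atol,
                               maxiter=1000)
    if info != 0:
        x = sparse.linalg.spsolve(A.tocsc(), b)
    return x


def solve_steady(field: SoluteField, reaction_rate_map: ReactionMap,
                 grid: DomainGrid, settings: Optional[SolverSettings] = None,
                 clamp_from_layer: Optional[int] = None) -> SoluteField:
    """Relax a bulk-maintained field to diffusion-reaction steady state.

    Parameters
    ----------
    reaction_rate_map
        Either a constant per-voxel rate array (g/L/h, sinks negative) or a
        callable mapping the full concentration array to such rates; the
        callable form is re-evaluated every Picard sweep so saturating
        (Monod) sinks shut off as the concentration approaches zero.
    clamp_from_layer
        Voxel layer index from which the field is held at the bulk
        concentration (the well-mixed region above the boundary layer).
        Defaults to the top layer only.

    The field is updated in place and returned.  Raises
    :class:`ConvergenceError` (carrying the final residual) if the Picard
    iteration does not reach tolerance.
    """
    if not field.bulk_maintained:
        raise ValueError("solve_steady requires a bulk-maintained field")
    settings = settings or SolverSettings()
    nx, ny, nz = grid.shape
    kc = nz - 1 if clamp_from_layer is None else int(clamp_from_layer)
    kc = max(1, min(kc, nz - 1))
    D = field.diffusivity
    h2 = grid.voxel_size ** 2
    bulk = field.bulk_concentration

    conc = field.concentration
    conc[:, :, kc:] = bulk

    nzA = kc
    K = _neg_laplacian(nx, ny, nzA, dirichlet_top=True) * (D / h2)
    nA = nx * ny * nzA
    rhs_dirichlet = np.zeros(nA)
    top = np.arange(nA).reshape(nx, ny, nzA)[:, :, -1].ravel()
    rhs_dirichlet[top] = (D / h2) * bulk

    if callable(reaction_rate_map):
        rate_fn = reaction_rate_map
    else:
        const_rates = np.asarray(reaction_rate_map, dtype=float)
        # one direct solve; fall back to Picard only if it undershoots zero
        b = rhs_dirichlet + const_rates[:, :, :nzA].reshape(nA)
        S = _spd_solve(K.tocsr(), b, conc[:, :, :nzA].reshape(nA))
        if S.min() >= -1e-12 * max(bulk, 1.0):
            conc[:, :, :nzA] = np.maximum(S, 0.0).reshape(nx, ny, nzA)
            return field

        def rate_fn(c: np.ndarray) -> np.ndarray:  # saturating fallback
            return np.where(c > 0, const_rates, 0.0)

    S_prev = conc[:, :, :nzA].copy()
    scale = max(bulk, 1e-300)
    residual = np.inf
    for _ in range(settings.max_iterations):
        full = conc.copy()
        full[:, :, :nzA] = S_prev
        rates = np.asarray(rate_fn(full), dtype=float)[:, :, :nzA]
        sinks = np.minimum(rates, 0.0)
        sources = np.maximum(rates, 0.0)
        kcoef = -sinks.reshape(nA) / np.maximum(S_prev.reshape(nA), 1e-300)
        A = (K + sparse.diags(kcoef)).tocsr()
        b = rhs_dirichlet + sources.reshape(nA)
        S = _spd_solve(A, b, S_prev.reshape(nA)).reshape(nx, ny, nzA)
        S = np.maximum(S, 0.0)
        residual = float(np.max(np.abs(S - S_prev)) / scale)
        S_prev = S
        if residual <= settings.tolerance:
            conc[:, :, :nzA] = S
            return field
    raise ConvergenceError(
        f"steady solve for '{field.name}' did not converge "
        f"(residual {residual:.3e} > {settings.tolerance:.3e})", residual)


_TRANSIENT_CACHE: dict[tuple, object] = {}


def _transient_factor(grid: DomainGrid, D: float, dt: float):
    key = (grid.shape, grid.voxel_size, D, dt)
    lu = _TRANSIENT_CACHE.get(key)
    if lu is None:
        nx, ny, nz = grid.shape
        K = _neg_laplacian(nx, ny, nz, dirichlet_top=False)
        n = nx * ny * nz
        A = sparse.identity(n, format="csc") + (dt * D / grid.voxel_size ** 2) * K
        lu = splu(A.tocsc())
        if len(_TRANSIENT_CACHE) > 32:
            _TRANSIENT_CACHE.clear()
        _TRANSIENT_CACHE[key] = lu
    return lu


def step_transient(field: SoluteField, source_rate_map: np.ndarray, dt: float,
                   grid: DomainGrid,
                   settings: Optional[SolverSettings] = None) -> SoluteField:
    """Advance an accumulating field by ``dt`` hours (implicit Euler).

    Zero-flux at top and bottom and periodic laterally, so total solute
    mass increases by exactly sum(source * voxel_volume * dt) up to linear
    solver round-off.  Sources are g/L/h per voxel and must be
    non-negative.  Unconditionally stable; ``settings.transient_substep``
    may subdivide the step for temporal accuracy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if field.bulk_maintained:
        raise ValueError("step_transient is for accumulating fields")
    settings = settings or SolverSettings()
    src = np.asarray(source_rate_map, dtype=float)
    if np.any(src < 0):
        raise ValueError("transient sources must be non-negative")
    sub = settings.transient_substep
    n_sub = 1 if sub is None else max(1, int(np.ceil(dt / sub)))
    dt_sub = dt / n_sub
    nx, ny, nz = grid.shape
    lu = _transient_factor(grid, field.diffusivity, dt_sub)
    c = field.concentration.reshape(nx * ny * nz)
    s = src.reshape(nx * ny * nz)
    for _ in range(n_sub):
        c = lu.solve(c + dt_sub * s)
    field.concentration = c.reshape(nx, ny, nz)
    return field
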