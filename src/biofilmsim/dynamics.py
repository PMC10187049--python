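"""Per-step agent rules: division, shoving, surfactant-triggered
detachment, and planktonic random movement.

Division and shoving conserve total mass exactly.  Detachment is one-way:
a cell that leaves the biofilm becomes planktonic, drifts in the boundary
layer below the bulk medium, and never rejoins the biofilm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .domain import (Agent, CellState, DomainGrid, Population,
                     SimulationState, local_concentration, periphery_agents)

__all__ = ["DivisionSettings", "ShoveSettings", "divide_if_ready",
           "shove_relax", "surfactant_detach", "planktonic_move",
           "erosion_detach"]


@dataclass
class DivisionSettings:
    """Cell-division rule: divide when the sphere radius reaches
    ``division_radius``; the mass split ratio is uniform in
    [split_low, split_high]; daughters separate by half the sum of their
    radii along a random direction (shoving resolves residual overlap)."""

    division_radius: float = 1.0  # um
    split_low: float = 0.45
    split_high: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.split_low <= self.split_high < 1:
            raise ValueError("split ratios must satisfy 0 < low <= high < 1")
        if self.division_radius <= 0:
            raise ValueError("division_radius must be positive")


@dataclass
class ShoveSettings:
    """Overlap-relaxation controls."""

    overlap_tolerance: float = 0.05  # um
    shove_multiplier: float = 1.0
    max_sweeps: int = 50

    def __post_init__(self) -> None:
        if self.overlap_tolerance < 0:
            raise ValueError("overlap_tolerance must be non-negative")


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def divide_if_ready(agent: Agent, settings: DivisionSettings,
                    rng: np.random.Generator,
                    new_id: Optional[int] = None) -> list[Agent]:
    """Divide ``agent`` if its radius has reached the division radius.

    Returns ``[agent]`` unchanged when below threshold, else two daughters
    of the same species and state whose biomass and capsule masses sum
    exactly to the parent's.  The first daughter keeps the parent id; the
    second receives ``new_id``.
    """
    if agent.radius_um < settings.division_radius:
        return [agent]
    frac = rng.uniform(settings.split_low, settings.split_high)
    direction = _random_unit_vector(rng)
    b1, b2 = agent.biomass_fg * frac, agent.biomass_fg * (1.0 - frac)
    c1, c2 = agent.capsule_fg * frac, agent.capsule_fg * (1.0 - frac)
    d1 = Agent(id=agent.id, species=agent.species, state=agent.state,
               position=agent.position.copy(), biomass_fg=b1, capsule_fg=c1)
    d2 = Agent(id=agent.id + 1 if new_id is None else new_id,
               species=agent.species, state=agent.state,
               position=agent.position.copy(), biomass_fg=b2, capsule_fg=c2)
    # exact conservation: second daughter takes the remainder
    d2.biomass_fg = agent.biomass_fg - d1.biomass_fg
    d2.capsule_fg = agent.capsule_fg - d1.capsule_fg
    offset = direction * (d1.radius_um + d2.radius_um) / 4.0
    d1.position = d1.position + offset
    d2.position = d2.position - offset
    if agent.state is CellState.BIOFILM:
        for d in (d1, d2):
            d.position[2] = max(d.position[2], d.radius_um)
    return [d1, d2]


def shove_relax(agents: Population, grid: DomainGrid,
                settings: ShoveSettings) -> Population:
    """Resolve pairwise overlaps among BIOFILM agents.

    Damped-Jacobi relaxation: every overlapping pair contributes a
    displacement of half its overlap to each member along the centre line;
    all displacements are accumulated and applied simultaneously, which
    makes the result independent of pair ordering and hence deterministic.
    Sweeps repeat until the largest overlap is within tolerance or the
    sweep cap is reached (then a warning is issued).  Positions wrap
    periodically in x,y and biofilm cells are kept above the substratum
    (z >= radius).  Planktonic agents are not touched.
    """
    rows = np.flatnonzero(agents.state == int(CellState.BIOFILM))
    if len(rows) < 2:
        return agents
    pos = agents.pos[rows].copy()
    pos[:, 0] %= grid.side_x
    pos[:, 1] %= grid.side_y
    r = agents.radius[rows]
    rmax = float(r.max())
    box = np.array([grid.side_x, grid.side_y,
                    max(grid.side_z, pos[:, 2].max() + 4 * rmax + 1)])
    moved = False
    for sweep in range(settings.max_sweeps):
        tree = cKDTree(np.mod(pos, box), boxsize=box)
        pairs = tree.query_pairs(r=2.0 * rmax, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[i] - pos[j]
        # minimum-image convention laterally
        for ax, side in ((0, grid.side_x), (1, grid.side_y)):
            d[:, ax] -= side * np.round(d[:, ax] / side)
        dist = np.linalg.norm(d, axis=1)
        overlap = r[i] + r[j] - dist
        sel = overlap > settings.overlap_tolerance
        if not sel.any():
            break
        i, j, d, dist, overlap = i[sel], j[sel], d[sel], dist[sel], overlap[sel]
        # coincident centres: deterministic fallback direction
        zero = dist < 1e-12
        if zero.any():
            d[zero] = np.array([1.0, 0.0, 0.0])
            dist[zero] = 1.0
        unit = d / dist[:, None]
        push = 0.5 * settings.shove_multiplier * overlap[:, None] * unit
        disp = np.zeros_like(pos)
        np.add.at(disp, i, push)
        np.add.at(disp, j, -push)
        pos += disp
        pos[:, 0] %= grid.side_x
        pos[:, 1] %= grid.side_y
        np.maximum(pos[:, 2], r, out=pos[:, 2])
        moved = True
    else:
        warnings.warn("shove_relax reached max_sweeps with residual overlap",
                      RuntimeWarning, stacklevel=2)
    if moved:
        agents.pos[rows] = pos
    return agents


def surfactant_detach(state: SimulationState) -> SimulationState:
    """Detach periphery biofilm cells exposed to surfactant above their
    species tolerance.

    A periphery cell detaches when the surfactant concentration in its
    voxel strictly exceeds its species' ``surfactant_tolerance``; it then
    becomes PLANKTONIC and is relocated to a uniformly random position in
    the boundary-layer band just below the bulk medium.  Enclosed cells
    never detach; detachment is irreversible.
    """
    if not state.variant.surfactant_active:
        return state
    field = state.fields["surfactant"]
    agents = state.agents
    grid = state.grid
    peri = periphery_agents(state)
    if not peri:
        return state
    peri_rows = np.flatnonzero(np.isin(agents.ids, list(peri)))
    idx = grid.voxel_index(agents.pos[peri_rows])
    conc = field.concentration[idx[:, 0], idx[:, 1], idx[:, 2]]
    tol = np.array([agents.species_params(s).surfactant_tolerance or np.inf
                    for s in agents.species_idx[peri_rows]])
    detach_rows = peri_rows[conc > tol]
    if len(detach_rows) == 0:
        return state
    rng = state.rng
    n = len(detach_rows)
    lo = grid.side_z - grid.boundary_layer_thickness
    new_xy = rng.uniform([0.0, 0.0], [grid.side_x, grid.side_y], size=(n, 2))
    new_z = rng.uniform(lo, grid.side_z, size=n)
    agents.state[detach_rows] = int(CellState.PLANKTONIC)
    agents.pos[detach_rows, 0] = new_xy[:, 0]
    agents.pos[detach_rows, 1] = new_xy[:, 1]
    agents.pos[detach_rows, 2] = new_z
    return state


def planktonic_move(state: SimulationState, dt: float,
                    rng: Optional[np.random.Generator] = None,
                    step_length: float = 5.0) -> SimulationState:
    """Random isotropic step of every planktonic cell.

    Each planktonic agent moves ``step_length`` um in a uniformly random
    direction per call, wrapped periodically in x,y and reflected at the
    top and bottom of the boundary-layer band.  Biofilm agents are
    untouched; planktonic cells neither grow nor divide but remain in all
    counts.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = rng if rng is not None else state.rng
    agents = state.agents
    grid = state.grid
    rows = np.flatnonzero(agents.state == int(CellState.PLANKTONIC))
    if len(rows) == 0 or step_length == 0:
        return state
    v = rng.normal(size=(len(rows), 3))
    norms = np.linalg.norm(v, axis=1)
    norms[norms < 1e-12] = 1.0
    step = step_length * v / norms[:, None]
    pos = agents.pos[rows] + step
    pos[:, 0] %= grid.side_x
    pos[:, 1] %= grid.side_y
    lo = grid.side_z - grid.boundary_layer_thickness
    span = grid.boundary_layer_thickness
    t = np.mod(pos[:, 2] - lo, 2.0 * span)
    pos[:, 2] = lo + span - np.abs(t - span)
    agents.pos[rows] = pos
    return state


def erosion_detach(state: SimulationState, rate_per_h: float,
                   dt: float) -> SimulationState:
    """Optional generic shear-erosion rule (disabled by default).

    Periphery cells detach stochastically with probability
    ``rate_per_h * dt * (height / domain height)``, mimicking stronger
    shear at the biofilm front.  All detachment in the default models is
    surfactant-driven, so this is off unless explicitly enabled.
    """
    if rate_per_h <= 0:
        return state
    agents = state.agents
    grid = state.grid
    peri = periphery_agents(state)
    if not peri:
        return state
    rows = np.flatnonzero(np.isin(agents.ids, list(peri)))
    p = rate_per_h * dt * agents.pos[rows, 2] / grid.side_z
    drawn = state.rng.uniform(size=len(rows)) < np.clip(p, 0.0, 1.0)
    rows = rows[drawn]
    if len(rows):
        lo = grid.side_z - grid.boundary_layer_thickness
        agents.state[rows] = int(CellState.PLANKTONIC)
        agents.pos[rows, 0] = state.rng.uniform(0, grid.side_x, len(rows))
        agents.pos[rows, 1] = state.rng.uniform(0, grid.side_y, len(rows))
        agents.pos[rows, 2] = state.rng.uniform(lo, grid.side_z, len(rows))
    return state
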