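"""Core data model for the individual-based biofilm simulator.

The simulated system is a 3D rectangular domain with a solid substratum at
``z = 0``, periodic lateral boundaries, and well-mixed bulk medium above the
biofilm.  Bacterial cells are hard spheres ("agents") attached to the biofilm
or floating planktonically in the boundary layer below the bulk.  Dissolved
chemicals (glucose, oxygen, an inhibitor, a biosurfactant) live on a regular
voxel grid.

Unit conventions, chosen so that no conversion factors appear in the code:

=============  =========================================
length         micrometre (um)
time           hour (h)
cell mass      femtogram (fg)
concentration  g/L, which equals fg/um^3 exactly
density        g/L (so volume [um^3] = mass [fg] / rho)
=============  =========================================
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CellState",
    "ModelVariant",
    "SpeciesParams",
    "DomainGrid",
    "Agent",
    "Population",
    "SoluteField",
    "SimulationState",
    "radius_from_masses",
    "local_concentration",
    "periphery_agents",
    "occupancy_grid",
    "OutOfDomainError",
]


class OutOfDomainError(ValueError):
    """A position query fell outside the simulation domain (in z)."""


class CellState(enum.IntEnum):
    """Whether a cell is attached to the biofilm or free-floating."""

    BIOFILM = 0
    PLANKTONIC = 1


class ModelVariant(enum.Enum):
    """The five model configurations.

    COMPETITION           both species share glucose and oxygen.
    INDEPENDENT_SUBSTRATES control: each species has its own carbon source
                           (substrate1 / substrate2) with identical kinetic
                           constants; oxygen is still shared.
    INHIBITION            L. paracasei secretes a bacteriostatic inhibitor
                           acting noncompetitively on S. oralis.
    SURFACTANT            L. paracasei secretes a biosurfactant that detaches
                           periphery cells of both species; no EPS capsule.
    INHIBITION_SURFACTANT both mechanisms together; no EPS capsule.
    """

    COMPETITION = "competition"
    INDEPENDENT_SUBSTRATES = "independent_substrates"
    INHIBITION = "inhibition"
    SURFACTANT = "surfactant"
    INHIBITION_SURFACTANT = "inhibition_surfactant"

    @property
    def inhibition_active(self) -> bool:
        return self in (ModelVariant.INHIBITION, ModelVariant.INHIBITION_SURFACTANT)

    @property
    def surfactant_active(self) -> bool:
        return self in (ModelVariant.SURFACTANT, ModelVariant.INHIBITION_SURFACTANT)

    @property
    def eps_active(self) -> bool:
        # Surfactant-containing models omit EPS capsule production.
        return self not in (ModelVariant.SURFACTANT, ModelVariant.INHIBITION_SURFACTANT)

    @property
    def shared_carbon(self) -> bool:
        return self is not ModelVariant.INDEPENDENT_SUBSTRATES

    @property
    def required_fields(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.shared_carbon:
            names.append("glucose")
        else:
            names.extend(["substrate1", "substrate2"])
        names.append("oxygen")
        if self.inhibition_active:
            names.append("inhibitor")
        if self.surfactant_active:
            names.append("surfactant")
        return tuple(names)


@dataclass
class SpeciesParams:
    """Growth and production parameters for one species.

    Yields follow the bookkeeping convention that negative values are
    consumed per gram of new biomass and positive values are produced.
    ``biomass_fraction``/``capsule_fraction`` split newly synthesised mass
    between the cell proper and its EPS capsule.
    """

    name: str
    mu_max: float  # 1/h
    K_Sg: float  # g/L, carbon-source half-saturation
    K_So: float  # g/L, oxygen half-saturation
    yield_glucose: float  # g glucose per g new biomass (negative)
    yield_oxygen: float  # g oxygen per g new biomass (negative)
    biomass_fraction: float = 1.0
    capsule_fraction: float = 0.0
    K_I: Optional[float] = None  # g/L; set only for the inhibited species
    production_rate_k: Optional[float] = None  # 1/h, first-order production
    yield_inhibitor: Optional[float] = None  # g inhibitor / g producer biomass
    yield_surfactant: Optional[float] = None  # g surfactant / g producer biomass
    surfactant_tolerance: Optional[float] = None  # g/L detachment threshold
    cell_density_rho_b: float = 150.0  # g/L
    capsule_density_rho_c: float = 75.0  # g/L

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.K_Sg <= 0 or self.K_So <= 0:
            raise ValueError("half-saturation constants must be positive")
        if self.K_I is not None and self.K_I <= 0:
            raise ValueError("K_I must be positive when present")
        if not math.isclose(self.biomass_fraction + self.capsule_fraction, 1.0,
                            rel_tol=0, abs_tol=1e-12):
            raise ValueError("biomass_fraction + capsule_fraction must equal 1")
        if self.cell_density_rho_b <= 0 or self.capsule_density_rho_c <= 0:
            raise ValueError("densities must be positive")
        for attr in ("yield_inhibitor", "yield_surfactant", "surfactant_tolerance",
                     "production_rate_k"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{attr} must be non-negative when present")


def radius_from_masses(biomass_fg, capsule_fg, rho_b: float = 150.0,
                       rho_c: float = 75.0):
    """Sphere radius (um) of a cell with the given biomass and capsule mass.

    Because 1 g/L == 1 fg/um^3, volume is simply mass/density and
    ``r = (3 V / 4 pi)^(1/3)``.  Accepts scalars or arrays.
    """
    volume = np.asarray(biomass_fg) / rho_b + np.asarray(capsule_fg) / rho_c
    return np.cbrt(3.0 * volume / (4.0 * np.pi))


@dataclass(frozen=True)
class DomainGrid:
    """Rectangular voxelised domain.

    Substratum at z=0 (zero-flux), bulk-connected top face, periodic lateral
    faces.  ``boundary_layer_thickness`` is the stagnant-liquid thickness
    separating the biofilm front from the well-mixed bulk.
    """

    side_x: float = 136.0
    side_y: float = 136.0
    side_z: float = 136.0
    voxel_size: float = 8.0
    boundary_layer_thickness: float = 40.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for side in (self.side_x, self.side_y, self.side_z):
            n = side / self.voxel_size
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError("each side must be a positive integer multiple"
                                 " of voxel_size")
        if not 0 < self.boundary_layer_thickness < self.side_z:
            raise ValueError("boundary_layer_thickness must lie in (0, side_z)")

    @property
    def nx(self) -> int:
        return round(self.side_x / self.voxel_size)

    @property
    def ny(self) -> int:
        return round(self.side_y / self.voxel_size)

    @property
    def nz(self) -> int:
        return round(self.side_z / self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    @property
    def substratum_area(self) -> float:
        """Surface area of the colonisable substratum (um^2)."""
        return self.side_x * self.side_y

    def wrap_xy(self, position):
        """Apply the periodic lateral boundary to one point or an (n,3) array."""
        pos = np.array(position, dtype=float, copy=True)
        pos[..., 0] %= self.side_x
        pos[..., 1] %= self.side_y
        return pos

    def voxel_index(self, position):
        """0-based voxel indices of point(s); half-open voxels [i*h, (i+1)*h).

        x and y are wrapped periodically; a z outside [0, side_z] raises
        :class:`OutOfDomainError`.
        """
        pos = np.asarray(position, dtype=float)
        z = pos[..., 2]
        if np.any(z < 0) or np.any(z > self.side_z):
            raise OutOfDomainError("position outside domain in z")
        h = self.voxel_size
        ix = np.floor(pos[..., 0] / h).astype(int) % self.nx
        iy = np.floor(pos[..., 1] / h).astype(int) % self.ny
        iz = np.minimum(np.floor(z / h).astype(int), self.nz - 1)
        return np.stack([ix, iy, iz], axis=-1)

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.voxel_size


@dataclass
class Agent:
    """One spherical cell.

    ``radius_um`` is derived from the two mass pools and the species
    densities; it is stored for convenience but must always satisfy
    :func:`radius_from_masses`.
    """

    id: int
    species: SpeciesParams
    state: CellState
    position: np.ndarray  # (x, y, z) um
    biomass_fg: float
    capsule_fg: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.biomass_fg <= 0:
            raise ValueError("biomass must be positive")
        if self.capsule_fg < 0:
            raise ValueError("capsule mass cannot be negative")

    @property
    def radius_um(self) -> float:
        return float(radius_from_masses(self.biomass_fg, self.capsule_fg,
                                        self.species.cell_density_rho_b,
                                        self.species.capsule_density_rho_c))


class Population:
    """Structure-of-arrays container for all agents of a simulation.

    Rows are in insertion order; ids are unique and never reused.  This is
    the engine's working representation; :class:`Agent` records are produced
    on demand for per-cell operations.
    """

    def __init__(self, species_list: Sequence[SpeciesParams]):
        self.species_list = list(species_list)
        self._name_to_idx = {sp.name: i for i, sp in enumerate(self.species_list)}
        self.ids = np.empty(0, dtype=np.int64)
        self.species_idx = np.empty(0, dtype=np.int8)
        self.state = np.empty(0, dtype=np.int8)
        self.pos = np.empty((0, 3), dtype=float)
        self.biomass = np.empty(0, dtype=float)
        self.capsule = np.empty(0, dtype=float)
        self.radius = np.empty(0, dtype=float)
        self.next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def species_params(self, idx: int) -> SpeciesParams:
        return self.species_list[idx]

    def species_mask(self, name: str) -> np.ndarray:
        return self.species_idx == self._name_to_idx[name]

    def add(self, species: SpeciesParams, state: CellState, position,
            biomass_fg: float, capsule_fg: float = 0.0,
            agent_id: Optional[int] = None) -> int:
        """Append one cell; returns its id."""
        if agent_id is None:
            agent_id = self.next_id
        self.next_id = max(self.next_id, agent_id + 1)
        sp = self._name_to_idx[species.name]
        self.ids = np.append(self.ids, agent_id)
        self.species_idx = np.append(self.species_idx, sp)
        self.state = np.append(self.state, int(state))
        self.pos = np.vstack([self.pos, np.asarray(position, dtype=float)])
        self.biomass = np.append(self.biomass, biomass_fg)
        self.capsule = np.append(self.capsule, capsule_fg)
        params = self.species_list[sp]
        self.radius = np.append(self.radius, radius_from_masses(
            biomass_fg, capsule_fg, params.cell_density_rho_b,
            params.capsule_density_rho_c))
        return int(agent_id)

    def recompute_radii(self, rows: Optional[np.ndarray] = None) -> None:
        if rows is None:
            rows = np.arange(self.n)
        for si, sp in enumerate(self.species_list):
            m = rows[self.species_idx[rows] == si]
            if len(m):
                self.radius[m] = radius_from_masses(
                    self.biomass[m], self.capsule[m],
                    sp.cell_density_rho_b, sp.capsule_density_rho_c)

    def agent(self, row: int) -> Agent:
        """Materialise row ``row`` as an :class:`Agent` record."""
        return Agent(id=int(self.ids[row]),
                     species=self.species_list[self.species_idx[row]],
                     state=CellState(int(self.state[row])),
                     position=self.pos[row].copy(),
                     biomass_fg=float(self.biomass[row]),
                     capsule_fg=float(self.capsule[row]))

    def __iter__(self) -> Iterator[Agent]:
        return (self.agent(i) for i in range(self.n))

    @classmethod
    def from_agents(cls, agents: Iterable[Agent],
                    species_list: Optional[Sequence[SpeciesParams]] = None
                    ) -> "Population":
        agents = list(agents)
        if species_list is None:
            seen: dict[str, SpeciesParams] = {}
            for a in agents:
                seen.setdefault(a.species.name, a.species)
            species_list = list(seen.values())
        pop = cls(species_list)
        for a in agents:
            pop.add(a.species, a.state, a.position, a.biomass_fg, a.capsule_fg,
                    agent_id=a.id)
        return pop

    def copy(self) -> "Population":
        new = Population(self.species_list)
        new.ids = self.ids.copy()
        new.species_idx = self.species_idx.copy()
        new.state = self.state.copy()
        new.pos = self.pos.copy()
        new.biomass = self.biomass.copy()
        new.capsule = self.capsule.copy()
        new.radius = self.radius.copy()
        new.next_id = self.next_id
        return new

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "id": self.ids,
            "species": [self.species_list[i].name for i in self.species_idx],
            "state": [CellState(int(s)).name for s in self.state],
            "x": self.pos[:, 0],
            "y": self.pos[:, 1],
            "z": self.pos[:, 2],
            "biomass_fg": self.biomass,
            "capsule_fg": self.capsule,
            "radius_um": self.radius,
        })


@dataclass
class SoluteField:
    """One dissolved chemical on the voxel grid.

    ``bulk_maintained`` marks nutrients whose concentration is clamped to
    ``bulk_concentration`` above the boundary layer; secreted products
    (inhibitor, surfactant) instead accumulate under zero-flux boundaries.
    """

    name: str
    concentration: np.ndarray  # g/L, shape == grid.shape
    diffusivity: float  # um^2/h
    bulk_concentration: float  # g/L
    bulk_maintained: bool = True

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def uniform(cls, name: str, grid: DomainGrid, value: float,
                diffusivity: float, bulk_concentration: Optional[float] = None,
                bulk_maintained: bool = True) -> "SoluteField":
        return cls(name=name,
                   concentration=np.full(grid.shape, float(value)),
                   diffusivity=diffusivity,
                   bulk_concentration=(value if bulk_concentration is None
                                       else bulk_concentration),
                   bulk_maintained=bulk_maintained)


@dataclass
class SimulationState:
    """Full state of one run at one instant; the unit of checkpointing."""

    time: float
    agents: Population
    fields: dict[str, SoluteField]
    variant: ModelVariant
    grid: DomainGrid
    rng: np.random.Generator
    # cumulative bookkeeping, fg, keyed by solute name (consumption positive)
    consumed: dict[str, float] = dc_field(default_factory=dict)
    produced_biomass: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        missing = set(self.variant.required_fields) - set(self.fields)
        if missing:
            raise ValueError(f"variant {self.variant} requires fields {missing}")


def local_concentration(field: SoluteField, position, grid: DomainGrid,
                        interpolate: bool = False) -> float:
    """Concentration (g/L) of ``field`` at a point.

    Default is the containing voxel's value (coarse-grained convention);
    ``interpolate=True`` switches to trilinear interpolation.  Positions
    outside the domain in z raise :class:`OutOfDomainError`.
    """
    if interpolate:
        pos = grid.wrap_xy(position)
        if not 0 <= pos[2] <= grid.side_z:
            raise OutOfDomainError("position outside domain in z")
        h = grid.voxel_size
        coords = np.asarray(pos) / h - 0.5
        return float(ndimage.map_coordinates(
            field.concentration, coords.reshape(3, 1), order=1,
            mode="nearest")[0])
    ix, iy, iz = grid.voxel_index(position)
    return float(field.concentration[ix, iy, iz])


def occupancy_grid(agents: Population, grid: DomainGrid) -> np.ndarray:
    """Boolean voxel grid: True where at least one BIOFILM agent centre lies."""
    occ = np.zeros(grid.shape, dtype=bool)
    mask = agents.state == int(CellState.BIOFILM)
    if mask.any():
        idx = grid.voxel_index(agents.pos[mask])
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return occ


def periphery_agents(state: SimulationState) -> set[int]:
    """Ids of BIOFILM agents on the biofilm periphery.

    A biofilm agent is peripheral when its containing voxel has at least one
    biomass-free voxel in its 26-neighbourhood, or touches the domain top.
    The substratum below z=0 never counts as free space; lateral neighbours
    wrap periodically.  Planktonic agents are never peripheral.
    """
    agents = state.agents
    mask = agents.state == int(CellState.BIOFILM)
    if not mask.any():
        return set()
    occ = occupancy_grid(agents, state.grid)
    # pad: periodic in x,y; below substratum counts occupied; above top free
    padded = np.pad(occ, ((1, 1), (1, 1), (0, 0)), mode="wrap")
    padded = np.pad(padded, ((0, 0), (0, 0), (1, 0)), mode="constant",
                    constant_values=True)
    padded = np.pad(padded, ((0, 0), (0, 0), (0, 1)), mode="constant",
                    constant_values=False)
    enclosed = ndimage.minimum_filter(padded, size=3)[1:-1, 1:-1, 1:-1]
    idx = state.grid.voxel_index(agents.pos[mask])
    on_periphery = ~enclosed[idx[:, 0], idx[:, 1], idx[:, 2]]
    return set(agents.ids[mask][on_periphery].tolist())
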