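"""Run orchestration: seeding, the global time loop, the five model
variants, and replicate batches.

Each global step executes a fixed operation order:

1. solve the bulk-maintained nutrient fields to pseudo-steady state at the
   current biomass distribution;
2. advance the accumulating inhibitor/surfactant fields by one transient
   step with the current production sources;
3. grow every biofilm cell with its local effective growth rate (exact
   exponential, rate frozen at step start);
4. divide cells that reached the division radius;
5. relax overlaps by shoving;
6. detach surfactant-exposed periphery cells (surfactant variants only);
7. random-walk the planktonic cells;
8. advance time.

All stochastic draws come from one per-replicate counter-based RNG stream
(Philox), consumed in fixed program order, so a (config, seed) pair fully
determines the trajectory.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from . import dynamics, kinetics, params as default_params, postprocess, solvers
from .domain import (CellState, DomainGrid, ModelVariant, Population,
                     SimulationState, SoluteField, SpeciesParams)

__all__ = ["RunConfig", "Trajectory", "seed_biofilm", "step", "run",
           "run_replicates", "make_fields", "single_species_config",
           "dual_species_config"]

#: default diffusivities, um^2/h; secreted products default to glucose's
DEFAULT_DIFFUSIVITIES = {
    "glucose": default_params.GLUCOSE_DIFFUSIVITY,
    "substrate1": default_params.GLUCOSE_DIFFUSIVITY,
    "substrate2": default_params.GLUCOSE_DIFFUSIVITY,
    "oxygen": default_params.OXYGEN_DIFFUSIVITY,
    "inhibitor": default_params.GLUCOSE_DIFFUSIVITY,
    "surfactant": default_params.GLUCOSE_DIFFUSIVITY,
}

DEFAULT_BULK = {
    "glucose": default_params.BULK_GLUCOSE,
    "substrate1": default_params.BULK_GLUCOSE,
    "substrate2": default_params.BULK_GLUCOSE,
    "oxygen": default_params.BULK_OXYGEN,
    "inhibitor": 0.0,
    "surfactant": 0.0,
}


@dataclass
class RunConfig:
    """Declarative description of one simulation (or replicate batch)."""

    variant: ModelVariant = ModelVariant.COMPETITION
    species: list[SpeciesParams] = dc_field(
        default_factory=default_params.default_species)
    seed_counts: dict[str, int] = dc_field(
        default_factory=lambda: {"so34": 88, "lb334": 88})
    bulk_concentrations: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_BULK))
    diffusivities: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DIFFUSIVITIES))
    duration: float = 16.0  # h
    dt: float = 0.05  # h
    output_interval: float = 1.0  # h
    rng_seed: int = 0
    replicates: int = 5
    grid: DomainGrid = dc_field(default_factory=DomainGrid)
    solver: solvers.SolverSettings = dc_field(
        default_factory=solvers.SolverSettings)
    division: dynamics.DivisionSettings = dc_field(
        default_factory=dynamics.DivisionSettings)
    shove: dynamics.ShoveSettings = dc_field(
        default_factory=dynamics.ShoveSettings)
    planktonic_step_length: float = 5.0  # um per global step
    planktonic_growth: bool = False
    erosion_rate: float = 0.0  # 1/h; generic shear erosion, off by default
    birth_mass_fraction: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if isinstance(self.variant, str):
            self.variant = ModelVariant(self.variant)
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        names = {sp.name for sp in self.species}
        unknown = set(self.seed_counts) - names
        if unknown:
            raise ValueError(f"seed counts reference unknown species {unknown}")
        if any(c < 0 for c in self.seed_counts.values()):
            raise ValueError("seed counts must be non-negative")

    @property
    def total_seed_cells(self) -> int:
        return sum(self.seed_counts.values())

    @property
    def species_order(self) -> list[str]:
        return [sp.name for sp in self.species]

    def species_by_name(self, name: str) -> SpeciesParams:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def config_hash(self) -> str:
        from .io import config_to_dict

        blob = repr(sorted(config_to_dict(self).items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def dual_species_config(variant=ModelVariant.COMPETITION,
                        **overrides) -> RunConfig:
    """Default dual biofilm: 88 + 88 cells of the two species."""
    return RunConfig(variant=variant, **overrides)


def single_species_config(species_name: str,
                          variant=ModelVariant.COMPETITION,
                          total_cells: int = 176, **overrides) -> RunConfig:
    """Single-species biofilm seeded with the full 176-cell inoculum."""
    return RunConfig(variant=variant,
                     seed_counts={species_name: total_cells}, **overrides)


@dataclass
class Trajectory:
    """Output of one run: the time series of replicate summaries plus the
    final state, with provenance (seed, config hash)."""

    times: list[float]
    summaries: pd.DataFrame
    final_state: SimulationState
    seed: int
    config_hash: str
    states: Optional[dict[float, Population]] = None


def make_fields(config: RunConfig) -> dict[str, SoluteField]:
    """Initial solute fields for a variant: nutrients start at bulk,
    secreted products at zero."""
    fields: dict[str, SoluteField] = {}
    for name in config.variant.required_fields:
        maintained = name not in ("inhibitor", "surfactant")
        value = config.bulk_concentrations.get(name, DEFAULT_BULK[name])
        fields[name] = SoluteField.uniform(
            name, config.grid, value if maintained else 0.0,
            diffusivity=config.diffusivities.get(name,
                                                 DEFAULT_DIFFUSIVITIES[name]),
            bulk_concentration=value, bulk_maintained=maintained)
    return fields


def _division_biomass(sp: SpeciesParams,
                      settings: dynamics.DivisionSettings) -> float:
    """Biomass (fg) at which a capsule-free cell reaches the division
    radius."""
    return sp.cell_density_rho_b * (4.0 / 3.0) * np.pi \
        * settings.division_radius ** 3


def seed_biofilm(config: RunConfig,
                 rng: Optional[np.random.Generator] = None) -> SimulationState:
    """Place the inoculum on the substratum.

    Cells are put at uniformly random (x, y) with z equal to their radius;
    birth biomass is uniform in the configured fraction of the division
    mass; in dual runs the species assignment of consecutive placements is
    a random interleave.  One shove relaxation removes initial overlaps.
    """
    if rng is None:
        rng = np.random.Generator(np.random.Philox(config.rng_seed))
    grid = config.grid
    labels: list[str] = []
    for name in config.species_order:
        labels.extend([name] * config.seed_counts.get(name, 0))
    labels = list(np.array(labels, dtype=object)[rng.permutation(len(labels))]
                  ) if labels else []
    pop = Population(config.species)
    lo, hi = config.birth_mass_fraction
    for name in labels:
        sp = config.species_by_name(name)
        mass = rng.uniform(lo, hi) * _division_biomass(sp, config.division)
        x = rng.uniform(0.0, grid.side_x)
        y = rng.uniform(0.0, grid.side_y)
        pop.add(sp, CellState.BIOFILM, (x, y, 0.0), mass)
        pop.pos[pop.n - 1, 2] = pop.radius[pop.n - 1]
    dynamics.shove_relax(pop, grid, config.shove)
    if pop.n >= 2:
        if _max_overlap(pop, grid) > config.shove.overlap_tolerance + 1e-9:
            raise RuntimeError("seeding density too high: overlaps remain "
                               "after relaxation")
    state = SimulationState(time=0.0, agents=pop, fields=make_fields(config),
                            variant=config.variant, grid=grid, rng=rng)
    return state


def _max_overlap(pop: Population, grid: DomainGrid) -> float:
    from scipy.spatial import cKDTree

    rows = np.flatnonzero(pop.state == int(CellState.BIOFILM))
    if len(rows) < 2:
        return 0.0
    pos = pop.pos[rows].copy()
    pos[:, 0] %= grid.side_x
    pos[:, 1] %= grid.side_y
    r = pop.radius[rows]
    box = np.array([grid.side_x, grid.side_y,
                    max(grid.side_z, pos[:, 2].max() + 4 * r.max() + 1)])
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(r=2.0 * float(r.max()), output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    for ax, side in ((0, grid.side_x), (1, grid.side_y)):
        d[:, ax] -= side * np.round(d[:, ax] / side)
    dist = np.linalg.norm(d, axis=1)
    return float(np.max(r[pairs[:, 0]] + r[pairs[:, 1]] - dist, initial=0.0))


def _biomass_per_voxel(state: SimulationState, config: RunConfig
                       ) -> dict[str, np.ndarray]:
    """Per-species biofilm biomass (fg) aggregated on the voxel grid."""
    pop = state.agents
    out: dict[str, np.ndarray] = {}
    active = pop.state == int(CellState.BIOFILM)
    if config.planktonic_growth:
        active = np.ones(pop.n, dtype=bool)
    for si, sp in enumerate(pop.species_list):
        X = np.zeros(state.grid.shape)
        rows = np.flatnonzero(active & (pop.species_idx == si))
        if len(rows):
            idx = state.grid.voxel_index(pop.pos[rows])
            np.add.at(X, (idx[:, 0], idx[:, 1], idx[:, 2]), pop.biomass[rows])
        out[sp.name] = X
    return out


def _clamp_layer(state: SimulationState, config: RunConfig) -> int:
    """First voxel layer held at bulk: boundary-layer thickness above the
    biofilm front."""
    grid = state.grid
    pop = state.agents
    mask = pop.state == int(CellState.BIOFILM)
    z_front = float(np.max(pop.pos[mask, 2] + pop.radius[mask])) if mask.any() \
        else 0.0
    z_clamp = z_front + grid.boundary_layer_thickness
    kc = int(np.ceil(z_clamp / grid.voxel_size - 0.5))
    return max(1, min(kc, grid.nz - 1))


def _solve_nutrients(state: SimulationState, config: RunConfig,
                     Xvox: dict[str, np.ndarray]) -> None:
    """Pseudo-steady solve of all bulk-maintained fields, iterating the
    inter-field Monod coupling to a joint fixed point."""
    grid = state.grid
    voxvol = grid.voxel_volume
    kc = _clamp_layer(state, config)
    variant = state.variant
    order = [n for n in variant.required_fields
             if state.fields[n].bulk_maintained]

    def consumers(field_name: str) -> list[SpeciesParams]:
        if field_name == "oxygen":
            return list(config.species)
        return [sp for sp in config.species
                if kinetics.carbon_source_name(sp, variant,
                                               config.species_order)
                == field_name]

    def rate_fn_for(field_name: str):
        specs = consumers(field_name)

        def rate_fn(conc: np.ndarray) -> np.ndarray:
            rates = np.zeros_like(conc)
            for sp in specs:
                X = Xvox[sp.name]
                if field_name == "oxygen":
                    carbon = kinetics.carbon_source_name(
                        sp, variant, config.species_order)
                    other = state.fields[carbon].concentration
                    f_other = other / (sp.K_Sg + other)
                    half, y = sp.K_So, sp.yield_oxygen
                else:
                    So = state.fields["oxygen"].concentration
                    f_other = So / (sp.K_So + So)
                    half, y = sp.K_Sg, sp.yield_glucose
                f_self = conc / (half + conc)
                rate = sp.mu_max * f_self * f_other
                if variant.inhibition_active and sp.K_I is not None:
                    I = state.fields["inhibitor"].concentration
                    rate = rate * (sp.K_I / (sp.K_I + I))
                rates += y * rate * X / voxvol
            return rates

        return rate_fn

    coupled = any(len(consumers(n)) > 0 for n in order)
    max_outer = 20 if coupled else 1
    tol = config.solver.tolerance
    for _ in range(max_outer):
        change = 0.0
        for name in order:
            f = state.fields[name]
            before = f.concentration.copy()
            solvers.solve_steady(f, rate_fn_for(name), grid, config.solver,
                                 clamp_from_layer=kc)
            scale = max(f.bulk_concentration, 1e-300)
            change = max(change,
                         float(np.max(np.abs(f.concentration - before)))
                         / scale)
        if change <= tol:
            break


def _step_products(state: SimulationState, config: RunConfig,
                   Xvox: dict[str, np.ndarray]) -> None:
    """Transient step of the accumulating inhibitor/surfactant fields."""
    voxvol = state.grid.voxel_volume
    for name in ("inhibitor", "surfactant"):
        if name not in state.fields:
            continue
        src = np.zeros(state.grid.shape)
        for sp in config.species:
            k = sp.production_rate_k
            y = sp.yield_inhibitor if name == "inhibitor" else sp.yield_surfactant
            if k is None or y is None:
                continue
            src += y * k * Xvox[sp.name] / voxvol
        solvers.step_transient(state.fields[name], src, config.dt, state.grid,
                               config.solver)


def _grow_agents(state: SimulationState, config: RunConfig) -> None:
    """Grow every active cell with its local effective rate; update the
    consumption/production ledger."""
    pop = state.agents
    grid = state.grid
    active = pop.state == int(CellState.BIOFILM)
    if config.planktonic_growth:
        active = np.ones(pop.n, dtype=bool)
    if not active.any():
        return
    rows_all = np.flatnonzero(active)
    idx = grid.voxel_index(pop.pos[rows_all])
    eps = state.variant.eps_active
    for si, sp in enumerate(pop.species_list):
        sel = pop.species_idx[rows_all] == si
        if not sel.any():
            continue
        rows = rows_all[sel]
        vix = idx[sel]
        solutes = {}
        for name, f in state.fields.items():
            solutes[name] = f.concentration[vix[:, 0], vix[:, 1], vix[:, 2]]
        mu = kinetics.effective_mu(sp, solutes, state.variant,
                                   config.species_order)
        new_b, new_c, delta = kinetics.grow_masses(
            pop.biomass[rows], pop.capsule[rows], mu, config.dt,
            sp.biomass_fraction, sp.capsule_fraction, eps)
        pop.biomass[rows] = new_b
        pop.capsule[rows] = new_c
        total = float(np.sum(delta))
        state.produced_biomass[sp.name] = (
            state.produced_biomass.get(sp.name, 0.0) + total)
        carbon = kinetics.carbon_source_name(sp, state.variant,
                                             config.species_order)
        state.consumed[carbon] = (state.consumed.get(carbon, 0.0)
                                  + abs(sp.yield_glucose) * total)
        state.consumed["oxygen"] = (state.consumed.get("oxygen", 0.0)
                                    + abs(sp.yield_oxygen) * total)
        pop.recompute_radii(rows)


def _divide_agents(state: SimulationState, config: RunConfig) -> None:
    pop = state.agents
    ready = np.flatnonzero(pop.radius >= config.division.division_radius)
    for row in ready:
        agent = pop.agent(row)
        out = dynamics.divide_if_ready(agent, config.division, state.rng,
                                       new_id=pop.next_id)
        if len(out) == 1:
            continue
        d1, d2 = out
        pop.pos[row] = state.grid.wrap_xy(d1.position)
        pop.biomass[row] = d1.biomass_fg
        pop.capsule[row] = d1.capsule_fg
        pop.radius[row] = d1.radius_um
        pop.add(d2.species, d2.state, state.grid.wrap_xy(d2.position),
                d2.biomass_fg, d2.capsule_fg, agent_id=d2.id)


def step(state: SimulationState, config: RunConfig) -> SimulationState:
    """Advance the simulation by one global step ``config.dt``."""
    Xvox = _biomass_per_voxel(state, config)
    _solve_nutrients(state, config, Xvox)
    _step_products(state, config, Xvox)
    _grow_agents(state, config)
    _divide_agents(state, config)
    dynamics.shove_relax(state.agents, state.grid, config.shove)
    if state.variant.surfactant_active:
        dynamics.surfactant_detach(state)
    if config.erosion_rate > 0:
        dynamics.erosion_detach(state, config.erosion_rate, config.dt)
    dynamics.planktonic_move(state, config.dt, state.rng,
                             config.planktonic_step_length)
    state.time += config.dt
    return state


def run(config: RunConfig, seed: Optional[int] = None,
        store_states: bool = False) -> Trajectory:
    """Run one full simulation and collect summaries at every output
    interval (plus t=0 and the final time)."""
    seed = config.rng_seed if seed is None else seed
    rng = np.random.Generator(np.random.Philox(seed))
    state = seed_biofilm(config, rng)
    n_steps = int(round(config.duration / config.dt))
    rec_every = max(1, int(round(config.output_interval / config.dt)))
    times: list[float] = []
    frames: list[pd.DataFrame] = []
    states: dict[float, Population] = {}

    def record() -> None:
        times.append(round(state.time, 9))
        frame = postprocess.summarize_state(state)
        frames.append(frame)
        if store_states:
            states[times[-1]] = state.agents.copy()

    record()
    for i in range(1, n_steps + 1):
        step(state, config)
        state.time = round(i * config.dt, 12)  # avoid fp drift
        if i % rec_every == 0 or i == n_steps:
            record()
    summaries = pd.concat(frames, ignore_index=True)
    return Trajectory(times=times, summaries=summaries, final_state=state,
                      seed=seed, config_hash=config.config_hash(),
                      states=states if store_states else None)


def run_replicates(config: RunConfig,
                   base_seed: Optional[int] = None) -> list[Trajectory]:
    """Run ``config.replicates`` independent replicates with seeds
    base_seed + 0 .. base_seed + (n-1)."""
    if config.replicates < 1:
        raise ValueError("replicate count must be >= 1")
    base = config.rng_seed if base_seed is None else base_seed
    return [run(config, seed=base + i) for i in range(config.replicates)]
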