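"""Agent-rule tests: division, shoving, surfactant detachment, and
planktonic movement."""

import numpy as np
import pytest

from biofilmsim import engine
from biofilmsim.domain import (Agent, CellState, DomainGrid, ModelVariant,
                               Population, SimulationState, SoluteField)
from biofilmsim.dynamics import (DivisionSettings, ShoveSettings,
                                 divide_if_ready, planktonic_move,
                                 shove_relax, surfactant_detach)

from conftest import fast_config


def make_rng(seed=0):
    return np.random.Generator(np.random.Philox(seed))


class TestDivision:
    def test_below_threshold_unchanged(self, so):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(5, 5, 1), biomass_fg=100.0)
        out = divide_if_ready(a, DivisionSettings(), make_rng())
        assert out == [a]

    def test_masses_conserved_exactly(self, so):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(5, 5, 1), biomass_fg=200.0, capsule_fg=40.0)
        # radius > 1 um guaranteed? force threshold below current radius
        settings = DivisionSettings(division_radius=a.radius_um)
        d1, d2 = divide_if_ready(a, settings, make_rng(), new_id=99)
        assert d1.biomass_fg + d2.biomass_fg == 200.0
        assert d1.capsule_fg + d2.capsule_fg == 40.0
        assert {d1.id, d2.id} == {0, 99}
        assert d1.species is so and d2.state is CellState.BIOFILM

    def test_split_ratio_within_bounds(self, so):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(5, 5, 1), biomass_fg=700.0)
        d1, d2 = divide_if_ready(a, DivisionSettings(), make_rng(3))
        frac = d1.biomass_fg / 700.0
        assert 0.45 <= frac <= 0.55

    def test_deterministic_given_seed(self, so):
        outs = []
        for _ in range(2):
            a = Agent(id=0, species=so, state=CellState.BIOFILM,
                      position=(5, 5, 1), biomass_fg=700.0)
            outs.append(divide_if_ready(a, DivisionSettings(), make_rng(7)))
        (a1, a2), (b1, b2) = outs
        np.testing.assert_array_equal(a1.position, b1.position)
        np.testing.assert_array_equal(a2.position, b2.position)
        assert a1.biomass_fg == b1.biomass_fg

    def test_daughters_stay_above_substratum(self, so):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(5, 5, 0.9), biomass_fg=700.0)
        for seed in range(10):
            for d in divide_if_ready(a, DivisionSettings(), make_rng(seed)):
                assert d.position[2] >= d.radius_um - 1e-12


class TestShove:
    def grid(self):
        return DomainGrid(64, 64, 48, 8, boundary_layer_thickness=24)

    def pop_of(self, so, positions, biomass=628.3):
        agents = [Agent(id=i, species=so, state=CellState.BIOFILM,
                        position=p, biomass_fg=biomass)
                  for i, p in enumerate(positions)]
        return Population.from_agents(agents, [so])

    def test_overlapping_pair_separates_symmetrically(self, so):
        # two ~1-um spheres at centre distance 1 -> pushed to distance 2
        pop = self.pop_of(so, [(31.5, 32, 5), (32.5, 32, 5)])
        r = pop.radius.copy()
        shove_relax(pop, self.grid(), ShoveSettings(overlap_tolerance=1e-9))
        d = np.linalg.norm(pop.pos[0] - pop.pos[1])
        assert d == pytest.approx(r[0] + r[1], abs=1e-9)
        mid = 0.5 * (pop.pos[0] + pop.pos[1])
        np.testing.assert_allclose(mid[:2], (32.0, 32.0), atol=1e-9)

    def test_no_overlap_is_bitwise_fixed_point(self, so):
        pop = self.pop_of(so, [(10, 10, 5), (20, 20, 5), (30, 30, 5)])
        before = pop.pos.copy()
        shove_relax(pop, self.grid(), ShoveSettings())
        assert np.array_equal(pop.pos, before)

    def test_substratum_constraint(self, so):
        # vertical stack forces the lower agent downward; z stays >= r
        pop = self.pop_of(so, [(32, 32, 1.0), (32, 32, 1.5)])
        shove_relax(pop, self.grid(), ShoveSettings(overlap_tolerance=1e-6))
        assert np.all(pop.pos[:, 2] >= pop.radius - 1e-12)

    def test_mass_untouched_by_shoving(self, so):
        pop = self.pop_of(so, [(31.5, 32, 5), (32.5, 32, 5)])
        total = pop.biomass.sum() + pop.capsule.sum()
        shove_relax(pop, self.grid(), ShoveSettings())
        assert pop.biomass.sum() + pop.capsule.sum() == total

    def test_sweep_cap_warns(self, so):
        # an over-dense cluster cannot fully relax in one sweep
        pos = [(32 + 0.01 * i, 32, 1) for i in range(8)]
        pop = self.pop_of(so, pos)
        with pytest.warns(RuntimeWarning):
            shove_relax(pop, self.grid(),
                        ShoveSettings(overlap_tolerance=1e-12, max_sweeps=1))


def surf_state(so, lb, agents, conc, grid=None):
    grid = grid or DomainGrid(64, 64, 48, 8, boundary_layer_thickness=24)
    pop = Population.from_agents(agents, [so, lb])
    fields = {
        "glucose": SoluteField.uniform("glucose", grid, 2.0, 2.1e4),
        "oxygen": SoluteField.uniform("oxygen", grid, 0.0064, 7.2e4),
        "surfactant": SoluteField.uniform("surfactant", grid, conc, 2.1e4,
                                          bulk_concentration=0.0,
                                          bulk_maintained=False),
    }
    return SimulationState(time=0.0, agents=pop, fields=fields,
                           variant=ModelVariant.SURFACTANT, grid=grid,
                           rng=make_rng(11))


class TestSurfactantDetach:
    def agents(self, so, lb):
        return [
            Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(10, 10, 1), biomass_fg=400.0),
            Agent(id=1, species=lb, state=CellState.BIOFILM,
                  position=(30, 30, 1), biomass_fg=400.0),
        ]

    def test_species_specific_thresholds(self, so, lb):
        # 0.006 g/L exceeds the S. oralis tolerance (0.005) but not the
        # L. paracasei one (0.008)
        state = surf_state(so, lb, self.agents(so, lb), conc=0.006)
        surfactant_detach(state)
        assert state.agents.state[0] == int(CellState.PLANKTONIC)
        assert state.agents.state[1] == int(CellState.BIOFILM)

    def test_below_both_thresholds_nothing_detaches(self, so, lb):
        state = surf_state(so, lb, self.agents(so, lb), conc=0.004)
        surfactant_detach(state)
        assert np.all(state.agents.state == int(CellState.BIOFILM))

    def test_exactly_at_threshold_stays(self, so, lb):
        state = surf_state(so, lb, self.agents(so, lb), conc=0.005)
        surfactant_detach(state)
        assert state.agents.state[0] == int(CellState.BIOFILM)

    def test_enclosed_cell_never_detaches(self, so, lb):
        agents = []
        aid = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (0, 1, 2):
                    agents.append(Agent(
                        id=aid, species=so, state=CellState.BIOFILM,
                        position=(36 + 8 * dx, 36 + 8 * dy, 12 + 8 * dz),
                        biomass_fg=400.0))
                    aid += 1
        # the block floats above the substratum, so only the centre cell
        # has no free neighbouring voxel
        enclosed_ids = {13}
        state = surf_state(so, lb, agents, conc=0.02)
        surfactant_detach(state)
        for i in enclosed_ids:
            assert state.agents.state[i] == int(CellState.BIOFILM)

    def test_detached_relocate_to_boundary_layer_band(self, so, lb):
        state = surf_state(so, lb, self.agents(so, lb), conc=0.02)
        surfactant_detach(state)
        grid = state.grid
        rows = state.agents.state == int(CellState.PLANKTONIC)
        z = state.agents.pos[rows, 2]
        assert np.all(z >= grid.side_z - grid.boundary_layer_thickness)
        assert np.all(z <= grid.side_z)

    def test_monotone_in_concentration(self, so, lb):
        detached = []
        for conc in (0.0055, 0.02):
            state = surf_state(so, lb, self.agents(so, lb), conc=conc)
            surfactant_detach(state)
            detached.append(set(state.agents.ids[
                state.agents.state == int(CellState.PLANKTONIC)].tolist()))
        assert detached[0] <= detached[1]


class TestPlanktonicMove:
    def state(self, so, lb):
        a = Agent(id=0, species=so, state=CellState.PLANKTONIC,
                  position=(32, 32, 40), biomass_fg=400.0)
        return surf_state(so, lb, [a], conc=0.0)

    def test_zero_step_length_is_identity(self, so, lb):
        state = self.state(so, lb)
        before = state.agents.pos.copy()
        planktonic_move(state, dt=0.05, step_length=0.0)
        assert np.array_equal(state.agents.pos, before)

    def test_reflection_keeps_agent_in_band(self, so, lb):
        state = self.state(so, lb)
        grid = state.grid
        lo = grid.side_z - grid.boundary_layer_thickness
        for _ in range(10_000):
            planktonic_move(state, dt=0.05, step_length=5.0)
            z = state.agents.pos[0, 2]
            assert lo - 1e-9 <= z <= grid.side_z + 1e-9

    def test_trajectory_reproducible(self, so, lb):
        trajs = []
        for _ in range(2):
            state = self.state(so, lb)
            rng = make_rng(123)
            pts = []
            for _ in range(50):
                planktonic_move(state, dt=0.05, rng=rng, step_length=5.0)
                pts.append(state.agents.pos[0].copy())
            trajs.append(np.array(pts))
        np.testing.assert_array_equal(trajs[0], trajs[1])

    def test_biofilm_agents_untouched(self, so, lb):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(32, 32, 1), biomass_fg=400.0)
        state = surf_state(so, lb, [a], conc=0.0)
        planktonic_move(state, dt=0.05, step_length=5.0)
        np.testing.assert_array_equal(state.agents.pos[0], (32, 32, 1))


class TestDetachmentIsOneWay:
    def test_planktonic_set_grows_monotonically_over_a_run(self):
        config = fast_config(variant="surfactant",
                             seed_counts={"so34": 12, "lb334": 20},
                             duration=3.0, output_interval=0.5)
        traj = engine.run(config, seed=4, store_states=True)
        prev: set = set()
        for t in traj.times:
            pop = traj.states[t]
            plank = set(pop.ids[pop.state == int(CellState.PLANKTONIC)]
                        .tolist())
            assert prev <= plank
            prev = plank
        assert prev, "expected some detachment in a surfactant run"
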