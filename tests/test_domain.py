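"""Domain model tests: grid geometry, agent radii, concentration queries,
periphery detection, and periodic-wrap equivalence."""

import numpy as np
import pytest

from biofilmsim import engine
from biofilmsim.domain import (Agent, CellState, DomainGrid, ModelVariant,
                               OutOfDomainError, Population, SoluteField,
                               local_concentration, periphery_agents,
                               radius_from_masses)
from biofilmsim.postprocess import biovolume, thickness

from conftest import fast_config


class TestDomainGrid:
    def test_default_surface_area(self):
        assert DomainGrid().substratum_area == 18496.0

    def test_voxel_counts(self):
        g = DomainGrid(136, 136, 136, 8)
        assert g.shape == (17, 17, 17)
        assert g.voxel_volume == 512.0

    def test_side_must_be_voxel_multiple(self):
        with pytest.raises(ValueError):
            DomainGrid(130, 136, 136, 8)

    def test_boundary_layer_inside_domain(self):
        with pytest.raises(ValueError):
            DomainGrid(64, 64, 48, 8, boundary_layer_thickness=48)

    def test_voxel_index_wraps_laterally(self):
        g = DomainGrid(64, 64, 48, 8, boundary_layer_thickness=24)
        assert tuple(g.voxel_index((65.0, -1.0, 4.0))) == (0, 7, 0)

    def test_voxel_index_rejects_z_outside(self):
        g = DomainGrid(64, 64, 48, 8, boundary_layer_thickness=24)
        with pytest.raises(OutOfDomainError):
            g.voxel_index((1.0, 1.0, 49.0))


class TestAgentGeometry:
    def test_radius_matches_sphere_of_total_volume(self, so):
        # 628.3 fg of pure biomass at 150 g/L is a 1-um-radius sphere
        mass = 150.0 * (4 / 3) * np.pi
        assert radius_from_masses(mass, 0.0) == pytest.approx(1.0)

    def test_capsule_density_half_doubles_capsule_volume(self):
        r_cap = radius_from_masses(0.0, 75.0 * (4 / 3) * np.pi)
        assert r_cap == pytest.approx(1.0)

    def test_agent_radius_property(self, so):
        a = Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(1, 1, 1), biomass_fg=300.0, capsule_fg=40.0)
        expect = radius_from_masses(300.0, 40.0, so.cell_density_rho_b,
                                    so.capsule_density_rho_c)
        assert a.radius_um == pytest.approx(float(expect), rel=1e-12)

    def test_invalid_masses_rejected(self, so):
        with pytest.raises(ValueError):
            Agent(id=0, species=so, state=CellState.BIOFILM,
                  position=(0, 0, 0), biomass_fg=0.0)


class TestSpeciesParams:
    def test_fraction_sum_enforced(self, so):
        with pytest.raises(ValueError):
            __import__("biofilmsim").streptococcus_oralis(
                biomass_fraction=0.7)

    def test_positive_constants_enforced(self):
        with pytest.raises(ValueError):
            __import__("biofilmsim").streptococcus_oralis(K_Sg=0.0)


class TestModelVariant:
    @pytest.mark.parametrize("variant,inhib,surf,eps,shared", [
        (ModelVariant.COMPETITION, False, False, True, True),
        (ModelVariant.INDEPENDENT_SUBSTRATES, False, False, True, False),
        (ModelVariant.INHIBITION, True, False, True, True),
        (ModelVariant.SURFACTANT, False, True, False, True),
        (ModelVariant.INHIBITION_SURFACTANT, True, True, False, True),
    ])
    def test_flags_are_function_of_variant(self, variant, inhib, surf, eps,
                                           shared):
        assert variant.inhibition_active is inhib
        assert variant.surfactant_active is surf
        assert variant.eps_active is eps
        assert variant.shared_carbon is shared

    def test_required_fields_match_mechanisms(self):
        assert "inhibitor" in ModelVariant.INHIBITION.required_fields
        assert "inhibitor" not in ModelVariant.COMPETITION.required_fields
        assert set(ModelVariant.INDEPENDENT_SUBSTRATES.required_fields) \
            == {"substrate1", "substrate2", "oxygen"}


class TestLocalConcentration:
    def test_uniform_field_everywhere(self, small_grid):
        f = SoluteField.uniform("glucose", small_grid, 2.0, 2.1e4)
        for p in [(1, 1, 1), (63, 63, 47), (32.5, 17.2, 20.0)]:
            assert local_concentration(f, p, small_grid) == 2.0

    def test_zero_field(self, small_grid):
        f = SoluteField.uniform("glucose", small_grid, 0.0, 2.1e4, 2.0)
        assert local_concentration(f, (5, 5, 5), small_grid) == 0.0

    def test_out_of_domain_z_raises(self, small_grid):
        f = SoluteField.uniform("glucose", small_grid, 2.0, 2.1e4)
        with pytest.raises(OutOfDomainError):
            local_concentration(f, (1, 1, small_grid.side_z + 1), small_grid)

    def test_voxel_convention_picks_containing_voxel(self, small_grid):
        f = SoluteField.uniform("glucose", small_grid, 1.0, 2.1e4)
        f.concentration[0, 0, 0] = 5.0
        assert local_concentration(f, (7.9, 7.9, 7.9), small_grid) == 5.0
        assert local_concentration(f, (8.1, 7.9, 7.9), small_grid) == 1.0


def _state_with(agents, grid, so, lb):
    pop = Population.from_agents(agents, [so, lb])
    from biofilmsim.domain import SimulationState

    fields = {"glucose": SoluteField.uniform("glucose", grid, 2.0, 2.1e4),
              "oxygen": SoluteField.uniform("oxygen", grid, 0.0064, 7.2e4)}
    return SimulationState(time=0.0, agents=pop, fields=fields,
                           variant=ModelVariant.COMPETITION, grid=grid,
                           rng=np.random.default_rng(0))


class TestPeriphery:
    def test_isolated_cell_is_periphery(self, small_grid, so, lb):
        a = Agent(id=7, species=so, state=CellState.BIOFILM,
                  position=(10, 10, 1), biomass_fg=300.0)
        state = _state_with([a], small_grid, so, lb)
        assert periphery_agents(state) == {7}

    def test_fully_enclosed_cell_excluded(self, small_grid, so, lb):
        agents = []
        aid = 0
        # fill a 3x3x3 voxel block around voxel (4,4,1)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    agents.append(Agent(
                        id=aid, species=so, state=CellState.BIOFILM,
                        position=(36 + 8 * dx, 36 + 8 * dy, 12 + 8 * dz),
                        biomass_fg=300.0))
                    aid += 1
        state = _state_with(agents, small_grid, so, lb)
        peri = periphery_agents(state)
        center_id = 13  # the (0,0,0) offset agent
        assert center_id not in peri
        # the bottom-centre cell is enclosed too: the substratum below it
        # is not free space
        bottom_center_id = 12  # offset (0, 0, -1)
        assert bottom_center_id not in peri
        assert len(peri) == 25

    def test_planktonic_never_peripheral(self, small_grid, so, lb):
        a = Agent(id=1, species=so, state=CellState.PLANKTONIC,
                  position=(10, 10, 40), biomass_fg=300.0)
        state = _state_with([a], small_grid, so, lb)
        assert periphery_agents(state) == set()

    def test_empty_population(self, small_grid, so, lb):
        state = _state_with([], small_grid, so, lb)
        assert periphery_agents(state) == set()

    def test_removal_never_encloses_others(self, small_grid, so, lb):
        rng = np.random.default_rng(3)
        agents = [Agent(id=i, species=so, state=CellState.BIOFILM,
                        position=(rng.uniform(0, 64), rng.uniform(0, 64),
                                  rng.uniform(0.5, 20)), biomass_fg=300.0)
                  for i in range(60)]
        state = _state_with(agents, small_grid, so, lb)
        before = periphery_agents(state)
        for drop in (0, 17, 42):
            remaining = [a for a in agents if a.id != drop]
            after = periphery_agents(
                _state_with(remaining, small_grid, so, lb))
            assert (before - {drop}) <= after


class TestPeriodicEquivalence:
    def test_lateral_translation_preserves_observables(self, so, lb):
        config = fast_config(rng_seed=5)
        state = engine.seed_biofilm(config)
        base_bv = biovolume(state)
        base_th = thickness(state)
        base_peri = periphery_agents(state)
        state.agents.pos[:, 0] += config.grid.side_x
        state.agents.pos = config.grid.wrap_xy(state.agents.pos)
        assert biovolume(state) == pytest.approx(base_bv, rel=1e-12)
        assert thickness(state) == pytest.approx(base_th, rel=1e-12)
        assert periphery_agents(state) == base_peri


class TestRadiusConsistencyAfterStepping:
    def test_radii_match_masses_after_engine_steps(self):
        config = fast_config(duration=0.5)
        traj = engine.run(config, seed=9)
        pop = traj.final_state.agents
        expect = pop.radius.copy()
        pop.recompute_radii()
        np.testing.assert_allclose(pop.radius, expect, rtol=1e-9)
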