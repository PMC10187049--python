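"""Plain-text run serialization.

One agent table (CSV) per output timepoint with fixed columns
``id, species, state, x, y, z, biomass_fg, capsule_fg, radius_um``, one
headered dense-array text file per solute field, and a ``manifest.json``
listing the timepoints.  Run configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .domain import (CellState, DomainGrid, ModelVariant, Population,
                     SimulationState, SoluteField, SpeciesParams)

AGENT_COLUMNS = ["id", "species", "state", "x", "y", "z", "biomass_fg",
                 "capsule_fg", "radius_um"]

__all__ = ["AGENT_COLUMNS", "save_agent_table", "load_agent_table",
           "save_field", "load_field", "save_state", "load_manifest",
           "config_to_dict", "config_from_dict", "save_config",
           "load_config"]


def save_agent_table(agents: Population, path: Union[str, Path]) -> Path:
    path = Path(path)
    agents.to_dataframe()[AGENT_COLUMNS].to_csv(path, index=False)
    return path


def load_agent_table(path: Union[str, Path],
                     species_list: Sequence[SpeciesParams]) -> Population:
    frame = pd.read_csv(path)
    missing = set(AGENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"agent table missing columns {missing}")
    by_name = {sp.name: sp for sp in species_list}
    pop = Population(list(species_list))
    for rec in frame.itertuples(index=False):
        pop.add(by_name[rec.species], CellState[rec.state],
                (rec.x, rec.y, rec.z), rec.biomass_fg, rec.capsule_fg,
                agent_id=int(rec.id))
    return pop


def save_field(field: SoluteField, grid: DomainGrid, time: float,
               path: Union[str, Path]) -> Path:
    path = Path(path)
    header = json.dumps({"name": field.name, "shape": list(grid.shape),
                         "voxel_size": grid.voxel_size, "time": time,
                         "diffusivity": field.diffusivity,
                         "bulk_concentration": field.bulk_concentration,
                         "bulk_maintained": field.bulk_maintained})
    np.savetxt(path, field.concentration.reshape(-1), header=header,
               fmt="%.12e")
    return path


def load_field(path: Union[str, Path]) -> SoluteField:
    path = Path(path)
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# ").strip())
    values = np.loadtxt(path)
    return SoluteField(name=header["name"],
                       concentration=values.reshape(header["shape"]),
                       diffusivity=header["diffusivity"],
                       bulk_concentration=header["bulk_concentration"],
                       bulk_maintained=header["bulk_maintained"])


def save_state(state: SimulationState, outdir: Union[str, Path],
               save_fields: bool = True) -> dict:
    """Write one snapshot; returns its manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"t{state.time:08.3f}".replace(".", "p")
    agent_file = f"agents_{tag}.csv"
    save_agent_table(state.agents, outdir / agent_file)
    entry = {"time": state.time, "agents": agent_file, "fields": {}}
    if save_fields:
        for name, field in state.fields.items():
            field_file = f"field_{name}_{tag}.txt"
            save_field(field, state.grid, state.time, outdir / field_file)
            entry["fields"][name] = field_file
    manifest_path = outdir / "manifest.json"
    manifest = {"variant": state.variant.value, "timepoints": []}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["timepoints"] = [e for e in manifest["timepoints"]
                              if e["time"] != state.time] + [entry]
    manifest["timepoints"].sort(key=lambda e: e["time"])
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return entry


def load_manifest(outdir: Union[str, Path]) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())


def _species_to_dict(sp: SpeciesParams) -> dict:
    return {k: v for k, v in dataclasses.asdict(sp).items() if v is not None}


def config_to_dict(config) -> dict:
    from . import engine  # noqa: F401  (type only)

    return {
        "variant": config.variant.value,
        "species": [_species_to_dict(sp) for sp in config.species],
        "seed_counts": dict(config.seed_counts),
        "bulk_concentrations": dict(config.bulk_concentrations),
        "diffusivities": dict(config.diffusivities),
        "duration": config.duration,
        "dt": config.dt,
        "output_interval": config.output_interval,
        "rng_seed": config.rng_seed,
        "replicates": config.replicates,
        "grid": dataclasses.asdict(config.grid),
        "solver": {"tolerance": config.solver.tolerance,
                   "max_iterations": config.solver.max_iterations},
        "division": dataclasses.asdict(config.division),
        "shove": dataclasses.asdict(config.shove),
        "planktonic_step_length": config.planktonic_step_length,
        "planktonic_growth": config.planktonic_growth,
        "erosion_rate": config.erosion_rate,
    }


def config_from_dict(data: dict):
    from . import dynamics, engine, solvers

    kw = dict(data)
    kw["variant"] = ModelVariant(kw.get("variant", "competition"))
    if "species" in kw:
        kw["species"] = [SpeciesParams(**d) for d in kw["species"]]
    if "grid" in kw:
        kw["grid"] = DomainGrid(**kw["grid"])
    if "solver" in kw:
        kw["solver"] = solvers.SolverSettings(**kw["solver"])
    if "division" in kw:
        kw["division"] = dynamics.DivisionSettings(**kw["division"])
    if "shove" in kw:
        kw["shove"] = dynamics.ShoveSettings(**kw["shove"])
    if "birth_mass_fraction" in kw:
        kw["birth_mass_fraction"] = tuple(kw["birth_mass_fraction"])
    return engine.RunConfig(**kw)


def save_config(config, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
    return path


def load_config(path: Union[str, Path]):
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
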