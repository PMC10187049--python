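"""Observables computed from simulation output: biovolume, counts, biofilm
thickness, replicate statistics, and the dilution-series regression.

Biovolume is the sum of agent sphere volumes (capsule included by default,
overlaps not deduplicated), the same aggregation used for the imaged
biofilms.  Planktonic cells are excluded from biovolume and thickness but
kept in counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .domain import (CellState, Population, SimulationState,
                     radius_from_masses)

__all__ = ["biovolume", "thickness", "summarize_state", "summarize_runs",
           "replicate_cv", "dilution_regression", "RegressionResult",
           "EmptyBiofilmError"]


class EmptyBiofilmError(ValueError):
    """An observable that needs biofilm cells was asked of an empty biofilm."""


def _population(obj: Union[SimulationState, Population]) -> Population:
    return obj.agents if isinstance(obj, SimulationState) else obj


def _select(pop: Population, species: Optional[str],
            cell_state: Optional[CellState]) -> np.ndarray:
    mask = np.ones(pop.n, dtype=bool)
    if species is not None:
        mask &= pop.species_mask(species)
    if cell_state is not None:
        mask &= pop.state == int(cell_state)
    return mask


def biovolume(state: Union[SimulationState, Population],
              species: Optional[str] = None,
              cell_state: Optional[CellState] = CellState.BIOFILM,
              include_capsule: bool = True) -> float:
    """Total volume (um^3) of the selected cells as a sum of sphere
    volumes.  ``species=None`` selects all species; ``cell_state=None``
    selects both biofilm and planktonic cells."""
    pop = _population(state)
    mask = _select(pop, species, cell_state)
    if include_capsule:
        r = pop.radius[mask]
    else:
        r = np.empty(mask.sum())
        sub = np.flatnonzero(mask)
        for si, sp in enumerate(pop.species_list):
            m = pop.species_idx[sub] == si
            r[m] = radius_from_masses(pop.biomass[sub[m]], 0.0,
                                      sp.cell_density_rho_b,
                                      sp.capsule_density_rho_c)
    return float(np.sum(4.0 / 3.0 * np.pi * r ** 3))


def thickness(state: SimulationState) -> float:
    """Mean biofilm thickness (um): over the occupied (x, y) voxel columns,
    the per-column maximum of (z + radius) of biofilm agents."""
    pop = state.agents
    mask = pop.state == int(CellState.BIOFILM)
    if not mask.any():
        raise EmptyBiofilmError("thickness is undefined for an empty biofilm")
    grid = state.grid
    idx = grid.voxel_index(pop.pos[mask])
    col = idx[:, 0] * grid.ny + idx[:, 1]
    tops = pop.pos[mask, 2] + pop.radius[mask]
    order = np.argsort(col, kind="stable")
    col_sorted, tops_sorted = col[order], tops[order]
    boundaries = np.flatnonzero(np.diff(col_sorted)) + 1
    col_max = np.maximum.reduceat(tops_sorted,
                                  np.concatenate([[0], boundaries]))
    return float(np.mean(col_max))


def summarize_state(state: SimulationState) -> pd.DataFrame:
    """Tidy per-species, per-state summary of one snapshot."""
    pop = state.agents
    try:
        thick = thickness(state)
    except EmptyBiofilmError:
        thick = np.nan
    rows = []
    for sp in pop.species_list:
        for cs in CellState:
            mask = _select(pop, sp.name, cs)
            rows.append({
                "time_h": state.time,
                "species": sp.name,
                "state": cs.name,
                "biovolume_um3": biovolume(pop, sp.name, cs),
                "count": int(mask.sum()),
                "thickness_um": thick if cs is CellState.BIOFILM else np.nan,
            })
    return pd.DataFrame(rows)


def summarize_runs(trajectories: Sequence) -> pd.DataFrame:
    """Long-format summary across replicates: run_id, time_h, species,
    state, biovolume_um3, count, thickness_um."""
    frames = []
    for i, traj in enumerate(trajectories):
        frame = traj.summaries.copy()
        frame.insert(0, "run_id", i)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def replicate_cv(summaries: Sequence, species: str,
                 cell_state: CellState = CellState.BIOFILM,
                 observable: str = "biovolume_um3",
                 time: Optional[float] = None) -> float:
    """Coefficient of variation (percent, sample SD over mean) of one
    observable across replicates at the final (or given) time.

    ``summaries`` is a sequence of per-replicate summary DataFrames or
    Trajectory objects.  Requires at least two replicates and a non-zero
    mean.
    """
    if len(summaries) < 2:
        raise ValueError("replicate_cv needs at least 2 replicates")
    values = []
    for item in summaries:
        frame = item.summaries if hasattr(item, "summaries") else item
        t = frame["time_h"].max() if time is None else time
        sel = frame[(frame["time_h"] == t)
                    & (frame["species"] == species)
                    & (frame["state"] == cell_state.name)]
        if len(sel) != 1:
            raise ValueError("summary selection did not yield one row")
        values.append(float(sel[observable].iloc[0]))
    values = np.asarray(values)
    mean = values.mean()
    if mean == 0:
        raise ValueError("replicate_cv undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def dilution_regression(table: Union[pd.DataFrame, tuple],
                        x_col: str = "dilution",
                        y_col: str = "biovolume_um3") -> RegressionResult:
    """Ordinary least squares of biovolume on medium-dilution fraction.

    Accepts a DataFrame with dilution/biovolume columns or an (x, y) pair.
    R^2 is the squared Pearson correlation (0 for constant response).
    Degenerate designs (<3 points unless exactly 2, or a single distinct
    dilution) are rejected.
    """
    if isinstance(table, pd.DataFrame):
        x = np.asarray(table[x_col], dtype=float)
        y = np.asarray(table[y_col], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in table)
    if len(x) < 2:
        raise ValueError("regression needs at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("regression needs >= 2 distinct dilution values")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2))
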