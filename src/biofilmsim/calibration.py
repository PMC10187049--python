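"""Growth-parameter estimation against a dilution-series response.

The in vitro reference is a glucose dilution sweep: single-species
biofilms grown for 16 h in medium diluted to a fraction of full strength,
with biovolume responding roughly linearly to the dilution fraction.  The
simulated counterpart reruns the single-species model at each dilution
(only the carbon-source bulk concentration is scaled; oxygen is never
diluted) and the free parameter (mu_max or K_Sg) is adjusted by bisection
until the simulated response matches the target.

The objective compares *normalised* slopes — the OLS slope of biovolume
versus dilution fraction divided by the full-strength biovolume — which
makes the fit insensitive to the absolute biovolume unit mismatch between
imaging software and simulation.  Every objective evaluation reuses the
same replicate seeds (common random numbers), so bisection sees a
deterministic function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .domain import SpeciesParams
from .postprocess import biovolume, dilution_regression

__all__ = ["CalibrationTarget", "BisectionResult", "dilution_response",
           "normalized_slope", "bisection_fit", "STANDARD_DILUTIONS"]

#: glucose sweep fractions of the 2 g/L full-strength medium
#: (2, 1.5, 1, 0.5, 0.2, 0.1, 0.02 g/L)
STANDARD_DILUTIONS = (1.0, 0.75, 0.5, 0.25, 0.1, 0.05, 0.01)

#: biologically relevant search ranges, one per tunable parameter
DEFAULT_BRACKETS = {"mu_max": (0.05, 1.0), "K_Sg": (0.01, 5.0)}


@dataclass
class CalibrationTarget:
    """What the simulated dilution response should match.

    Either a table of (dilution, biovolume) measurements — its normalised
    OLS slope is the objective value — or a pre-computed normalised slope.
    """

    table: Optional[pd.DataFrame] = None
    normalized_slope: Optional[float] = None
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.table is None and self.normalized_slope is None:
            raise ValueError("provide a table or a normalised slope")
        if self.table is not None and self.table["dilution"].nunique() < 2:
            raise ValueError("target table needs >= 2 distinct dilutions")

    def target_slope(self) -> float:
        if self.normalized_slope is not None:
            return self.normalized_slope
        return normalized_slope(self.table)


def dilution_response(params: SpeciesParams, dilutions: Sequence[float],
                      base_config: engine.RunConfig,
                      base_seed: int = 0,
                      replicates: int = 1) -> pd.DataFrame:
    """Mean final single-species biofilm biovolume at each medium dilution.

    One replicate batch per dilution; only the species' carbon-source bulk
    concentration is scaled by the dilution fraction.
    """
    if any(not 0 < d <= 1 for d in dilutions):
        raise ValueError("dilutions must lie in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for d in dilutions:
        bulk = dict(base_config.bulk_concentrations)
        full = bulk.get("glucose", engine.DEFAULT_BULK["glucose"])
        bulk["glucose"] = d * full
        bulk["substrate1"] = d * full
        bulk["substrate2"] = d * full
        config = replace(base_config,
                         species=[params],
                         seed_counts={params.name:
                                      base_config.total_seed_cells},
                         bulk_concentrations=bulk,
                         replicates=replicates)
        trajs = engine.run_replicates(config, base_seed=base_seed)
        vols = [biovolume(t.final_state, species=params.name) for t in trajs]
        rows.append({"dilution": float(d),
                     "biovolume_um3": float(np.mean(vols))})
    return pd.DataFrame(rows)


def normalized_slope(table: pd.DataFrame) -> float:
    """OLS slope of biovolume on dilution, divided by the biovolume at the
    highest dilution present (full strength in the standard sweep)."""
    res = dilution_regression(table)
    top = table[table["dilution"] == table["dilution"].max()]
    ref = float(top["biovolume_um3"].mean())
    if ref <= 0:
        raise ValueError("full-strength biovolume must be positive")
    return res.slope / ref


@dataclass
class BisectionResult:
    value: float
    objective: float
    iterations: int
    history: list[tuple[float, float]]


def bisection_fit(param_name: str, bracket: tuple[float, float],
                  target: CalibrationTarget,
                  base_config: engine.RunConfig,
                  species: SpeciesParams,
                  dilutions: Sequence[float] = STANDARD_DILUTIONS,
                  base_seed: int = 0, replicates: int = 1,
                  max_iterations: int = 60,
                  check_monotone: bool = True) -> BisectionResult:
    """Fit one growth parameter by bisection on the normalised-slope
    objective.

    ``objective(theta) = normalised simulated slope - target slope``; the
    bracket must produce a sign change (else an error suggests widening
    it).  Iteration stops when |objective| <= target.tolerance or the
    bracket has shrunk to 1e-3 of its initial width.  Common random
    numbers (fixed ``base_seed``) make the objective deterministic.
    """
    if param_name not in ("mu_max", "K_Sg"):
        raise ValueError("param_name must be 'mu_max' or 'K_Sg'")
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo > hi:
        lo, hi = hi, lo
    target_slope = target.target_slope()
    history: list[tuple[float, float]] = []

    def objective(value: float) -> float:
        p = replace(species, **{param_name: value})
        table = dilution_response(p, dilutions, base_config,
                                  base_seed=base_seed, replicates=replicates)
        obj = normalized_slope(table) - target_slope
        history.append((value, obj))
        return obj

    if lo == hi:
        return BisectionResult(lo, objective(lo), 0, history)

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo == 0:
        return BisectionResult(lo, f_lo, 0, history)
    if f_hi == 0:
        return BisectionResult(hi, f_hi, 0, history)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"objective has no sign change on [{lo}, {hi}] "
            f"(f(lo)={f_lo:.4g}, f(hi)={f_hi:.4g}); widen or move the bracket")

    width0 = hi - lo
    mid = 0.5 * (lo + hi)
    iterations = 0
    first_mid = True
    for _ in range(max_iterations):
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid)
        iterations += 1
        if first_mid and check_monotone:
            # cheap monotonicity sanity check on the three known points
            lo_v, hi_v = sorted([(lo, f_lo), (hi, f_hi)])
            if not (min(lo_v[1], hi_v[1]) - abs(target.tolerance)
                    <= f_mid <= max(lo_v[1], hi_v[1]) + abs(target.tolerance)):
                raise RuntimeError(
                    "objective is not monotone across the bracket "
                    f"(f({lo})={f_lo:.4g}, f({mid})={f_mid:.4g}, "
                    f"f({hi})={f_hi:.4g}); calibration aborted")
            first_mid = False
        if abs(f_mid) <= target.tolerance:
            return BisectionResult(mid, f_mid, iterations, history)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        if (hi - lo) <= 1e-3 * width0:
            break
    mid = 0.5 * (lo + hi)
    return BisectionResult(mid, history[-1][1], iterations, history)
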