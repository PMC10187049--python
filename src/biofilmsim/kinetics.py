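"""Rate laws: dual-substrate Monod growth, noncompetitive inhibition,
biomass/capsule partitioning, and solute consumption/production rates.

Growth follows dX/dt = mu_max * Sg/(K_Sg+Sg) * So/(K_So+So) * X, with the
additional multiplicative factor K_I/(K_I+I) for the inhibited species when
the inhibition mechanism is active.  The inhibitor and surfactant are
produced by L. paracasei in a separate first-order reaction,
rate = yield * k * X, independent of the growth rate.

All functions accept scalars or numpy arrays for the concentration and mass
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .domain import Agent, ModelVariant, SpeciesParams, radius_from_masses

__all__ = [
    "RateBundle",
    "monod_mu",
    "inhibition_factor",
    "effective_mu",
    "carbon_source_name",
    "grow_masses",
    "biomass_step",
    "solute_rates",
]

ArrayLike = Union[float, np.ndarray]


@dataclass
class RateBundle:
    """Per-cell rates: specific growth rate (1/h) and solute mass rates
    (fg/h; consumption negative, production positive)."""

    mu: float
    glucose: float = 0.0
    oxygen: float = 0.0
    inhibitor: float = 0.0
    surfactant: float = 0.0


def monod_mu(params: SpeciesParams, Sg: ArrayLike, So: ArrayLike) -> ArrayLike:
    """Specific growth rate (1/h) from the dual-substrate Monod law."""
    Sg = np.asarray(Sg, dtype=float)
    So = np.asarray(So, dtype=float)
    if np.any(Sg < 0) or np.any(So < 0):
        raise ValueError("substrate concentrations must be non-negative")
    mu = params.mu_max * Sg / (params.K_Sg + Sg) * So / (params.K_So + So)
    return mu if mu.ndim else float(mu)


def inhibition_factor(I: ArrayLike, K_I: float) -> ArrayLike:
    """Noncompetitive growth-reduction factor K_I/(K_I+I), in (0, 1]."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    if K_I <= 0:
        raise ValueError("K_I must be positive")
    f = K_I / (K_I + I)
    return f if f.ndim else float(f)


def carbon_source_name(params: SpeciesParams, variant: ModelVariant,
                       species_order: Optional[list[str]] = None) -> str:
    """Which field a species reads as its carbon source.

    Shared-carbon variants use glucose; the independent-substrates control
    assigns substrate1 to the first species of the run and substrate2 to the
    second (same kinetic constants as glucose).
    """
    if variant.shared_carbon:
        return "glucose"
    if species_order is None:
        raise ValueError("species_order required for independent substrates")
    return f"substrate{species_order.index(params.name) + 1}"


def effective_mu(params: SpeciesParams, solutes: Mapping[str, ArrayLike],
                 variant: ModelVariant,
                 species_order: Optional[list[str]] = None) -> ArrayLike:
    """Growth rate at the given local concentrations under a model variant.

    ``solutes`` maps field name -> local concentration(s).  Equals
    :func:`monod_mu` except that (a) the inhibited species is scaled by the
    inhibition factor when inhibition is active, and (b) under independent
    substrates each species reads its own carbon field.
    """
    carbon = carbon_source_name(params, variant, species_order)
    try:
        Sg = solutes[carbon]
        So = solutes["oxygen"]
    except KeyError as exc:
        raise KeyError(f"missing required solute field: {exc}") from exc
    mu = monod_mu(params, Sg, So)
    if variant.inhibition_active and params.K_I is not None:
        try:
            I = solutes["inhibitor"]
        except KeyError as exc:
            raise KeyError("missing required solute field: inhibitor") from exc
        mu = mu * inhibition_factor(I, params.K_I)
    return mu


def grow_masses(biomass: ArrayLike, capsule: ArrayLike, mu: ArrayLike,
                dt: float, biomass_fraction: float, capsule_fraction: float,
                eps_active: bool = True):
    """Exponential growth over one step with mu frozen at step start.

    New mass Delta = X*(e^(mu dt) - 1) with X the biomass pool; Delta is
    split biomass:capsule per the species fractions, or routed entirely to
    biomass when EPS production is switched off.  Returns
    (new_biomass, new_capsule, delta_total).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    biomass = np.asarray(biomass, dtype=float)
    capsule = np.asarray(capsule, dtype=float)
    delta = biomass * np.expm1(mu * dt)
    if eps_active:
        new_b = biomass + biomass_fraction * delta
        new_c = capsule + capsule_fraction * delta
    else:
        new_b = biomass + delta
        new_c = capsule
    return new_b, new_c, delta


def biomass_step(agent: Agent, mu: float, dt: float,
                 eps_active: bool = True) -> Agent:
    """Grow one agent in place for ``dt`` hours; radius is recomputed."""
    sp = agent.species
    new_b, new_c, _ = grow_masses(agent.biomass_fg, agent.capsule_fg, mu, dt,
                                  sp.biomass_fraction, sp.capsule_fraction,
                                  eps_active)
    agent.biomass_fg = float(new_b)
    agent.capsule_fg = float(new_c)
    return agent


def solute_rates(agent: Agent, mu: float, params: SpeciesParams,
                 variant: ModelVariant = ModelVariant.COMPETITION) -> RateBundle:
    """Per-cell solute mass rates (fg/h) at growth rate ``mu``.

    Nutrient consumption is growth-coupled (yield * mu * X, negative);
    inhibitor/surfactant production is first-order in producer biomass
    (yield * k * X) whenever the species produces them and the variant
    activates the corresponding mechanism.  To inject into a field, divide
    by the voxel volume (fg/um^3/h == g/L/h).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    X = agent.biomass_fg
    bundle = RateBundle(mu=mu,
                        glucose=params.yield_glucose * mu * X,
                        oxygen=params.yield_oxygen * mu * X)
    k = params.production_rate_k
    if k is not None:
        if variant.inhibition_active and params.yield_inhibitor is not None:
            bundle.inhibitor = params.yield_inhibitor * k * X
        if variant.surfactant_active and params.yield_surfactant is not None:
            bundle.surfactant = params.yield_surfactant * k * X
    return bundle
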