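"""Default species parameterisations for the two oral isolates.

The constants are the calibrated growth parameters of the Streptococcus
oralis strain So34 and the Lactobacillus paracasei strain LB334: maximum
specific growth rates and glucose half-saturations fitted so that simulated
biofilm biovolume declines with medium dilution as observed in vitro, oxygen
half-saturations from the literature, and the inhibitor/surfactant
production kinetics of L. paracasei (first-order in producer biomass,
k = 0.7 /h, product yields 0.3 and 0.4 g/g).
"""

from __future__ import annotations

from .domain import SpeciesParams

__all__ = [
    "streptococcus_oralis",
    "lactobacillus_paracasei",
    "default_species",
    "BULK_GLUCOSE",
    "BULK_OXYGEN",
    "GLUCOSE_DIFFUSIVITY",
    "OXYGEN_DIFFUSIVITY",
]

#: full-strength medium glucose, g/L
BULK_GLUCOSE = 2.0
#: dissolved oxygen, g/L (never diluted)
BULK_OXYGEN = 0.0064

#: um^2/h; the secreted products default to the glucose value
GLUCOSE_DIFFUSIVITY = 2.1e4
OXYGEN_DIFFUSIVITY = 7.2e4


def streptococcus_oralis(**overrides) -> SpeciesParams:
    """S. oralis So34: faster-growing, inhibitor-sensitive, lower surfactant
    tolerance (0.005 g/L)."""
    kw = dict(
        name="so34",
        mu_max=0.32,
        K_Sg=1.756,
        K_So=0.192e-3,
        K_I=0.0025,
        yield_glucose=-3.0,
        yield_oxygen=-2.0,
        biomass_fraction=0.8,
        capsule_fraction=0.2,
        surfactant_tolerance=0.005,
    )
    kw.update(overrides)
    return SpeciesParams(**kw)


def lactobacillus_paracasei(**overrides) -> SpeciesParams:
    """L. paracasei LB334: slower-growing producer of the inhibitor
    (yield 0.3 g/g) and surfactant (yield 0.4 g/g), tolerance 0.008 g/L."""
    kw = dict(
        name="lb334",
        mu_max=0.153,
        K_Sg=1.2,
        K_So=0.2e-3,
        yield_glucose=-0.17,
        yield_oxygen=-1.0,
        biomass_fraction=0.9,
        capsule_fraction=0.1,
        production_rate_k=0.7,
        yield_inhibitor=0.3,
        yield_surfactant=0.4,
        surfactant_tolerance=0.008,
    )
    kw.update(overrides)
    return SpeciesParams(**kw)


def default_species() -> list[SpeciesParams]:
    return [streptococcus_oralis(), lactobacillus_paracasei()]
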