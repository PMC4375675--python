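"""Physiological parameter set for the *Eisenia fetida* energy budget.

The defaults are the literature-derived constants for *E. fetida*: metabolic
normalisation and activation energy for the Arrhenius temperature response,
energetic contents and synthesis costs of tissue and food, ingestion and
allocation rate maxima, and the life-history masses (birth, maturity,
asymptote) and incubation period that delimit the life cycle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

#: Boltzmann's constant in eV/K, as used in metabolic scaling theory.
K_BOLTZMANN = 8.62e-5


@dataclass(frozen=True)
class EnergyBudgetParams:
    """Constants of the individual energy budget.

    Attributes
    ----------
    Ae : float
        Assimilation efficiency (dimensionless fraction of ingested energy).
    B0 : float
        Taxon-specific metabolic normalisation constant (kJ/day).
    E : float
        Activation energy of the Arrhenius response (eV).
    k_B : float
        Boltzmann's constant (eV/K).
    Ec : float
        Energy content of tissue and of stored reserve (kJ/g).
    Es : float
        Energy cost of synthesising 1 g of tissue (kJ/g).
    Ex : float
        Energy content of food (kJ/g).
    IGmax : float
        Maximum ingestion rate of a 1-g worm under optimal food (g/day/g);
        scales with surface area M^(2/3).
    h : float
        Half-saturation food density of the type II functional response
        (g per 0.01 m^2 patch).
    Mb : float
        Mass at birth (g).
    Mc : float
        Mass of a cocoon (g).
    Mp : float
        Mass at sexual maturity (g).
    Mm : float
        Maximum (asymptotic) mass (g).
    rB : float
        von Bertalanffy growth constant (1/day).
    T0 : float
        Cocoon incubation period at the reference temperature (days).
    rm : float
        Maximum rate of energy allocation to reproduction (kJ/g/day).
    Tref : float
        Reference temperature (K).
    """

    Ae: float = 0.50
    B0: float = 967.0
    E: float = 0.25
    k_B: float = K_BOLTZMANN
    Ec: float = 7.0
    Es: float = 3.6
    Ex: float = 21.2
    IGmax: float = 0.70
    h: float = 3.5
    Mb: float = 0.011
    Mc: float = 0.015
    Mp: float = 0.25
    Mm: float = 0.50
    rB: float = 0.177
    rm: float = 0.182
    T0: float = 23.0
    Tref: float = 298.15

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if self.Ae > 1:
            raise ValueError(f"assimilation efficiency Ae must be <= 1, got {self.Ae}")
        if not (self.Mb < self.Mp < self.Mm):
            raise ValueError(
                f"life-history masses must satisfy Mb < Mp < Mm, "
                f"got Mb={self.Mb}, Mp={self.Mp}, Mm={self.Mm}"
            )

    def replace(self, **changes: float) -> "EnergyBudgetParams":
        """Return a copy with the given parameters replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "EnergyBudgetParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown energy-budget parameters: {sorted(unknown)}")
        return cls(**d)


#: Names of the tunable physiological parameters (excludes the physical
#: constant k_B), in the conventional presentation order.
PARAMETER_NAMES = (
    "Ae", "B0", "E", "Ec", "Es", "Ex", "IGmax", "h",
    "Mb", "Mc", "Mp", "Mm", "rB", "rm", "T0", "Tref",
)
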