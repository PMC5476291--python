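"""Reduced kinetic model: stoichiometric matrix, rate laws and parameters.

The reduced model couples five macroscopic bioreactions over 14 species:

* MR1 — acetate assimilation to succinate (Michaelis–Menten in acetate);
* MR2 — butyrate assimilation to succinate (Haldane substrate inhibition
  with an optimum concentration, multiplied by a diauxic repression factor
  ``k_D/(ACE + k_D)`` so that even traces of acetate shut butyrate uptake
  down);
* MR3 — photosynthesis: CO2 fixation to glyceraldehyde 3-phosphate (GAP),
  with a Beer–Lambert depth-averaged light factor ``(1 - exp(-beta*B))/
  (beta*B)`` — self-shading by biomass reduces the mean light available;
* MR4 — functional biomass synthesis from succinate (first order);
* MR5 — functional biomass synthesis from GAP (first order).

All rates are specific rates (per mol of functional biomass); the state
equation is ``dM/dt = K' · alpha(M) · B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .efm import MacroscopicReaction

M_CARBON = 12.011  # g/mol

#: mol carbon per mol for the carbon-carrying species of the reduced model
CARBON_ATOMS = {
    "ACE": 2.0,
    "BUTYR": 4.0,
    "SUC": 4.0,
    "GAP": 3.0,
    "CO2": 1.0,
    "B": 8.52139,  # lumped functional-biomass pseudo-species
}

#: canonical row order of the reduced stoichiometric matrix
SPECIES_ORDER = [
    "ACE", "BUTYR", "SUC", "GAP", "B",
    "CO2", "O2", "H2O", "H", "Pi", "NH4", "SO4", "Mg", "Light",
]

MOLAR_MASSES = {"SUC": 118.09, "GAP": 170.06, "B": 186.0}

INCIDENT_LIGHT_REF = 136.0  # µE m^-2 s^-1


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class KineticParameters:
    """The ten calibrated kinetic parameters of the reduced model.

    Units: rate constants k_mr1/k_mr2/gamma_mr3 in mol L^-1 h^-1 per mol
    biomass; Ks_mr1, Sopt_mr2, k_D in mol L^-1; beta_mr2 in h^-1 per mol
    biomass; beta_mr3 in (mol biomass)^-1 L; k_mr4, k_mr5 in h^-1 per mol
    biomass.
    """

    k_mr1: float = 3.79e-1
    Ks_mr1: float = 5.52e-5
    k_mr2: float = 3.61e-2
    beta_mr2: float = 2.58e5
    Sopt_mr2: float = 1.93e-5
    k_D: float = 5.39e-10
    gamma_mr3: float = 2.62e-1
    beta_mr3: float = 2.48e3
    k_mr4: float = 2.37e5
    k_mr5: float = 2.83e1

    NAMES = (
        "k_mr1", "Ks_mr1", "k_mr2", "beta_mr2", "Sopt_mr2",
        "k_D", "gamma_mr3", "beta_mr3", "k_mr4", "k_mr5",
    )

    def __post_init__(self) -> None:
        for name in self.NAMES:
            if getattr(self, name) <= 0:
                raise KineticsError(f"parameter {name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES])

    @classmethod
    def from_array(cls, values) -> "KineticParameters":
        return cls(**dict(zip(cls.NAMES, map(float, values))))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in self.NAMES}


#: calibrated reference parameter set of the model
TABLE_PARAMS = KineticParameters()


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def _require_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise KineticsError(f"{name} must be non-negative, got {value}")


def rate_mr1(ACE: float, p: KineticParameters) -> float:
    """Michaelis–Menten acetate uptake, bounded by k_mr1."""
    _require_nonnegative(ACE=ACE)
    return p.k_mr1 * ACE / (p.Ks_mr1 + ACE)


def rate_mr2(BUTYR: float, ACE: float, p: KineticParameters) -> float:
    """Haldane butyrate uptake with diauxic repression by acetate.

    The Haldane denominator ``BUTYR + (k_mr2/beta_mr2)(BUTYR/Sopt - 1)^2``
    gives the maximal rate k_mr2 exactly at BUTYR = Sopt and vanishing
    uptake at high butyrate (substrate inhibition).  The factor
    ``k_D/(ACE + k_D)`` represses uptake while acetate remains.
    """
    _require_nonnegative(BUTYR=BUTYR, ACE=ACE)
    if BUTYR == 0:
        return 0.0
    denom = BUTYR + (p.k_mr2 / p.beta_mr2) * (BUTYR / p.Sopt_mr2 - 1.0) ** 2
    return p.k_mr2 * BUTYR / denom * (p.k_D / (ACE + p.k_D))


def light_fraction(x: float) -> float:
    """Beer–Lambert depth average (1 - exp(-x))/x, continuous limit 1 at 0."""
    if x < 0:
        raise KineticsError("attenuation argument must be non-negative")
    if x < 1e-12:
        return 1.0
    return -math.expm1(-x) / x


def rate_mr3(
    B: float,
    incident_light: float,
    p: KineticParameters,
    incident_light_ref: float = INCIDENT_LIGHT_REF,
) -> float:
    """Photosynthesis rate: linear in depth-averaged light.

    gamma_mr3 is the specific rate at the reference incident intensity;
    other intensities scale the rate linearly.  Self-shading enters through
    the average-light factor (1 - exp(-beta_mr3 * B)) / (beta_mr3 * B).
    """
    _require_nonnegative(B=B, incident_light=incident_light)
    if incident_light == 0:
        return 0.0
    return (
        p.gamma_mr3
        * (incident_light / incident_light_ref)
        * light_fraction(p.beta_mr3 * B)
    )


def rate_mr4(SUC: float, p: KineticParameters) -> float:
    """First-order biomass synthesis from succinate."""
    _require_nonnegative(SUC=SUC)
    return p.k_mr4 * SUC


def rate_mr5(GAP: float, p: KineticParameters) -> float:
    """First-order biomass synthesis from GAP."""
    _require_nonnegative(GAP=GAP)
    return p.k_mr5 * GAP


#: kinetic-law registry: law id -> (species needed, evaluator)
_KINETIC_LAWS = {
    "mr1": lambda s, p, I: rate_mr1(s.get("ACE", 0.0), p),
    "mr2": lambda s, p, I: rate_mr2(s.get("BUTYR", 0.0), s.get("ACE", 0.0), p),
    "mr3": lambda s, p, I: rate_mr3(s.get("B", 0.0), I, p),
    "mr4": lambda s, p, I: rate_mr4(s.get("SUC", 0.0), p),
    "mr5": lambda s, p, I: rate_mr5(s.get("GAP", 0.0), p),
}


# ---------------------------------------------------------------------------
# Reduced model container
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    """The reduced stoichiometric model: species, K matrix, kinetic laws.

    ``K`` has one row per species and one column per macroscopic reaction;
    ``kinetic_law_ids`` binds each column to a registered rate law.  The
    light row is cumulative photon consumption (bookkeeping only; photons
    never limit the rates).  ``molar_masses`` provides the masses for the
    total-biomass mass balance X(t) = sum_A M_A A(t) + M_B B(t).
    """

    species: list[str]
    K: np.ndarray
    mrs: list[MacroscopicReaction]
    kinetic_law_ids: list[str]
    molar_masses: dict[str, float] = field(default_factory=lambda: dict(MOLAR_MASSES))
    incident_light_ref: float = INCIDENT_LIGHT_REF

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.species), len(self.kinetic_law_ids)):
            raise KineticsError(
                f"K shape {self.K.shape} inconsistent with "
                f"{len(self.species)} species x {len(self.kinetic_law_ids)} reactions"
            )
        unknown = set(self.kinetic_law_ids) - set(_KINETIC_LAWS)
        if unknown:
            raise KineticsError(f"unknown kinetic laws: {sorted(unknown)}")
        self._index = {s: i for i, s in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.kinetic_law_ids)

    def index(self, species: str) -> int:
        return self._index[species]

    def has_species(self, species: str) -> bool:
        return species in self._index

    def state_dict(self, state: np.ndarray) -> dict[str, float]:
        return {s: float(state[i]) for s, i in self._index.items()}

    def rates(
        self,
        state: np.ndarray,
        p: KineticParameters,
        incident_light: float,
    ) -> np.ndarray:
        """Specific macroscopic rates alpha (per mol biomass) at a state.

        Negative concentration excursions from the integrator are clipped
        to zero for rate evaluation.
        """
        values = {
            s: max(float(state[i]), 0.0) for s, i in self._index.items()
        }
        return np.array([
            _KINETIC_LAWS[law](values, p, incident_light)
            for law in self.kinetic_law_ids
        ])

    def total_biomass(self, state: np.ndarray) -> float:
        """Total biomass X (g/L): accumulating metabolites plus functional
        biomass, weighted by molar mass."""
        X = 0.0
        for species, mass in self.molar_masses.items():
            if species in self._index:
                X += mass * max(float(state[self._index[species]]), 0.0)
        return X

    def carbon_vector(self) -> np.ndarray:
        return np.array([CARBON_ATOMS.get(s, 0.0) for s in self.species])

    def to_frame(self) -> pd.DataFrame:
        """The reduced stoichiometric matrix as a labelled table."""
        return pd.DataFrame(
            self.K, index=self.species,
            columns=[mr.id for mr in self.mrs],
        )

    def n_parameters(self) -> int:
        return len(KineticParameters.NAMES)


def build_reduced_model(
    mrs: list[MacroscopicReaction],
    p: KineticParameters | None = None,
    species_order: list[str] | None = None,
) -> ReducedModel:
    """Assemble the reduced model from five macroscopic reactions.

    The five reactions must jointly touch exactly 14 distinct species; rows
    follow the canonical species order, columns the order MR1..MR5 given.
    """
    touched: set[str] = set()
    for mr in mrs:
        touched |= set(mr.net_stoichiometry)
    order = species_order or SPECIES_ORDER
    if species_order is None and len(touched) != 14:
        raise KineticsError(
            f"expected 14 distinct species across the macroscopic reactions, "
            f"got {len(touched)}: {sorted(touched)}"
        )
    missing = touched - set(order)
    if missing:
        raise KineticsError(f"species missing from row order: {sorted(missing)}")
    K = np.zeros((len(order), len(mrs)))
    law_ids = []
    for j, mr in enumerate(mrs):
        for met, coef in mr.net_stoichiometry.items():
            K[order.index(met), j] = coef
        law_ids.append(mr.kinetic_law_id or mr.id.lower())
    return ReducedModel(species=list(order), K=K, mrs=mrs, kinetic_law_ids=law_ids)


# ---------------------------------------------------------------------------
# Reference (printed-table) instance
# ---------------------------------------------------------------------------

#: net stoichiometries of the five reference macroscopic reactions
TABLE_MR_STOICHIOMETRY = {
    "MR1": {"H": -3.5, "ACE": -2.0, "O2": -0.5, "SUC": 1.0, "H2O": 1.5},
    "MR2": {"H": -7.0, "O2": -1.5, "BUTYR": -1.0, "SUC": 1.0, "H2O": 5.0},
    "MR3": {"Light": -24.0, "CO2": -3.0, "H2O": -2.0, "Pi": -1.0,
            "GAP": 1.0, "O2": 3.0},
    "MR4": {"H": -7.30239, "O2": -4.61237, "SUC": -4.14597,
            "NH4": -0.984915, "Pi": -0.1216, "SO4": -0.02169, "Mg": -0.0101,
            "B": 1.0, "H2O": 7.04167, "CO2": 8.06249},
    "MR5": {"GAP": -4.14597, "O2": -2.53938, "NH4": -0.984916,
            "SO4": -0.02169, "Mg": -0.0101,
            "H": 0.989545, "B": 1.0, "H2O": 2.8957, "CO2": 3.91652,
            "Pi": 4.02437},
}


def table_macroreactions() -> list[MacroscopicReaction]:
    """The five reference macroscopic reactions with bound kinetic laws."""
    return [
        MacroscopicReaction(
            id=mr_id,
            net_stoichiometry=dict(stoich),
            kinetic_law_id=mr_id.lower(),
        )
        for mr_id, stoich in TABLE_MR_STOICHIOMETRY.items()
    ]


def reference_model() -> ReducedModel:
    """The 14-species x 5-reaction reference model."""
    return build_reduced_model(table_macroreactions())


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def convert_units(value: float, from_unit: str, to_unit: str, species: str) -> float:
    """Convert between field units and molar concentrations.

    Supported: ``gC/L`` <-> ``M`` for carbon-counted substrates (ACE,
    BUTYR, SUC, GAP, CO2) and ``g/L`` <-> ``M`` for biomass (B).
    """
    pair = (from_unit, to_unit)
    if pair == ("gC/L", "M"):
        if species not in CARBON_ATOMS:
            raise KineticsError(f"no carbon count for species {species!r}")
        return value / (CARBON_ATOMS[species] * M_CARBON)
    if pair == ("M", "gC/L"):
        if species not in CARBON_ATOMS:
            raise KineticsError(f"no carbon count for species {species!r}")
        return value * CARBON_ATOMS[species] * M_CARBON
    if pair == ("g/L", "M"):
        if species not in MOLAR_MASSES:
            raise KineticsError(f"no molar mass for species {species!r}")
        return value / MOLAR_MASSES[species]
    if pair == ("M", "g/L"):
        if species not in MOLAR_MASSES:
            raise KineticsError(f"no molar mass for species {species!r}")
        return value * MOLAR_MASSES[species]
    raise KineticsError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")
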