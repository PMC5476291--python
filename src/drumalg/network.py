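"""Metabolic network data model, SBML input/output and sub-network splitting.

A :class:`MetabolicNetwork` is a plain stoichiometric description of a core
carbon network: metabolites (with optional elemental compositions and a
functional role), reactions (signed stoichiometries, reversibility, a
sub-network tag) and a growth-associated maintenance (GAM) value attached to
the biomass reaction.  Networks are split into sub-networks for dynamic
reduction: each sub-network declares which metabolites are *exchange*
metabolites (allowed to accumulate or deplete) while all remaining touched
metabolites are constrained to quasi-steady state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COMPARTMENTS = ("cytosol", "chloroplast", "glyoxysome", "extracellular")
ROLES = (
    "substrate_S",
    "accumulating_A",
    "functional_biomass_B",
    "internal_QSS",
    "external_bookkeeping",
)
ELEMENTS = ("C", "H", "O", "N", "P", "S", "Mg")


class NetworkError(ValueError):
    """Structural problem in a metabolic network or an SBML document."""


@dataclass
class Metabolite:
    """A chemical species of the network.

    ``composition`` maps element symbols to (possibly fractional) atom
    counts; lumped pseudo-species such as functional biomass carry
    non-integer formulas.  ``role`` distinguishes external substrates (S),
    accumulating interface metabolites (A), functional biomass (B),
    quasi-steady-state internals and bookkeeping species.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    composition: dict[str, float] | None = None
    role: str = "external_bookkeeping"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if self.role not in ROLES:
            raise NetworkError(f"unknown metabolite role {self.role!r}")
        if self.composition is not None:
            for el, count in self.composition.items():
                if count < 0:
                    raise NetworkError(
                        f"negative {el} count in composition of {self.id!r}"
                    )

    def carbon(self) -> float | None:
        if self.composition is None:
            return None
        return float(self.composition.get("C", 0.0))


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    subnetwork_tag: str = "none"

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise NetworkError(
                    f"reaction {self.id!r} stores a zero coefficient for {met!r}"
                )

    def equation(self) -> str:
        """Human-readable equation string, Table-style formatting."""
        lhs, rhs = [], []
        for met, coef in self.stoichiometry.items():
            part = met if abs(abs(coef) - 1.0) < 1e-12 else f"{abs(coef):g} {met}"
            (lhs if coef < 0 else rhs).append(part)
        arrow = "<=>" if self.reversible else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


@dataclass
class MetabolicNetwork:
    """A stoichiometric network plus the GAM maintenance bookkeeping."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    gam_mol_atp_per_mol_biomass: float = 0.0

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise NetworkError(
                    f"reaction {rxn.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
        if self.gam_mol_atp_per_mol_biomass < 0:
            raise NetworkError("GAM must be non-negative")

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def compositions(self) -> dict[str, dict[str, float]]:
        return {m.id: m.composition for m in self.metabolites
                if m.composition is not None}

    # -- matrices --------------------------------------------------------
    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Full stoichiometric matrix, metabolites x reactions."""
        S = pd.DataFrame(
            0.0, index=self.metabolite_ids, columns=self.reaction_ids
        )
        for rxn in self.reactions:
            for met, coef in rxn.stoichiometry.items():
                S.loc[met, rxn.id] = coef
        return S

    def to_table(self) -> pd.DataFrame:
        """One row per reaction: id, equation, reversible, tag."""
        return pd.DataFrame(
            {
                "id": [r.id for r in self.reactions],
                "equation": [r.equation() for r in self.reactions],
                "reversible": [r.reversible for r in self.reactions],
                "tag": [r.subnetwork_tag for r in self.reactions],
            }
        )

    def copy(self) -> "MetabolicNetwork":
        return copy.deepcopy(self)


@dataclass
class SubNetwork:
    """A reaction subset with declared exchange and internal metabolites.

    Exchange metabolites may have nonzero net production or consumption;
    internal metabolites are constrained to quasi-steady state during
    elementary-mode reduction.  The two sets are disjoint and jointly cover
    every metabolite touched by the sub-network's reactions.
    """

    parent: MetabolicNetwork
    tag: str
    reaction_ids: list[str]
    exchange_metabolites: list[str]
    internal_metabolites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        touched = self.touched_metabolites()
        exchange = set(self.exchange_metabolites)
        if not self.internal_metabolites:
            self.internal_metabolites = touched - exchange
        overlap = exchange & self.internal_metabolites
        if overlap:
            raise NetworkError(
                f"sub-network {self.tag!r}: metabolites both exchange and "
                f"internal: {sorted(overlap)}"
            )
        uncovered = touched - exchange - self.internal_metabolites
        if uncovered:
            raise NetworkError(
                f"sub-network {self.tag!r}: touched metabolites not declared "
                f"exchange or internal: {sorted(uncovered)}"
            )

    def touched_metabolites(self) -> set[str]:
        touched: set[str] = set()
        for rid in self.reaction_ids:
            touched |= set(self.parent.reaction(rid).stoichiometry)
        return touched

    def reactions(self) -> list[Reaction]:
        return [self.parent.reaction(rid) for rid in self.reaction_ids]

    def stoichiometric_matrix(self, internal_only: bool = False) -> pd.DataFrame:
        S = self.parent.stoichiometric_matrix()[self.reaction_ids]
        if internal_only:
            rows = sorted(self.internal_metabolites)
        else:
            rows = sorted(self.touched_metabolites())
        return S.loc[rows]


# ---------------------------------------------------------------------------
# SBML input / output
# ---------------------------------------------------------------------------

_COMPOSITION_PREFIX = "COMPOSITION:"
_ROLE_PREFIX = "ROLE:"


def _format_notes(met: Metabolite) -> str:
    lines = []
    if met.composition is not None:
        comp = ";".join(f"{el}:{count:g}" for el, count in met.composition.items())
        lines.append(f"<p>{_COMPOSITION_PREFIX} {comp}</p>")
    lines.append(f"<p>{_ROLE_PREFIX} {met.role}</p>")
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(lines) + "</body>"
    )


def _parse_notes(notes: str) -> tuple[dict[str, float] | None, str | None]:
    composition = None
    role = None
    for raw in notes.replace("</p>", "\n").splitlines():
        line = raw
        while "<" in line and ">" in line:  # strip xhtml tags
            start = line.index("<")
            end = line.index(">", start)
            line = line[:start] + line[end + 1:]
        line = line.strip()
        if line.startswith(_COMPOSITION_PREFIX):
            composition = {}
            for token in line[len(_COMPOSITION_PREFIX):].strip().split(";"):
                if not token:
                    continue
                el, _, count = token.partition(":")
                composition[el.strip()] = float(count)
        elif line.startswith(_ROLE_PREFIX):
            candidate = line[len(_ROLE_PREFIX):].strip()
            if candidate in ROLES:
                role = candidate
    return composition, role


def read_sbml(path) -> MetabolicNetwork:
    """Read a metabolic network from an SBML file (level 2 or 3).

    Reversibility is taken from the SBML ``reversible`` flag; compartments
    from the species' compartment attribute; elemental compositions and
    metabolite roles from species notes when present (``COMPOSITION:`` /
    ``ROLE:`` lines), else left absent.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise NetworkError(
            f"SBML parse failure in {path}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkError(f"SBML file {path} contains no model")
    if model.getNumReactions() == 0:
        raise NetworkError(f"SBML model in {path} has no reactions")

    metabolites = []
    for sp in model.getListOfSpecies():
        composition, role = (None, None)
        if sp.isSetNotes():
            composition, role = _parse_notes(
                libsbml.XMLNode.convertXMLNodeToString(sp.getNotes())
            )
        compartment = sp.getCompartment() or "cytosol"
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=compartment,
                composition=composition,
                role=role or "external_bookkeeping",
            )
        )

    reactions = []
    for rxn in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise NetworkError(
                f"reaction {rxn.getId()!r} has empty or cancelling stoichiometry"
            )
        tag = "none"
        if rxn.isSetNotes():
            notes = libsbml.XMLNode.convertXMLNodeToString(rxn.getNotes())
            for line in notes.splitlines():
                if "SUBNETWORK:" in line:
                    candidate = line.split("SUBNETWORK:", 1)[1]
                    while "<" in candidate and ">" in candidate:
                        start = candidate.index("<")
                        candidate = candidate[:start] + candidate[candidate.index(">", start) + 1:]
                    tag = candidate.strip()
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                reversible=bool(rxn.getReversible()),
                subnetwork_tag=tag,
            )
        )

    return MetabolicNetwork(metabolites=metabolites, reactions=reactions)


def write_sbml(network: MetabolicNetwork, path) -> None:
    """Write the network as SBML level 3 version 1."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel("network")
    compartments = {m.compartment for m in network.metabolites}
    for comp in sorted(compartments):
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for met in network.metabolites:
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setNotes(_format_notes(met), True)
    for rxn in network.reactions:
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        rx.setNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>SUBNETWORK: {rxn.subnetwork_tag}</p></body>",
            True,
        )
        for met, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Element balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    """Per-reaction, per-element net imbalances.

    ``imbalances`` lists every (reaction, element) pair whose absolute net
    imbalance exceeds the tolerance; ``unchecked`` lists reactions touching
    at least one composition-free metabolite (those reactions cannot be
    audited and are reported rather than failed).
    """

    imbalances: pd.DataFrame
    unchecked: list[str]
    tolerance: float

    def is_balanced(self, element: str | None = None) -> bool:
        if self.imbalances.empty:
            return True
        if element is None:
            return False
        return not (self.imbalances["element"] == element).any()


def check_element_balance(
    network: MetabolicNetwork,
    elements: tuple[str, ...] = ELEMENTS,
    tolerance: float = 1e-6,
) -> BalanceReport:
    """Audit elemental conservation of every reaction.

    Only metabolites with known compositions contribute; a reaction touching
    any composition-free metabolite is reported as unchecked.  Elements a
    reaction's metabolites do not declare count as zero.
    """
    compositions = network.compositions()
    rows = []
    unchecked = []
    for rxn in network.reactions:
        missing = [m for m in rxn.stoichiometry if m not in compositions]
        if missing:
            unchecked.append(rxn.id)
            continue
        for el in elements:
            net = sum(
                coef * compositions[met].get(el, 0.0)
                for met, coef in rxn.stoichiometry.items()
            )
            if abs(net) > tolerance:
                rows.append({"reaction": rxn.id, "element": el, "imbalance": net})
    frame = pd.DataFrame(rows, columns=["reaction", "element", "imbalance"])
    return BalanceReport(imbalances=frame, unchecked=unchecked, tolerance=tolerance)


# ---------------------------------------------------------------------------
# Sub-network splitting
# ---------------------------------------------------------------------------

def split_subnetworks(
    network: MetabolicNetwork,
    assignment: dict[str, str],
    exchange_declaration: dict[str, list[str]],
) -> list[SubNetwork]:
    """Split the network into sub-networks according to a reaction tagging.

    Every reaction must be assigned exactly one tag; each tag's exchange
    metabolites are declared explicitly and the internal (quasi-steady-state)
    set of each sub-network is computed as touched-minus-exchange.
    """
    unassigned = set(network.reaction_ids) - set(assignment)
    if unassigned:
        raise NetworkError(f"unassigned reactions: {sorted(unassigned)}")
    unknown = set(assignment) - set(network.reaction_ids)
    if unknown:
        raise NetworkError(f"assignment references unknown reactions: {sorted(unknown)}")
    known_mets = set(network.metabolite_ids)
    for tag, mets in exchange_declaration.items():
        missing = set(mets) - known_mets
        if missing:
            raise NetworkError(
                f"exchange declaration for {tag!r} references unknown "
                f"metabolites: {sorted(missing)}"
            )

    tags = sorted(set(assignment.values()))
    subnetworks = []
    for tag in tags:
        rids = [rid for rid in network.reaction_ids if assignment[rid] == tag]
        subnetworks.append(
            SubNetwork(
                parent=network,
                tag=tag,
                reaction_ids=rids,
                exchange_metabolites=list(exchange_declaration.get(tag, [])),
            )
        )
    return subnetworks


# ---------------------------------------------------------------------------
# Growth-associated maintenance
# ---------------------------------------------------------------------------

def gam_from_specific_maintenance(
    mol_atp_per_gram_biomass: float, biomass_molar_mass: float
) -> float:
    """Convert a per-mass maintenance measurement to mol ATP per mol biomass.

    Experimental growth-associated maintenance is typically reported per
    gram of dry biomass; the network's biomass reaction works per mole of
    the lumped biomass species.
    """
    if mol_atp_per_gram_biomass < 0 or biomass_molar_mass <= 0:
        raise NetworkError("maintenance and molar mass must be positive")
    return mol_atp_per_gram_biomass * biomass_molar_mass

def find_biomass_reaction(network: MetabolicNetwork) -> Reaction:
    """The reaction producing the functional-biomass metabolite and
    consuming ATP."""
    biomass_ids = [
        m.id for m in network.metabolites if m.role == "functional_biomass_B"
    ]
    if not biomass_ids:
        raise NetworkError("network declares no functional-biomass metabolite")
    biomass_id = biomass_ids[0]
    for rxn in network.reactions:
        if rxn.stoichiometry.get(biomass_id, 0.0) > 0 and any(
            met.startswith("ATP") and coef < 0
            for met, coef in rxn.stoichiometry.items()
        ):
            return rxn
    raise NetworkError("no biomass reaction consuming ATP found")


def apply_gam(network: MetabolicNetwork, gam: float) -> MetabolicNetwork:
    """Return a copy with the growth-associated ATP maintenance set to ``gam``.

    The biomass reaction's ATP consumption is the sum of a fixed synthesis
    cost and the maintenance term; ADP and Pi release is adjusted in lock
    step so the reaction stays phosphate- and adenylate-coupled.  All other
    reactions are untouched.
    """
    if gam < 0:
        raise NetworkError("GAM must be non-negative")
    new = network.copy()
    rxn = find_biomass_reaction(new)
    atp_id = next(
        met for met, coef in rxn.stoichiometry.items()
        if met.startswith("ATP") and coef < 0
    )
    per_biomass = rxn.stoichiometry[
        next(m.id for m in new.metabolites if m.role == "functional_biomass_B")
    ]
    old_total = -rxn.stoichiometry[atp_id] / per_biomass
    synthesis_cost = old_total - network.gam_mol_atp_per_mol_biomass
    if synthesis_cost < -1e-9:
        raise NetworkError(
            "biomass ATP coefficient smaller than the recorded GAM"
        )
    new_total = max(synthesis_cost, 0.0) + gam
    delta = (new_total - old_total) * per_biomass
    stoich = dict(rxn.stoichiometry)
    stoich[atp_id] = stoich[atp_id] - delta
    adp_id = atp_id.replace("ATP", "ADP")
    for coupled in (adp_id, "Pi"):
        if coupled in stoich:
            stoich[coupled] = stoich[coupled] + delta
    stoich = {m: c for m, c in stoich.items() if c != 0}
    idx = new.reaction_ids.index(rxn.id)
    new.reactions[idx] = replace(rxn, stoichiometry=stoich)
    new.gam_mol_atp_per_mol_biomass = gam
    return new
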