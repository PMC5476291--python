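"""Programmatic example networks (synthetic).

``core_network()`` builds a *synthetic* lumped core carbon network for a
mixotrophic microalga: a glyoxysome sub-network assimilating acetate and
butyrate to succinate through the glyoxylate cycle, a chloroplast
photosynthesis sub-network fixing CO2 to glyceraldehyde 3-phosphate, and a
functional-biomass synthesis sub-network with anabolic and respiratory
routes coupled through an internal ATP pool.  It is constructed so that the
dynamic-reduction pipeline (split -> elementary flux modes -> yield-optimal
mode selection) reproduces the five reference macroscopic reactions MR1-MR5
exactly, while still exhibiting the qualitative features of the full-size
network: multiple biomass-yielding modes per substrate, mixed-substrate
modes, futile cycles and a tunable growth-associated maintenance (GAM).

This stand-in is NOT the full-size 172-reaction core network (which is not
redistributable here); it is a minimal synthetic network with the same
reduction behaviour, shipped so the complete pipeline is testable offline.
"""

from __future__ import annotations

from .network import Metabolite, MetabolicNetwork, Reaction, split_subnetworks
from .efm import (
    classify_modes,
    derive_macroscopic_reaction,
    enumerate_efms,
    select_best_yield,
    MacroscopicReaction,
)

#: carbon content of functional biomass implied by the reference
#: biosynthesis stoichiometry (mol C per mol biomass)
BIOMASS_CARBON = 8.52139

DEFAULT_GAM = 5.56  # mol ATP per mol biomass (growth-associated maintenance)

# biomass-synthesis bookkeeping: split of the reference SUC route into an
# anabolic branch (carbon into biomass) and a respiratory branch (carbon to
# CO2, regenerating ATP)
_SUC_ANABOLIC = BIOMASS_CARBON / 4.0            # mol SUC -> 1 mol precursor
_SUC_RESPIRED = 4.14597 - _SUC_ANABOLIC          # mol SUC fully oxidized
_ATP_PER_SUC = 12.0                              # mol ATP per mol SUC respired
_ATP_PER_BIOMASS = _ATP_PER_SUC * _SUC_RESPIRED  # total ATP demand at ref GAM
_SYNTHESIS_ATP = _ATP_PER_BIOMASS - DEFAULT_GAM  # demand net of maintenance

_GAP_ANABOLIC = BIOMASS_CARBON / 3.0
_GAP_RESPIRED = 4.14597 - _GAP_ANABOLIC
_ATP_PER_GAP = _ATP_PER_BIOMASS / _GAP_RESPIRED


def core_network() -> tuple[MetabolicNetwork, dict[str, str], dict[str, list[str]]]:
    """The synthetic core network, its sub-network assignment and the
    declared exchange metabolites per sub-network.

    Returns ``(network, assignment, exchange_declaration)`` ready for
    :func:`drumalg.network.split_subnetworks`.
    """
    mets = [
        Metabolite("ACE", "acetate", "extracellular", {"C": 2}, "substrate_S"),
        Metabolite("BUTYR", "butyrate", "extracellular", {"C": 4}, "substrate_S"),
        Metabolite("SUC", "succinate", "cytosol", {"C": 4}, "accumulating_A"),
        Metabolite("GAP", "glyceraldehyde 3-phosphate", "cytosol", {"C": 3},
                   "accumulating_A"),
        Metabolite("B", "functional biomass", "cytosol",
                   {"C": BIOMASS_CARBON}, "functional_biomass_B"),
        Metabolite("CO2", "carbon dioxide", "extracellular", {"C": 1}),
        Metabolite("O2", "oxygen", "extracellular", {"C": 0}),
        Metabolite("H2O", "water", "extracellular", {"C": 0}),
        Metabolite("H", "proton", "extracellular", {"C": 0}),
        Metabolite("Pi", "inorganic phosphate", "extracellular", {"C": 0}),
        Metabolite("NH4", "ammonium", "extracellular", {"C": 0}),
        Metabolite("SO4", "sulfate", "extracellular", {"C": 0}),
        Metabolite("Mg", "magnesium", "extracellular", {"C": 0}),
        Metabolite("Light", "photon", "extracellular", {"C": 0}),
        # glyoxysome internals
        Metabolite("AcCoA", "acetyl-CoA (lumped)", "glyoxysome", {"C": 2},
                   "internal_QSS"),
        # chloroplast internals
        Metabolite("ATPc", "chloroplast ATP", "chloroplast", None, "internal_QSS"),
        Metabolite("NADPH", "chloroplast NADPH", "chloroplast", None,
                   "internal_QSS"),
        # cytosolic internals
        Metabolite("PREC", "biomass precursor pool", "cytosol",
                   {"C": BIOMASS_CARBON}, "internal_QSS"),
        Metabolite("ATPm", "cytosolic ATP", "cytosol", None, "internal_QSS"),
        Metabolite("ADPm", "cytosolic ADP", "cytosol", None, "internal_QSS"),
        Metabolite("CYC1", "cycle intermediate 1", "cytosol", {"C": 0},
                   "internal_QSS"),
        Metabolite("CYC2", "cycle intermediate 2", "cytosol", {"C": 0},
                   "internal_QSS"),
    ]

    rxns = [
        # --- glyoxysome: fatty-acid assimilation to succinate -------------
        Reaction("GX_ACE_UPTAKE",
                 {"ACE": -1, "H": -1, "AcCoA": 1},
                 subnetwork_tag="glyoxysome"),
        Reaction("GX_BUTYR_BETAOX",
                 {"BUTYR": -1, "H": -5.5, "O2": -1, "AcCoA": 2, "H2O": 3.5},
                 subnetwork_tag="glyoxysome"),
        Reaction("GX_GLYOXYLATE_CYCLE",
                 {"AcCoA": -2, "H": -1.5, "O2": -0.5, "SUC": 1, "H2O": 1.5},
                 subnetwork_tag="glyoxysome"),
        # --- chloroplast: photosynthesis ----------------------------------
        Reaction("PS_LIGHT_REACTIONS",
                 {"Light": -24, "H2O": -6, "O2": 3, "NADPH": 6, "ATPc": 9},
                 subnetwork_tag="photosynthesis"),
        Reaction("PS_CALVIN_CYCLE",
                 {"CO2": -3, "ATPc": -9, "NADPH": -6, "Pi": -1,
                  "GAP": 1, "H2O": 4},
                 subnetwork_tag="photosynthesis"),
        # --- cytosol: functional biomass synthesis ------------------------
        Reaction("BS_SUC_ANABOLISM",
                 {"SUC": -_SUC_ANABOLIC, "H": -7.30239, "NH4": -0.984915,
                  "Pi": -0.1216, "SO4": -0.02169, "Mg": -0.0101, "PREC": 1},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_SUC_RESPIRATION",
                 {"SUC": -1, "O2": -4.61237 / _SUC_RESPIRED,
                  "ADPm": -_ATP_PER_SUC, "Pi": -_ATP_PER_SUC,
                  "CO2": 4, "H2O": 7.04167 / _SUC_RESPIRED,
                  "ATPm": _ATP_PER_SUC},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_SUC_ANABOLISM_WASTEFUL",
                 # lower-yield anabolic route losing carbon as CO2
                 {"SUC": -2.5, "H": -7.30239, "NH4": -0.984915,
                  "Pi": -0.1216, "SO4": -0.02169, "Mg": -0.0101,
                  "PREC": 1, "CO2": 10.0 - BIOMASS_CARBON},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_GAP_ANABOLISM",
                 {"GAP": -_GAP_ANABOLIC, "NH4": -0.984916, "SO4": -0.02169,
                  "Mg": -0.0101, "PREC": 1, "Pi": 4.02437},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_GAP_RESPIRATION",
                 {"GAP": -1, "O2": -2.53938 / _GAP_RESPIRED,
                  "ADPm": -_ATP_PER_GAP, "Pi": -_ATP_PER_GAP,
                  "CO2": 3, "H2O": 2.8957 / _GAP_RESPIRED,
                  "H": 0.989545 / _GAP_RESPIRED, "ATPm": _ATP_PER_GAP},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_BIOMASS_ASSEMBLY",
                 {"PREC": -1, "ATPm": -_ATP_PER_BIOMASS,
                  "B": 1, "ADPm": _ATP_PER_BIOMASS, "Pi": _ATP_PER_BIOMASS},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_ATP_FUTILE",
                 {"ATPm": -1, "ADPm": 1, "Pi": 1},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_CYCLE_A", {"CYC1": -1, "CYC2": 1},
                 subnetwork_tag="biomass_synthesis"),
        Reaction("BS_CYCLE_B", {"CYC2": -1, "CYC1": 1},
                 subnetwork_tag="biomass_synthesis"),
    ]

    network = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        gam_mol_atp_per_mol_biomass=DEFAULT_GAM,
    )
    assignment = {r.id: r.subnetwork_tag for r in rxns}
    inorganics = ["CO2", "O2", "H2O", "H", "Pi", "NH4", "SO4", "Mg"]
    exchange = {
        "glyoxysome": ["ACE", "BUTYR", "SUC", "H", "O2", "H2O"],
        "photosynthesis": ["Light", "CO2", "H2O", "Pi", "GAP", "O2"],
        "biomass_synthesis": ["SUC", "GAP", "B"] + inorganics,
    }
    return network, assignment, exchange


def reduce_to_macroreactions(
    network: MetabolicNetwork,
    assignment: dict[str, str],
    exchange_declaration: dict[str, list[str]],
) -> list[MacroscopicReaction]:
    """Run the full reduction pipeline: split, enumerate, select, derive.

    Returns the five macroscopic reactions MR1 (acetate->SUC), MR2
    (butyrate->SUC), MR3 (light+CO2->GAP), MR4 (SUC->biomass), MR5
    (GAP->biomass).
    """
    subs = {
        s.tag: s
        for s in split_subnetworks(network, assignment, exchange_declaration)
    }
    glyox = subs["glyoxysome"]
    photo = subs["photosynthesis"]
    biosyn = subs["biomass_synthesis"]

    glyox_modes = enumerate_efms(glyox)
    from .efm import net_stoichiometry

    def consuming(modes, substrate):
        picked = [
            m for m in modes
            if net_stoichiometry(glyox, m).get(substrate, 0.0) < -1e-10
        ]
        if len(picked) != 1:
            raise ValueError(
                f"expected exactly one glyoxysome mode consuming {substrate!r}"
            )
        return picked[0]

    mr1 = derive_macroscopic_reaction(
        glyox, consuming(glyox_modes, "ACE"), "SUC", "MR1", "mr1")
    mr2 = derive_macroscopic_reaction(
        glyox, consuming(glyox_modes, "BUTYR"), "SUC", "MR2", "mr2")

    photo_modes = enumerate_efms(photo)
    if len(photo_modes) != 1:
        raise ValueError(
            f"photosynthesis sub-network should have one mode, "
            f"got {len(photo_modes)}"
        )
    mr3 = derive_macroscopic_reaction(photo, photo_modes[0], "GAP", "MR3", "mr3")

    bio_modes = enumerate_efms(biosyn)
    yielding, _futile = classify_modes(bio_modes, biosyn, "B")
    best_suc = select_best_yield(
        yielding, biosyn, substrate="SUC", loss="CO2", exclude_substrates=("GAP",))
    best_gap = select_best_yield(
        yielding, biosyn, substrate="GAP", loss="CO2", exclude_substrates=("SUC",))
    mr4 = derive_macroscopic_reaction(biosyn, best_suc, "B", "MR4", "mr4")
    mr5 = derive_macroscopic_reaction(biosyn, best_gap, "B", "MR5", "mr5")
    return [mr1, mr2, mr3, mr4, mr5]
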