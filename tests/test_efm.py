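"""Elementary mode enumeration, classification, selection and reduction."""

import numpy as np
import pytest

from drumalg.efm import (
    EFMError,
    carbon_yield,
    classify_modes,
    derive_macroscopic_reaction,
    enumerate_efms,
    net_stoichiometry,
    select_best_yield,
)
from drumalg.network import Metabolite, MetabolicNetwork, Reaction, SubNetwork, apply_gam
from drumalg.kinetics import TABLE_MR_STOICHIOMETRY

from efm_oracle import brute_force_modes, modes_as_set


def _subnetwork(met_specs, rxn_specs, exchange):
    """met_specs: list of ids; rxn_specs: (id, stoich, reversible)."""
    mets = [Metabolite(m) for m in met_specs]
    rxns = [Reaction(rid, stoich, reversible=rev)
            for rid, stoich, rev in rxn_specs]
    net = MetabolicNetwork(mets, rxns)
    return SubNetwork(net, "test", [r.id for r in rxns], exchange)


class TestEnumeration:
    def test_linear_chain_has_one_mode(self):
        sub = _subnetwork(
            ["Aext", "A", "B", "Bext"],
            [("r1", {"Aext": -1, "A": 1}, False),
             ("r2", {"A": -1, "B": 1}, False),
             ("r3", {"B": -1, "Bext": 1}, False)],
            ["Aext", "Bext"],
        )
        modes = enumerate_efms(sub)
        assert len(modes) == 1
        assert modes[0].support == frozenset({"r1", "r2", "r3"})

    def test_diamond_has_two_modes(self):
        sub = _subnetwork(
            ["A", "B", "C", "D"],
            [("ab", {"A": -1, "B": 1}, False),
             ("ac", {"A": -1, "C": 1}, False),
             ("bd", {"B": -1, "D": 1}, False),
             ("cd", {"C": -1, "D": 1}, False)],
            ["A", "D"],
        )
        modes = enumerate_efms(sub)
        assert len(modes) == 2
        supports = {m.support for m in modes}
        assert supports == {frozenset({"ab", "bd"}), frozenset({"ac", "cd"})}

    def test_reversible_mode_counted_once_with_canonical_orientation(self):
        sub = _subnetwork(
            ["A", "B"],
            [("r", {"A": -1, "B": 1}, True)],
            ["A", "B"],
        )
        modes = enumerate_efms(sub)
        # a fully reversible mode equals its negation: one mode, oriented
        # positively on its leading reaction
        assert len(modes) == 1
        assert modes[0].fluxes["r"] == pytest.approx(1.0)

    def test_reversible_internal_shuttle(self):
        # A -> X, X <-> Y, Y -> D: the reversible shuttle is used forward
        sub = _subnetwork(
            ["A", "X", "Y", "D"],
            [("in", {"A": -1, "X": 1}, False),
             ("shuttle", {"X": -1, "Y": 1}, True),
             ("out", {"Y": -1, "D": 1}, False)],
            ["A", "D"],
        )
        modes = enumerate_efms(sub)
        assert len(modes) == 1
        assert modes[0].fluxes["shuttle"] == pytest.approx(1.0)

    def test_output_order_is_deterministic(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = split_subnetworks(network, assignment, exchange)
        biosyn = next(s for s in subs if s.tag == "biomass_synthesis")
        first = [tuple(sorted(m.support)) for m in enumerate_efms(biosyn)]
        second = [tuple(sorted(m.support)) for m in enumerate_efms(biosyn)]
        assert first == second == sorted(first)

    def test_mode_cap_aborts(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = split_subnetworks(network, assignment, exchange)
        biosyn = next(s for s in subs if s.tag == "biomass_synthesis")
        with pytest.raises(EFMError, match="cap"):
            enumerate_efms(biosyn, max_modes=2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_networks(self, seed):
        """Double-description enumeration equals exhaustive support search
        on random networks with up to 8 reactions and 6 metabolites."""
        rng = np.random.default_rng(1000 + seed)
        n_mets = rng.integers(2, 7)
        n_rxns = rng.integers(2, 9)
        met_ids = [f"M{i}" for i in range(n_mets)]
        n_exchange = rng.integers(1, n_mets + 1)
        exchange = list(rng.choice(met_ids, size=n_exchange, replace=False))
        internal = [m for m in met_ids if m not in exchange]
        rxn_specs = []
        for j in range(n_rxns):
            stoich = {}
            for m in met_ids:
                if rng.random() < 0.4:
                    stoich[m] = float(rng.integers(-2, 3))
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                stoich = {met_ids[0]: 1.0}
            rxn_specs.append((f"R{j}", stoich, bool(rng.random() < 0.3)))
        sub = _subnetwork(met_ids, rxn_specs, exchange)

        modes = enumerate_efms(sub)
        rids = sorted(sub.reaction_ids)
        ours = modes_as_set(
            [m.as_vector(rids) for m in modes], rids)

        constrained = sorted(sub.internal_metabolites)
        S_full = sub.parent.stoichiometric_matrix()
        S = (S_full.loc[constrained, rids].to_numpy() if constrained
             else np.zeros((0, len(rids))))
        reversible = [sub.parent.reaction(r).reversible for r in rids]
        reference = modes_as_set(brute_force_modes(S, reversible), rids)
        assert ours == reference


class TestClassification:
    def _biomass_sub(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = split_subnetworks(network, assignment, exchange)
        return next(s for s in subs if s.tag == "biomass_synthesis")

    def test_partition_is_exhaustive_and_disjoint(self, core_net):
        biosyn = self._biomass_sub(core_net)
        modes = enumerate_efms(biosyn)
        yielding, futile = classify_modes(modes, biosyn, "B")
        assert len(yielding) + len(futile) == len(modes)
        assert len(yielding) > 0 and len(futile) > 0

    def test_pure_cycle_is_futile_with_zero_net_exchange(self, core_net):
        biosyn = self._biomass_sub(core_net)
        modes = enumerate_efms(biosyn)
        cycles = [m for m in modes
                  if m.support == frozenset({"BS_CYCLE_A", "BS_CYCLE_B"})]
        assert len(cycles) == 1
        assert net_stoichiometry(biosyn, cycles[0]) == {}
        _, futile = classify_modes(modes, biosyn, "B")
        assert cycles[0] in futile

    def test_single_pathway_network_is_all_biomass(self):
        sub = _subnetwork(
            ["S", "X", "B"],
            [("r1", {"S": -1, "X": 1}, False),
             ("r2", {"X": -1, "B": 1}, False)],
            ["S", "B"],
        )
        modes = enumerate_efms(sub)
        yielding, futile = classify_modes(modes, sub, "B")
        assert len(yielding) == 1 and len(futile) == 0


class TestSelection:
    def test_lower_loss_ratio_wins(self):
        sub = _subnetwork(
            ["S", "P1", "P2", "B", "CO2"],
            [("good1", {"S": -1, "P1": 1}, False),
             ("good2", {"P1": -1, "B": 1, "CO2": 2}, False),
             ("bad1", {"S": -1, "P2": 1}, False),
             ("bad2", {"P2": -1, "B": 1, "CO2": 3}, False)],
            ["S", "B", "CO2"],
        )
        modes = enumerate_efms(sub)
        best = select_best_yield(modes, sub, substrate="S", loss="CO2")
        assert best.support == frozenset({"good1", "good2"})

    def test_selection_invariant_to_mode_rescaling(self):
        sub = _subnetwork(
            ["S", "P1", "P2", "B", "CO2"],
            [("good1", {"S": -1, "P1": 1}, False),
             ("good2", {"P1": -1, "B": 1, "CO2": 2}, False),
             ("bad1", {"S": -1, "P2": 1}, False),
             ("bad2", {"P2": -1, "B": 1, "CO2": 3}, False)],
            ["S", "B", "CO2"],
        )
        modes = enumerate_efms(sub)
        scaled = [m.scaled(7.3) for m in modes]
        best = select_best_yield(scaled, sub, substrate="S", loss="CO2")
        assert best.support == frozenset({"good1", "good2"})

    def test_empty_candidate_set_errors(self):
        sub = _subnetwork(
            ["S", "B"],
            [("r", {"S": -1, "B": 1}, False)],
            ["S", "B"],
        )
        modes = enumerate_efms(sub)
        with pytest.raises(EFMError, match="no candidate"):
            select_best_yield(modes, sub, substrate="B", loss="S")

    def test_mixed_substrate_modes_are_excluded(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = split_subnetworks(network, assignment, exchange)
        biosyn = next(s for s in subs if s.tag == "biomass_synthesis")
        modes = enumerate_efms(biosyn)
        yielding, _ = classify_modes(modes, biosyn, "B")
        best = select_best_yield(
            yielding, biosyn, substrate="SUC", loss="CO2",
            exclude_substrates=("GAP",))
        net = net_stoichiometry(biosyn, best)
        assert net.get("GAP", 0.0) >= -1e-10


class TestMacroscopicReactions:
    def test_pipeline_reproduces_reference_stoichiometries(self, macroreactions):
        for mr in macroreactions:
            expected = TABLE_MR_STOICHIOMETRY[mr.id]
            assert set(mr.net_stoichiometry) == set(expected)
            for met, coef in expected.items():
                assert mr.net_stoichiometry[met] == pytest.approx(
                    coef, rel=1e-9, abs=1e-9), (mr.id, met)

    def test_internal_metabolites_net_to_zero(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = {s.tag: s for s in
                split_subnetworks(network, assignment, exchange)}
        for tag, sub in subs.items():
            for mode in enumerate_efms(sub):
                net = net_stoichiometry(sub, mode, tol=0.0)
                for met in sub.internal_metabolites:
                    assert abs(net.get(met, 0.0)) <= 1e-9

    def test_reference_product_must_be_produced(self, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = split_subnetworks(network, assignment, exchange)
        glyox = next(s for s in subs if s.tag == "glyoxysome")
        mode = enumerate_efms(glyox)[0]
        with pytest.raises(EFMError, match="zero"):
            derive_macroscopic_reaction(glyox, mode, "GAP")

    def test_source_mode_scaling_matches_reference_coefficient(
            self, macroreactions, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        subs = {s.tag: s for s in
                split_subnetworks(network, assignment, exchange)}
        mr4 = next(mr for mr in macroreactions if mr.id == "MR4")
        net = net_stoichiometry(subs["biomass_synthesis"], mr4.source_mode)
        assert net["B"] == pytest.approx(1.0)


class TestCarbonYield:
    def test_substrate_to_biomass_yield(self, macroreactions, core_net):
        network, _, _ = core_net
        comp = network.compositions()
        mr1, mr2, _, mr4, _ = macroreactions
        y_ace = carbon_yield([mr1, mr4], comp)
        y_butyr = carbon_yield([mr2, mr4], comp)
        assert y_ace == pytest.approx(0.514, abs=1e-3)
        assert y_ace == pytest.approx(y_butyr, abs=1e-12)

    def test_biomass_carbon_content_is_consistent(self, macroreactions):
        # carbon bookkeeping on the biosynthesis reactions implies the same
        # biomass carbon content from both substrate routes
        mr4 = next(mr for mr in macroreactions if mr.id == "MR4")
        mr5 = next(mr for mr in macroreactions if mr.id == "MR5")
        from_suc = -mr4.net_stoichiometry["SUC"] * 4 - mr4.net_stoichiometry["CO2"]
        from_gap = -mr5.net_stoichiometry["GAP"] * 3 - mr5.net_stoichiometry["CO2"]
        assert from_suc == pytest.approx(8.52139, abs=1e-5)
        assert from_gap == pytest.approx(8.52139, abs=1e-5)

    def test_chain_mismatch_errors(self, macroreactions, core_net):
        network, _, _ = core_net
        comp = network.compositions()
        mr1, _, mr3, _, mr5 = macroreactions
        with pytest.raises(EFMError, match="mismatch"):
            carbon_yield([mr1, mr5], comp)  # MR5 consumes GAP, not SUC

    def test_gam_monotonicity(self, core_net):
        """Raising the maintenance cost never improves the biomass carbon
        yield from succinate."""
        from drumalg.examples import reduce_to_macroreactions

        network, assignment, exchange = core_net
        comp = network.compositions()
        yields = []
        for gam in (0.0, 5.56, 12.2, 16.7):
            net = apply_gam(network, gam)
            mrs = reduce_to_macroreactions(net, assignment, exchange)
            yields.append(carbon_yield([mrs[0], mrs[3]], comp))
        assert all(a >= b - 1e-12 for a, b in zip(yields, yields[1:]))
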