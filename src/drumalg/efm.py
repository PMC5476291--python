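"""Elementary flux mode enumeration and macroscopic reaction derivation.

An elementary flux mode (EFM) of a sub-network is a support-minimal flux
distribution satisfying quasi-steady state over the sub-network's internal
metabolites and the irreversibility constraints.  Each sub-network is
reduced to macroscopic reactions: the net exchange stoichiometry of a
selected mode, rescaled so a designated reference product has coefficient
+1.  The scaled mode weights are retained so that macroscopic rates can be
mapped back to full-network fluxes.

Enumeration uses the canonical tableau double-description scheme: starting
from the generating rays of the flux cone (unit fluxes after splitting
reversible reactions), each quasi-steady-state constraint is imposed in
turn, combining adjacent rays of opposite sign; support-minimality is
enforced at every step.  Processing order is deterministic (sorted reaction
ids), so mode order and counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SubNetwork

_ZERO = 1e-10
_BIOMASS_TOL = 1e-9


class EFMError(ValueError):
    pass


@dataclass(frozen=True)
class ElementaryMode:
    """A support-minimal steady-state flux distribution of a sub-network.

    ``fluxes`` maps reaction ids to net flux values; reactions split for
    reversibility are recombined, so reversible reactions may carry negative
    net flux while irreversible ones are non-negative.
    """

    fluxes: dict[str, float]
    support: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.support is None:
            object.__setattr__(
                self,
                "support",
                frozenset(r for r, v in self.fluxes.items() if abs(v) > _ZERO),
            )

    def scaled(self, factor: float) -> "ElementaryMode":
        return ElementaryMode(
            fluxes={r: v * factor for r, v in self.fluxes.items()},
            support=self.support,
        )

    def as_vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes.get(r, 0.0) for r in reaction_ids])


def _split_reversible(subnetwork: SubNetwork):
    """Column matrix over internal metabolites with reversible reactions
    split into forward/backward halves; returns (matrix, column labels)."""
    rids = sorted(subnetwork.reaction_ids)
    internal = sorted(subnetwork.internal_metabolites)
    met_index = {m: i for i, m in enumerate(internal)}
    columns: list[tuple[str, int]] = []  # (reaction id, direction)
    vectors = []
    for rid in rids:
        rxn = subnetwork.parent.reaction(rid)
        col = np.zeros(len(internal))
        for met, coef in rxn.stoichiometry.items():
            if met in met_index:
                col[met_index[met]] = coef
        columns.append((rid, +1))
        vectors.append(col)
        if rxn.reversible:
            columns.append((rid, -1))
            vectors.append(-col)
    S = np.array(vectors).T if vectors else np.zeros((len(internal), 0))
    return S, columns


def _enumerate_rays(S: np.ndarray, max_modes: int) -> np.ndarray:
    """Extreme rays of {v >= 0 : S v = 0} by the tableau double-description
    method with a support-minimality (elementarity) test at each step."""
    n = S.shape[1]
    rays = np.eye(n)
    for i in range(S.shape[0]):
        residual = rays @ S[i]
        keep = [rays[j] for j in range(len(rays)) if abs(residual[j]) <= _ZERO]
        pos = [j for j in range(len(rays)) if residual[j] > _ZERO]
        neg = [j for j in range(len(rays)) if residual[j] < -_ZERO]
        combined = []
        for jp in pos:
            for jn in neg:
                new = residual[jp] * rays[jn] - residual[jn] * rays[jp]
                new[np.abs(new) <= _ZERO * np.max(np.abs(new))] = 0.0
                combined.append(new / np.max(np.abs(new)))
        candidates = keep + combined
        # support-minimality: drop any ray whose support strictly contains
        # another candidate's support
        supports = [frozenset(np.nonzero(np.abs(r) > _ZERO)[0]) for r in candidates]
        minimal = []
        for j, (ray, sup) in enumerate(zip(candidates, supports)):
            if any(
                k != j and supports[k] < sup
                for k in range(len(candidates))
            ):
                continue
            if any(
                k < j and supports[k] == sup
                for k in range(len(candidates))
            ):
                continue  # duplicate
            minimal.append(ray)
        rays = np.array(minimal) if minimal else np.zeros((0, n))
        if len(rays) > max_modes:
            raise EFMError(
                f"mode cap exceeded: more than {max_modes} candidate rays "
                f"({len(rays)}) while processing constraints"
            )
    return rays


def enumerate_efms(
    subnetwork: SubNetwork, max_modes: int = 100_000
) -> list[ElementaryMode]:
    """Enumerate all elementary flux modes of a sub-network.

    The quasi-steady-state constraint applies to the sub-network's internal
    metabolites only; exchange metabolites may have nonzero net exchange.
    Reversible reactions are handled by splitting and recombining; the
    two-cycle artifacts of splitting are discarded.  Output is ordered
    lexicographically by support and each mode is normalized to unit
    maximum flux.
    """
    if not subnetwork.reaction_ids:
        raise EFMError(f"sub-network {subnetwork.tag!r} is empty")
    S, columns = _split_reversible(subnetwork)
    rays = _enumerate_rays(S, max_modes)

    modes: dict[tuple, ElementaryMode] = {}
    for ray in rays:
        fluxes: dict[str, float] = {}
        for (rid, direction), v in zip(columns, ray):
            if v > _ZERO:
                fluxes[rid] = fluxes.get(rid, 0.0) + direction * v
        fluxes = {r: v for r, v in fluxes.items() if abs(v) > _ZERO}
        if not fluxes:
            continue  # forward/backward two-cycle artifact
        scale = max(abs(v) for v in fluxes.values())
        fluxes = {r: v / scale for r, v in fluxes.items()}
        # a mode running entirely over reversible reactions equals its
        # negation; canonical orientation: positive flux on the first
        # reaction of the sorted support
        if all(subnetwork.parent.reaction(r).reversible for r in fluxes):
            leader = min(fluxes)
            if fluxes[leader] < 0:
                fluxes = {r: -v for r, v in fluxes.items()}
        mode = ElementaryMode(fluxes=fluxes)
        signature = tuple(sorted(
            (r, round(v, 9)) for r, v in mode.fluxes.items()
        ))
        modes.setdefault(signature, mode)

    # recombination of split halves can cancel fluxes and shrink supports;
    # keep only modes whose support is minimal among the recombined set
    final = [
        m for m in modes.values()
        if not any(
            other.support < m.support for other in modes.values()
        )
    ]
    final.sort(key=lambda m: (
        tuple(sorted(m.support)),
        tuple(sorted(m.fluxes.items())),
    ))
    return final


# ---------------------------------------------------------------------------
# Mode algebra
# ---------------------------------------------------------------------------

def net_stoichiometry(
    subnetwork: SubNetwork, mode: ElementaryMode, tol: float = _ZERO
) -> dict[str, float]:
    """Net production (+) / consumption (-) of every touched metabolite."""
    net: dict[str, float] = {}
    for rid, weight in mode.fluxes.items():
        for met, coef in subnetwork.parent.reaction(rid).stoichiometry.items():
            net[met] = net.get(met, 0.0) + weight * coef
    return {m: v for m, v in net.items() if abs(v) > tol}


def classify_modes(
    modes: list[ElementaryMode],
    subnetwork: SubNetwork,
    biomass_id: str,
) -> tuple[list[ElementaryMode], list[ElementaryMode]]:
    """Partition modes into biomass-yielding and futile.

    A mode yields biomass when its net biomass production is strictly
    positive; everything else (pure dissipation, internal cycles) counts as
    futile.
    """
    biomass_yielding, futile = [], []
    for mode in modes:
        net = net_stoichiometry(subnetwork, mode)
        if net.get(biomass_id, 0.0) > _BIOMASS_TOL:
            biomass_yielding.append(mode)
        else:
            futile.append(mode)
    return biomass_yielding, futile


def select_best_yield(
    modes: list[ElementaryMode],
    subnetwork: SubNetwork,
    substrate: str,
    loss: str,
    exclude_substrates: tuple[str, ...] = (),
) -> ElementaryMode:
    """Pick the mode with minimal loss produced per substrate consumed.

    Only modes consuming the named substrate — and none of the
    ``exclude_substrates`` (other carbon sources) — are candidates, so each
    substrate gets its own dedicated macroscopic reaction.  Minimizing e.g.
    CO2 per substrate is equivalent to maximizing biomass per substrate
    carbon when biomass is the only other carbon sink.  Ties are broken by
    smallest support, then lexicographically.
    """
    candidates = []
    for mode in modes:
        net = net_stoichiometry(subnetwork, mode)
        if net.get(substrate, 0.0) >= -_ZERO:
            continue
        if any(net.get(other, 0.0) < -_ZERO for other in exclude_substrates):
            continue
        ratio = net.get(loss, 0.0) / (-net[substrate])
        candidates.append((ratio, len(mode.support), tuple(sorted(mode.support)), mode))
    if not candidates:
        raise EFMError(f"no candidate mode consumes {substrate!r}")
    candidates.sort(key=lambda item: item[:3])
    return candidates[0][3]


@dataclass
class MacroscopicReaction:
    """Net exchange stoichiometry of one elementary mode, as a lumped
    bioreaction.

    ``net_stoichiometry`` is normalized so the reference product carries
    coefficient +1; ``source_mode`` holds the correspondingly scaled flux
    mode, which maps this reaction's macroscopic rate back to full-network
    fluxes.
    """

    id: str
    net_stoichiometry: dict[str, float]
    source_mode: ElementaryMode | None = None
    kinetic_law_id: str = ""

    def coefficient(self, met: str) -> float:
        return self.net_stoichiometry.get(met, 0.0)

    def equation(self) -> str:
        lhs, rhs = [], []
        for met, coef in sorted(self.net_stoichiometry.items()):
            part = met if abs(abs(coef) - 1.0) < 1e-12 else f"{abs(coef):g} {met}"
            (lhs if coef < 0 else rhs).append(part)
        return f"{' + '.join(lhs)} --> {' + '.join(rhs)}"


def derive_macroscopic_reaction(
    subnetwork: SubNetwork,
    mode: ElementaryMode,
    reference: str,
    mr_id: str = "MR",
    kinetic_law_id: str = "",
) -> MacroscopicReaction:
    """Reduce a mode to its macroscopic reaction over exchange metabolites.

    Internal metabolites net exactly zero by the quasi-steady-state
    property of the mode; the stoichiometry is rescaled so the reference
    product has coefficient +1.
    """
    net = net_stoichiometry(subnetwork, mode)
    ref_coef = net.get(reference, 0.0)
    if abs(ref_coef) <= _ZERO:
        raise EFMError(
            f"reference metabolite {reference!r} nets to zero in mode"
        )
    scale = 1.0 / ref_coef
    internal_leak = {
        m: v for m, v in net.items()
        if m in subnetwork.internal_metabolites and abs(v) > 1e-9
    }
    if internal_leak:
        raise EFMError(
            f"mode is not at quasi-steady state over internals: {internal_leak}"
        )
    stoich = {
        m: v * scale
        for m, v in net.items()
        if m in set(subnetwork.exchange_metabolites) and abs(v * scale) > _ZERO
    }
    return MacroscopicReaction(
        id=mr_id,
        net_stoichiometry=stoich,
        source_mode=mode.scaled(scale),
        kinetic_law_id=kinetic_law_id,
    )


def carbon_yield(
    chain: list[MacroscopicReaction],
    compositions: dict[str, dict[str, float]],
    biomass_id: str = "B",
) -> float:
    """Carbon conversion yield of a substrate→intermediate→biomass chain.

    The first reaction produces the intermediate (reference coefficient +1),
    the second consumes it to make biomass.  Returns grams of biomass carbon
    per gram of substrate carbon (equal to the mol-carbon ratio).
    """
    if len(chain) != 2:
        raise EFMError("carbon yield is defined for a two-reaction chain")
    upstream, biosynth = chain

    def carbon(met: str) -> float:
        comp = compositions.get(met)
        if comp is None:
            raise EFMError(f"no composition for {met!r}")
        return comp.get("C", 0.0)

    produced = [
        m for m, c in upstream.net_stoichiometry.items()
        if c > _ZERO and carbon(m) > 0 and m != "CO2"
    ]
    intermediates = [
        m for m in produced if biosynth.net_stoichiometry.get(m, 0.0) < -_ZERO
    ]
    if not intermediates:
        raise EFMError(
            "chain mismatch: upstream product is not consumed by the "
            "biosynthesis reaction"
        )
    intermediate = intermediates[0]
    biomass_coef = biosynth.net_stoichiometry.get(biomass_id, 0.0)
    if biomass_coef <= _ZERO:
        raise EFMError("second chain reaction does not produce biomass")

    need_intermediate = -biosynth.net_stoichiometry[intermediate] / biomass_coef
    upstream_runs = need_intermediate / upstream.net_stoichiometry[intermediate]
    substrate_carbon = sum(
        -c * carbon(m) * upstream_runs
        for m, c in upstream.net_stoichiometry.items()
        if c < -_ZERO and carbon(m) > 0
    )
    return carbon(biomass_id) / substrate_carbon
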