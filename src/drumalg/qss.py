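"""Quasi-steady-state diagnostics and further-reduced model variants.

``detect_tqss`` finds the time an accumulating metabolite (succinate or
GAP) needs to reach quasi-steady state: the earliest time after which its
net production stays below a tolerance fraction of its gross production for
the remainder of the pre-exhaustion phase.  ``merge_reactions`` and
``build_mbm`` construct reduced variants that eliminate accumulating
metabolites by slaving their consuming reaction to the producing ones —
the fully-eliminated variant is a classical macroscopic bioreaction model
under the quasi-steady-state assumption.  ``compare_models`` confronts the
variants on shared datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import Dataset, objective
from .efm import MacroscopicReaction
from .kinetics import KineticParameters, ReducedModel, build_reduced_model
from .simulate import HOURS_PER_DAY, Trajectory

VARIANT_KINDS = (
    "drum_full",
    "merged_heterotrophic",
    "mbm_no_suc",
    "mbm_no_gap",
    "mbm_no_accumulation",
)


@dataclass
class QSSReport:
    """Outcome of quasi-steady-state detection for one metabolite."""

    metabolite: str
    t_qss_h: float | None     # None = not reached
    tolerance: float
    criterion: str
    window_end_h: float

    @property
    def reached(self) -> bool:
        return self.t_qss_h is not None

    @property
    def t_qss_minutes(self) -> float | None:
        return None if self.t_qss_h is None else self.t_qss_h * 60.0


@dataclass
class ModelVariant:
    """A reduced-model variant with provenance notes."""

    kind: str
    model: ReducedModel
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Quasi-steady-state detection
# ---------------------------------------------------------------------------

def _production_series(trajectory: Trajectory, metabolite: str):
    model = trajectory.model
    row = model.K[model.index(metabolite)]
    b = np.maximum(trajectory.species("B"), 0.0)
    gross = trajectory.alpha @ np.maximum(row, 0.0) * b
    net = trajectory.alpha @ row * b
    return gross, net


def detect_tqss(
    trajectory: Trajectory,
    metabolite: str,
    tol: float = 0.05,
) -> QSSReport:
    """Time for an accumulating metabolite to reach quasi-steady state.

    The criterion compares net to gross production: QSS holds at a time
    point when |net production| <= tol * gross production.  t_qss is the
    earliest time after which the criterion holds for the remainder of the
    pre-exhaustion phase — the period during which gross production stays
    above 1% of its maximum, which excludes the trivial steady state after
    growth stops.
    """
    model = trajectory.model
    if not model.has_species(metabolite):
        raise ValueError(f"model has no species {metabolite!r}")
    accumulating = set(model.molar_masses) - {"B"}
    if metabolite not in accumulating:
        raise ValueError(
            f"{metabolite!r} is not an accumulating metabolite of this model"
        )
    if not 0.0 < tol < 1.0:
        raise ValueError("tolerance must be in (0, 1)")

    gross, net = _production_series(trajectory, metabolite)
    peak = gross.max()
    criterion = "|net production| <= tol * gross production over pre-exhaustion phase"
    if peak <= 0.0:
        return QSSReport(metabolite, None, tol, criterion, 0.0)
    active = np.nonzero(gross >= 0.01 * peak)[0]
    window = active[-1]
    in_window = slice(0, window + 1)
    satisfied = np.abs(net[in_window]) <= tol * gross[in_window]

    # earliest index from which the criterion holds through the window end
    holds_after = np.flip(np.cumprod(np.flip(satisfied.astype(bool)))).astype(bool)
    idx = np.nonzero(holds_after)[0]
    window_end_h = float(trajectory.times_h[window])
    if len(idx) == 0:
        return QSSReport(metabolite, None, tol, criterion, window_end_h)
    return QSSReport(
        metabolite,
        float(trajectory.times_h[idx[0]]),
        tol,
        criterion,
        window_end_h,
    )


# ---------------------------------------------------------------------------
# Reduced variants
# ---------------------------------------------------------------------------

def _combine(
    parent: MacroscopicReaction,
    slave: MacroscopicReaction,
    metabolite: str,
    new_id: str,
) -> MacroscopicReaction:
    """parent + w * slave with w chosen to cancel ``metabolite``.

    The parent's kinetic law is retained: at quasi-steady state the slaved
    reaction runs exactly fast enough to consume the parent's production.
    """
    produced = parent.net_stoichiometry.get(metabolite, 0.0)
    consumed = slave.net_stoichiometry.get(metabolite, 0.0)
    if produced <= 0 or consumed >= 0:
        raise ValueError(
            f"cannot slave {slave.id} to {parent.id} through {metabolite!r}"
        )
    w = produced / (-consumed)
    stoich: dict[str, float] = dict(parent.net_stoichiometry)
    for met, coef in slave.net_stoichiometry.items():
        stoich[met] = stoich.get(met, 0.0) + w * coef
    stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
    return MacroscopicReaction(
        id=new_id,
        net_stoichiometry=stoich,
        source_mode=None,
        kinetic_law_id=parent.kinetic_law_id,
    )


def _eliminate(model: ReducedModel, metabolite: str) -> list[MacroscopicReaction]:
    """Merge the consumer of an accumulating metabolite into its producers."""
    producers = [mr for mr in model.mrs
                 if mr.net_stoichiometry.get(metabolite, 0.0) > 0]
    consumers = [mr for mr in model.mrs
                 if mr.net_stoichiometry.get(metabolite, 0.0) < 0]
    if len(consumers) != 1:
        raise ValueError(
            f"expected exactly one consumer of {metabolite!r}, "
            f"got {[m.id for m in consumers]}"
        )
    consumer = consumers[0]
    merged = []
    for mr in model.mrs:
        if mr is consumer:
            continue
        if mr in producers:
            merged.append(_combine(mr, consumer, metabolite, f"{mr.id}m"))
        else:
            merged.append(mr)
    return merged


def _variant_model(model: ReducedModel, eliminate: tuple[str, ...]) -> ReducedModel:
    mrs = model.mrs
    working = model
    for metabolite in eliminate:
        mrs = _eliminate(working, metabolite)
        species = [s for s in working.species if s != metabolite]
        working = build_reduced_model(mrs, species_order=species)
        working.molar_masses = {
            k: v for k, v in model.molar_masses.items() if k != metabolite
        }
    return working


def merge_reactions(model: ReducedModel) -> ModelVariant:
    """Merge the succinate-consuming biosynthesis into the assimilation
    reactions, eliminating succinate as a state.

    Each assimilation reaction gains 1/|SUC coefficient of the consumer|
    copies of the biosynthesis reaction; the assimilation kinetics are
    retained unchanged.  Valid once succinate is at quasi-steady state,
    i.e. after the brief initial transient of heterotrophic growth.
    """
    return ModelVariant(
        kind="merged_heterotrophic",
        model=_variant_model(model, ("SUC",)),
        notes="biosynthesis from succinate merged into substrate assimilation",
    )


def build_mbm(
    model: ReducedModel, allow_accumulation: set[str] | frozenset[str]
) -> ModelVariant:
    """Macroscopic bioreaction model allowing only the given metabolites to
    accumulate; the rest are eliminated by instantaneous consumption.

    ``allow_accumulation`` must be a subset of {SUC, GAP}.  Allowing both
    returns the unchanged full model.
    """
    allow = set(allow_accumulation)
    if not allow <= {"SUC", "GAP"}:
        raise ValueError("allow_accumulation must be a subset of {'SUC', 'GAP'}")
    eliminate = tuple(m for m in ("SUC", "GAP") if m not in allow)
    if not eliminate:
        return ModelVariant("drum_full", model, "no elimination")
    kind = {
        ("SUC",): "mbm_no_suc",
        ("GAP",): "mbm_no_gap",
        ("SUC", "GAP"): "mbm_no_accumulation",
    }[eliminate]
    return ModelVariant(
        kind=kind,
        model=_variant_model(model, eliminate),
        notes=f"eliminated: {', '.join(eliminate)}",
    )


def compare_models(
    variants: list[ModelVariant],
    datasets: list[Dataset],
    p: KineticParameters,
) -> pd.DataFrame:
    """Objective value per variant and relative increase vs the full model."""
    if not any(v.kind == "drum_full" for v in variants):
        raise ValueError("variants must include the drum_full reference")
    rows = []
    for variant in variants:
        err = objective(p, datasets, variant.model)
        rows.append({"kind": variant.kind, "error": err})
    frame = pd.DataFrame(rows)
    reference = float(
        frame.loc[frame["kind"] == "drum_full", "error"].iloc[0]
    )
    if reference > 0:
        frame["increase_pct"] = (frame["error"] - reference) / reference * 100.0
    else:
        # reference fits the data exactly (noise-free self-consistency):
        # any variant error is an infinite relative increase
        frame["increase_pct"] = np.where(
            frame["error"] > 0, np.inf, 0.0)
    return frame
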