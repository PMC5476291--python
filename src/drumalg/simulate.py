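"""Batch photobioreactor simulation of the reduced kinetic model.

States are molar concentrations; experimental conditions are given in the
field units (gC/L for substrates, g/L for total biomass) and converted at
the boundary.  Events (medium addition, light switching) restart the
integration at the event time.  Trajectories carry the 14 species, the
total biomass X(t), the macroscopic rates alpha and the depth-averaged
light fraction, and can be mapped back to full-network flux distributions
through the macroscopic reactions' source modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .efm import MacroscopicReaction
from .kinetics import (
    CARBON_ATOMS,
    KineticParameters,
    ReducedModel,
    convert_units,
    light_fraction,
)

HOURS_PER_DAY = 24.0


class SimulationError(RuntimeError):
    pass


@dataclass
class Event:
    """A mid-batch intervention.

    ``add_medium``: a feed of volume ``volume_ratio`` x culture volume with
    substrate concentrations ``added_ace``/``added_butyr`` (gC/L of the
    added volume) is mixed in, diluting every species.
    ``set_light``: the incident light becomes ``new_light`` from the event
    time onward.
    """

    time_days: float
    kind: str = "add_medium"
    added_ace: float = 0.0
    added_butyr: float = 0.0
    volume_ratio: float = 0.0
    new_light: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("add_medium", "set_light"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.volume_ratio < 0:
            raise ValueError("volume_ratio must be non-negative")


@dataclass
class ExperimentCondition:
    """Initial conditions and protocol of one batch experiment."""

    ace0: float = 0.0          # gC/L
    butyr0: float = 0.0        # gC/L
    x0: float = 0.02           # g/L initial total biomass
    incident_light: float = 0.0  # µE m^-2 s^-1 (0 = dark)
    duration_days: float = 15.0
    events: list[Event] = field(default_factory=list)
    role: str = "estimation"
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.ace0, self.butyr0, self.x0, self.incident_light) < 0:
            raise ValueError("concentrations and light must be non-negative")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        for ev in self.events:
            if not 0 <= ev.time_days <= self.duration_days:
                raise ValueError("event time outside experiment duration")


@dataclass
class Trajectory:
    """Time courses of one simulated batch."""

    times_h: np.ndarray
    states: np.ndarray            # n_times x n_species (molar)
    X: np.ndarray                 # total biomass, g/L
    alpha: np.ndarray             # n_times x n_mrs, specific rates
    light_frac: np.ndarray        # depth-averaged light fraction
    model: ReducedModel
    params: KineticParameters
    condition: ExperimentCondition

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.model.index(name)]

    def incident_light_at(self, t_h: float) -> float:
        light = self.condition.incident_light
        for ev in sorted(self.condition.events, key=lambda e: e.time_days):
            if ev.kind == "set_light" and t_h >= ev.time_days * HOURS_PER_DAY:
                light = ev.new_light
        return light

    def interp_state(self, t_h: float) -> np.ndarray:
        if not self.times_h[0] <= t_h <= self.times_h[-1]:
            raise ValueError(f"time {t_h} h outside trajectory span")
        return np.array([
            np.interp(t_h, self.times_h, self.states[:, j])
            for j in range(self.states.shape[1])
        ])

    def to_frame(self) -> pd.DataFrame:
        """Report table in field units; integrator-noise negatives are
        clipped to zero."""
        frame = pd.DataFrame({"time_h": self.times_h})
        frame["time_days"] = self.times_h / HOURS_PER_DAY
        if self.model.has_species("ACE"):
            frame["ACE_gC_L"] = [
                convert_units(max(v, 0.0), "M", "gC/L", "ACE")
                for v in self.species("ACE")
            ]
        if self.model.has_species("BUTYR"):
            frame["BUTYR_gC_L"] = [
                convert_units(max(v, 0.0), "M", "gC/L", "BUTYR")
                for v in self.species("BUTYR")
            ]
        frame["X_g_L"] = self.X
        if self.model.has_species("SUC"):
            frame["SUC_M"] = np.maximum(self.species("SUC"), 0.0)
        if self.model.has_species("GAP"):
            frame["GAP_M"] = np.maximum(self.species("GAP"), 0.0)
        frame["light_fraction"] = self.light_frac
        return frame


def ode_rhs(
    state: np.ndarray,
    model: ReducedModel,
    p: KineticParameters,
    incident_light: float,
) -> np.ndarray:
    """Right-hand side dM/dt = K · alpha(M) · B."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise SimulationError(f"non-finite state: {state}")
    B = max(float(state[model.index("B")]), 0.0)
    if B == 0.0:
        return np.zeros(model.n_species)
    alpha = model.rates(state, p, incident_light)
    return model.K @ alpha * B


def initial_state(condition: ExperimentCondition, model: ReducedModel) -> np.ndarray:
    """Molar initial state: substrates from gC/L, biomass from g/L, the
    accumulating pools SUC and GAP start empty."""
    state = np.zeros(model.n_species)
    if model.has_species("ACE"):
        state[model.index("ACE")] = convert_units(condition.ace0, "gC/L", "M", "ACE")
    if model.has_species("BUTYR"):
        state[model.index("BUTYR")] = convert_units(
            condition.butyr0, "gC/L", "M", "BUTYR")
    state[model.index("B")] = condition.x0 / model.molar_masses["B"]
    return state


def apply_addition_event(
    state: np.ndarray, event: Event, model: ReducedModel
) -> np.ndarray:
    """Mix a feed volume into the culture: every concentration c becomes
    (c + r * c_feed) / (1 + r)."""
    r = event.volume_ratio
    new = np.asarray(state, dtype=float) / (1.0 + r)
    if model.has_species("ACE") and event.added_ace:
        new[model.index("ACE")] += (
            r * convert_units(event.added_ace, "gC/L", "M", "ACE") / (1.0 + r)
        )
    if model.has_species("BUTYR") and event.added_butyr:
        new[model.index("BUTYR")] += (
            r * convert_units(event.added_butyr, "gC/L", "M", "BUTYR") / (1.0 + r)
        )
    return new


def default_sample_times(duration_days: float) -> np.ndarray:
    """Minute resolution for the first two hours (fast succinate
    transient), then ~6-minute steps to one day, then hourly."""
    t_end = duration_days * HOURS_PER_DAY
    fine = np.arange(0.0, min(2.0, t_end), 1.0 / 60.0)
    mid = np.arange(2.0, min(24.0, t_end), 0.1)
    coarse = np.arange(24.0, t_end, 1.0)
    times = np.unique(np.concatenate([fine, mid, coarse, [t_end]]))
    return times[times <= t_end]


def simulate(
    condition: ExperimentCondition,
    model: ReducedModel,
    p: KineticParameters,
    sample_times_h: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate one batch experiment, applying events exactly at their
    times, and post-compute total biomass, rates and light fraction."""
    times = (
        default_sample_times(condition.duration_days)
        if sample_times_h is None
        else np.asarray(sample_times_h, dtype=float)
    )
    state = initial_state(condition, model)
    light = condition.incident_light

    events = sorted(condition.events, key=lambda e: e.time_days)
    breakpoints = [e.time_days * HOURS_PER_DAY for e in events]
    t_end = condition.duration_days * HOURS_PER_DAY
    segments = []
    t0 = 0.0
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    light_per_time: list[np.ndarray] = []

    for ev, t_ev in list(zip(events, breakpoints)) + [(None, t_end)]:
        if t_ev > t0:
            seg_times = times[(times >= t0) & (times <= t_ev)]
            seg_eval = np.unique(np.concatenate([[t0], seg_times, [t_ev]]))
            sol = solve_ivp(
                lambda t, y: ode_rhs(y, model, p, light),
                (t0, t_ev),
                state,
                method="LSODA",
                t_eval=seg_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed at t={sol.t[-1]:.3f} h "
                    f"(state {sol.y[:, -1]}): {sol.message}"
                )
            keep = np.isin(sol.t, seg_times)
            all_t.append(sol.t[keep])
            all_y.append(sol.y[:, keep].T)
            light_per_time.append(np.full(int(keep.sum()), light))
            state = sol.y[:, -1].copy()
            t0 = t_ev
        if ev is not None:
            if ev.kind == "add_medium":
                state = apply_addition_event(state, ev, model)
            else:
                light = float(ev.new_light)
        segments.append(t0)

    times_h = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=0)
    lights = np.concatenate(light_per_time)
    # deduplicate sample points shared by adjacent segments (post-event state)
    _, keep_idx = np.unique(times_h, return_index=True)
    # prefer the later (post-event) row at duplicated times
    order = np.argsort(times_h, kind="stable")
    times_sorted = times_h[order]
    last_of_each = np.r_[np.diff(times_sorted) > 0, True]
    sel = order[last_of_each]
    times_h, states, lights = times_h[sel], states[sel], lights[sel]

    X = np.array([model.total_biomass(s) for s in states])
    alpha = np.array([
        model.rates(s, p, l) for s, l in zip(states, lights)
    ])
    b_idx = model.index("B")
    lf = np.array([
        light_fraction(p.beta_mr3 * max(s[b_idx], 0.0)) for s in states
    ])
    return Trajectory(
        times_h=times_h, states=states, X=X, alpha=alpha, light_frac=lf,
        model=model, params=p, condition=condition,
    )


# ---------------------------------------------------------------------------
# Flux reconstruction and derived diagnostics
# ---------------------------------------------------------------------------

@dataclass
class FluxMap:
    """Full-network fluxes at one instant, per unit functional biomass."""

    time_h: float
    fluxes: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction": list(self.fluxes), "flux_per_biomass": list(self.fluxes.values())}
        )


def reconstruct_fluxes(
    trajectory: Trajectory,
    mrs: list[MacroscopicReaction],
    t_h: float,
) -> FluxMap:
    """Map macroscopic rates back to full-network fluxes at time ``t_h``.

    Each macroscopic reaction carries the elementary mode it came from,
    scaled to its reference product; the flux of full-network reaction j is
    the rate-weighted sum of the mode weights.  Fluxes are per unit of
    functional biomass (the specific rates alpha already are).
    """
    if not trajectory.times_h[0] <= t_h <= trajectory.times_h[-1]:
        raise ValueError(f"time {t_h} h outside trajectory span")
    state = trajectory.interp_state(t_h)
    light = trajectory.incident_light_at(t_h)
    alpha = trajectory.model.rates(state, trajectory.params, light)
    fluxes: dict[str, float] = {}
    for rate, mr in zip(alpha, mrs):
        if mr.source_mode is None:
            raise ValueError(f"{mr.id} carries no source mode")
        for rid, weight in mr.source_mode.fluxes.items():
            fluxes[rid] = fluxes.get(rid, 0.0) + rate * weight
    return FluxMap(time_h=t_h, fluxes=fluxes)


def photosynthetic_quotient(
    trajectory: Trajectory, t_h: float
) -> float | None:
    """Net O2 production over net CO2 consumption at time ``t_h``.

    Returns None (undefined) when there is no net CO2 uptake — e.g. in
    darkness or when respiration dominates.
    """
    model = trajectory.model
    state = trajectory.interp_state(t_h)
    light = trajectory.incident_light_at(t_h)
    alpha = model.rates(state, trajectory.params, light)
    o2_rate = float(model.K[model.index("O2")] @ alpha)
    co2_rate = float(model.K[model.index("CO2")] @ alpha)
    if -co2_rate <= 0:
        return None
    return o2_rate / (-co2_rate)


# ---------------------------------------------------------------------------
# Disinhibition scenarios
# ---------------------------------------------------------------------------

def butyrate_exhaustion_day(
    trajectory: Trajectory, threshold_fraction: float = 0.05
) -> float | None:
    """First day at which butyrate drops below ``threshold_fraction`` of its
    maximal (post-event) level; None if never."""
    butyr = trajectory.species("BUTYR")
    if butyr.max() <= 0:
        return None
    threshold = threshold_fraction * butyr.max()
    below = np.nonzero(butyr < threshold)[0]
    if len(below) == 0:
        return None
    return float(trajectory.times_h[below[0]] / HOURS_PER_DAY)


def run_disinhibition_scenarios(
    model: ReducedModel,
    p: KineticParameters,
    butyr0: float = 0.5,
    x0: float = 0.02,
    duration_days: float = 20.0,
    event_day: float = 5.0,
) -> pd.DataFrame:
    """Strategies to overcome butyrate self-inhibition in a dark batch.

    Starting from an inhibitory butyrate-only culture, compares: no
    intervention; an acetate feed (0.5 gC/L, half culture volume); switching
    the light on (reference and doubled intensity); and feeding a
    fermentative acetate/butyrate mix with and without light.  Reports the
    butyrate exhaustion day per scenario (below 5% of the post-event level).
    """
    feed_mix = Event(
        event_day, "add_medium", added_ace=0.25, added_butyr=0.45,
        volume_ratio=0.5,
    )
    scenarios = {
        "no_addition": [],
        "acetate_feed": [
            Event(event_day, "add_medium", added_ace=0.5, volume_ratio=0.5)
        ],
        "light_136": [Event(event_day, "set_light", new_light=136.0)],
        "light_272": [Event(event_day, "set_light", new_light=272.0)],
        "mix_feed_dark": [feed_mix],
        "mix_feed_light": [feed_mix, Event(event_day, "set_light", new_light=136.0)],
    }
    rows = []
    for name, events in scenarios.items():
        condition = ExperimentCondition(
            ace0=0.0, butyr0=butyr0, x0=x0, incident_light=0.0,
            duration_days=duration_days, events=list(events), name=name,
        )
        traj = simulate(condition, model, p)
        exhaustion = butyrate_exhaustion_day(traj)
        rows.append({
            "scenario": name,
            "butyrate_exhaustion_day": exhaustion,
            "days_after_event": (
                None if exhaustion is None or name == "no_addition"
                else exhaustion - event_day
            ),
            "final_butyrate_gC_L": convert_units(
                float(traj.species("BUTYR")[-1]), "M", "gC/L", "BUTYR"),
            "final_X_g_L": float(traj.X[-1]),
        })
    return pd.DataFrame(rows)


def total_carbon(trajectory: Trajectory) -> np.ndarray:
    """Composition-weighted total carbon (mol C / L) along the trajectory."""
    carbon = trajectory.model.carbon_vector()
    return trajectory.states @ carbon
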