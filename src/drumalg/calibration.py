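"""Parameter calibration of the reduced model against batch data.

:class:`BatchGrowthModel` bundles a reduced kinetic model with a collection
of batch datasets (time series of acetate, butyrate and total biomass).
``fit`` estimates the ten kinetic parameters by multistart Nelder–Mead
least squares in log-parameter space (the parameters span many orders of
magnitude); starts are drawn log-uniformly inside the bounds, screened with
a single objective evaluation each, and the best candidates are optimized
locally.  Only datasets labelled ``estimation`` enter the objective;
validation errors are reported afterwards but never optimized.

Residuals are normalized per dataset and variable by the maximum observed
value of that variable, so substrate and biomass channels carry comparable
weight regardless of units and initial concentrations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import ode
from scipy.optimize import minimize

from .kinetics import CARBON_ATOMS, KineticParameters, M_CARBON, ReducedModel, reference_model
from .simulate import (
    HOURS_PER_DAY,
    ExperimentCondition,
    apply_addition_event,
    initial_state,
)

logger = logging.getLogger(__name__)

PENALTY = 1e6
OBS_COLUMNS = ("ACE_gC_L", "BUTYR_gC_L", "X_g_L")


@dataclass
class Dataset:
    """Observed time series for one batch replicate.

    ``observations`` has a ``time_days`` column and any subset of
    ``ACE_gC_L``, ``BUTYR_gC_L``, ``X_g_L``; missing values are allowed and
    simply skipped.
    """

    condition: ExperimentCondition
    observations: pd.DataFrame
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if "time_days" not in self.observations.columns:
            raise ValueError("observations need a time_days column")
        times = self.observations["time_days"]
        if (times < 0).any() or (times > self.condition.duration_days + 1e-9).any():
            raise ValueError("observation times outside condition duration")
        for col in self.observations.columns:
            if col == "time_days":
                continue
            values = self.observations[col].dropna()
            if (values < 0).any():
                raise ValueError(f"negative observations in {col}")


# ---------------------------------------------------------------------------
# Fast observable simulation (dynamic core only)
# ---------------------------------------------------------------------------

_CORE = ("ACE", "BUTYR", "SUC", "GAP", "B")


class _CoreSimulator:
    """Integrates only the dynamically coupled species of a reduced model.

    The bookkeeping rows (CO2, O2, water, minerals, photons) do not feed
    back into any rate law, so for calibration purposes the system closes
    over the substrate, accumulating and biomass species alone.
    """

    def __init__(self, model: ReducedModel):
        self.model = model
        self.core = [s for s in _CORE if model.has_species(s)]
        rows = [model.index(s) for s in self.core]
        self.K = np.ascontiguousarray(model.K[rows, :])
        self.idx = {s: i for i, s in enumerate(self.core)}
        self.b_idx = self.idx["B"]
        self.laws = list(model.kinetic_law_ids)
        self.masses = np.array([
            model.molar_masses.get(s, 0.0) for s in self.core
        ])

    def rhs(self, y, light, p):
        yc = np.maximum(y, 0.0)
        B = yc[self.b_idx]
        if B == 0.0:
            return np.zeros(len(yc))
        idx = self.idx
        ace = yc[idx["ACE"]] if "ACE" in idx else 0.0
        alpha = np.empty(len(self.laws))
        for j, law in enumerate(self.laws):
            if law == "mr1":
                alpha[j] = p.k_mr1 * ace / (p.Ks_mr1 + ace)
            elif law == "mr2":
                but = yc[idx["BUTYR"]] if "BUTYR" in idx else 0.0
                if but <= 0.0:
                    alpha[j] = 0.0
                else:
                    denom = but + (p.k_mr2 / p.beta_mr2) * (
                        but / p.Sopt_mr2 - 1.0) ** 2
                    alpha[j] = (p.k_mr2 * but / denom
                                * (p.k_D / (ace + p.k_D)))
            elif law == "mr3":
                if light <= 0.0:
                    alpha[j] = 0.0
                else:
                    x = p.beta_mr3 * B
                    frac = 1.0 if x < 1e-12 else -np.expm1(-x) / x
                    alpha[j] = (p.gamma_mr3 * frac
                                * (light / self.model.incident_light_ref))
            elif law == "mr4":
                alpha[j] = p.k_mr4 * (yc[idx["SUC"]] if "SUC" in idx else 0.0)
            elif law == "mr5":
                alpha[j] = p.k_mr5 * (yc[idx["GAP"]] if "GAP" in idx else 0.0)
            else:
                raise ValueError(law)
        return self.K @ alpha * B

    def initial(self, condition: ExperimentCondition) -> np.ndarray:
        full = initial_state(condition, self.model)
        return np.array([full[self.model.index(s)] for s in self.core])

    def observe(
        self,
        condition: ExperimentCondition,
        p: KineticParameters,
        times_days: np.ndarray,
        rtol: float = 1e-7,
        atol: float = 1e-11,
        max_steps_per_interval: int = 500,
    ) -> pd.DataFrame:
        """Observable channels (gC/L substrates, g/L total biomass) at the
        requested times, honouring any events of the condition.

        Integration effort is capped deterministically: a candidate
        parameter set that needs more than ``max_steps_per_interval``
        internal steps between consecutive output times is treated as a
        failed simulation (the optimizer sees a penalty).  The reference
        parameters use an order of magnitude fewer steps.
        """
        times_h = np.asarray(times_days, dtype=float) * HOURS_PER_DAY
        order = np.argsort(times_h)
        times_sorted = times_h[order]
        y = self.initial(condition)
        light = condition.incident_light
        events = sorted(condition.events, key=lambda e: e.time_days)
        bounds = [e.time_days * HOURS_PER_DAY for e in events]
        t_end = max(condition.duration_days * HOURS_PER_DAY, times_sorted[-1])
        out = np.empty((len(times_sorted), len(self.core)))
        t0 = 0.0
        filled = 0
        first = True
        for ev, t_ev in list(zip(events, bounds)) + [(None, t_end)]:
            # an observation at an event time reports the pre-event state
            lower = (times_sorted >= t0) if first else (times_sorted > t0)
            seg = times_sorted[lower & (times_sorted <= t_ev)]
            first = False
            targets = np.unique(np.concatenate([seg, [t_ev]]))
            current_light = light
            solver = ode(lambda t, yy: self.rhs(yy, current_light, p))
            solver.set_integrator(
                "lsoda", rtol=rtol, atol=atol,
                nsteps=max_steps_per_interval)
            solver.set_initial_value(y, t0)
            values = {}
            for t_target in targets:
                if t_target > solver.t:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        solver.integrate(t_target)
                    if not solver.successful():
                        raise RuntimeError(
                            f"integration exceeded the step budget at "
                            f"t={solver.t:.2f} h")
                values[t_target] = np.array(solver.y)
            for t_obs in seg:
                out[filled] = values[t_obs]
                filled += 1
            y = values[t_ev]
            t0 = t_ev
            if ev is not None:
                if ev.kind == "add_medium":
                    full = np.zeros(self.model.n_species)
                    for s, i in self.idx.items():
                        full[self.model.index(s)] = y[i]
                    full = apply_addition_event(full, ev, self.model)
                    y = np.array([full[self.model.index(s)] for s in self.core])
                else:
                    light = float(ev.new_light)
        out_unsorted = np.empty_like(out)
        out_unsorted[order] = out
        frame = pd.DataFrame({"time_days": np.asarray(times_days, dtype=float)})
        clipped = np.maximum(out_unsorted, 0.0)
        if "ACE" in self.idx:
            frame["ACE_gC_L"] = clipped[:, self.idx["ACE"]] * CARBON_ATOMS["ACE"] * M_CARBON
        if "BUTYR" in self.idx:
            frame["BUTYR_gC_L"] = clipped[:, self.idx["BUTYR"]] * CARBON_ATOMS["BUTYR"] * M_CARBON
        frame["X_g_L"] = clipped @ self.masses
        return frame


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def objective(
    p: KineticParameters,
    datasets: list[Dataset],
    model: ReducedModel,
    rtol: float = 1e-7,
    atol: float = 1e-11,
    _sim_cache: dict | None = None,
) -> float:
    """Normalized sum of squared residuals over all datasets.

    Residuals are (simulated - observed) / scale, with scale the maximum
    observed value of that variable within the dataset.  A simulation
    failure at a candidate parameter set contributes a large finite penalty
    instead of aborting the optimization.
    """
    if not datasets:
        raise ValueError("objective needs at least one dataset")
    cache = _sim_cache if _sim_cache is not None else {}
    total = 0.0
    for ds in datasets:
        key = id(model)
        sim = cache.get(key)
        if sim is None:
            sim = _CoreSimulator(model)
            cache[key] = sim
        try:
            predicted = sim.observe(
                ds.condition, p, ds.observations["time_days"].to_numpy(),
                rtol=rtol, atol=atol,
            )
        except Exception as exc:  # failed integration at extreme parameters
            logger.warning("simulation failed during objective: %s", exc)
            return PENALTY
        for col in OBS_COLUMNS:
            if col not in ds.observations.columns or col not in predicted.columns:
                continue
            obs = ds.observations[col].to_numpy(dtype=float)
            mask = np.isfinite(obs)
            if not mask.any():
                continue
            scale = obs[mask].max()
            if scale <= 0:
                scale = 1.0
            res = (predicted[col].to_numpy()[mask] - obs[mask]) / scale
            total += float(res @ res)
    return total


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

def default_bounds(
    center: KineticParameters | None = None, decades: float = 3.0
) -> dict[str, tuple[float, float]]:
    """Log-uniform search box: +/- ``decades`` around the reference values."""
    center = center or KineticParameters()
    factor = 10.0 ** decades
    return {
        name: (getattr(center, name) / factor, getattr(center, name) * factor)
        for name in KineticParameters.NAMES
    }


@dataclass
class CalibrationResult:
    """Estimates and diagnostics from a multistart fit."""

    best_params: KineticParameters
    best_error: float
    starts: pd.DataFrame
    split_errors: dict[str, float]
    model: ReducedModel
    bounds: dict[str, tuple[float, float]]
    seed: int

    def summary(self) -> str:
        lines = [
            "Batch growth model calibration (multistart Nelder-Mead, log space)",
            f"  seed: {self.seed}   starts: {len(self.starts)}   "
            f"converged: {int(self.starts['converged'].sum())}",
            f"  best objective: {self.best_error:.6g}",
            f"  estimation error: {self.split_errors.get('estimation', float('nan')):.6g}   "
            f"validation error: {self.split_errors.get('validation', float('nan')):.6g}",
            "",
            f"  {'parameter':<10} {'estimate':>12}   bounds",
        ]
        for name in KineticParameters.NAMES:
            lo, hi = self.bounds[name]
            lines.append(
                f"  {name:<10} {getattr(self.best_params, name):>12.4e}   "
                f"[{lo:.2e}, {hi:.2e}]"
            )
        return "\n".join(lines)


class BatchGrowthModel:
    """A reduced kinetic model confronted with batch datasets.

    Parameters
    ----------
    datasets:
        All available batch datasets; each dataset's condition carries a
        role (``estimation`` or ``validation``).  Fitting uses the
        estimation subset only.
    model:
        The reduced kinetic model; defaults to the 14-species reference
        instance.
    """

    def __init__(
        self,
        datasets: list[Dataset],
        model: ReducedModel | None = None,
    ):
        if not datasets:
            raise ValueError("need at least one dataset")
        self.datasets = list(datasets)
        self.model = model or reference_model()
        self._cache: dict = {}

    @property
    def estimation_datasets(self) -> list[Dataset]:
        return [d for d in self.datasets if d.condition.role == "estimation"]

    @property
    def validation_datasets(self) -> list[Dataset]:
        return [d for d in self.datasets if d.condition.role == "validation"]

    def objective(
        self, p: KineticParameters, subset: str = "estimation"
    ) -> float:
        datasets = (
            self.estimation_datasets if subset == "estimation"
            else self.validation_datasets if subset == "validation"
            else self.datasets
        )
        return objective(p, datasets, self.model, _sim_cache=self._cache)

    # -- fitting ---------------------------------------------------------
    def _objective_log(self, log_theta: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                       datasets: list[Dataset],
                       rtol: float = 1e-7, atol: float = 1e-11) -> float:
        theta = 10.0 ** np.clip(log_theta, lo, hi)
        penalty = float(np.sum(np.maximum(log_theta - hi, 0.0) ** 2
                               + np.maximum(lo - log_theta, 0.0) ** 2))
        try:
            p = KineticParameters.from_array(theta)
        except Exception:
            return PENALTY
        return objective(p, datasets, self.model, rtol=rtol, atol=atol,
                         _sim_cache=self._cache) * (1.0 + penalty) + penalty

    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
        screen_factor: int = 8,
        maxiter_start: int = 60,
        maxiter_polish: int = 1500,
        polish_rounds: int = 2,
        coordinate_cycles: int = 2,
        include_center: bool = True,
        search_rtol: float = 1e-6,
        search_atol: float = 1e-10,
    ) -> CalibrationResult:
        """Multistart Nelder–Mead in log-parameter space.

        ``screen_factor * n_starts`` log-uniform candidates are scored with
        one objective evaluation; Nelder–Mead chains start from the best
        ``n_starts`` and compete under a successive-halving budget: every
        chain runs ``maxiter_start`` iterations, the best third continues
        four times longer, the best two of those eight times longer.  The
        champion is then polished with restarted Nelder–Mead runs, the
        last at the full integration tolerance.  Deterministic given
        ``seed``.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        bounds = bounds or default_bounds()
        datasets = self.estimation_datasets
        if not datasets:
            raise ValueError("no estimation datasets")
        lo = np.log10([bounds[n][0] for n in KineticParameters.NAMES])
        hi = np.log10([bounds[n][1] for n in KineticParameters.NAMES])
        rng = np.random.default_rng(seed)

        def search_obj(x):
            return self._objective_log(x, lo, hi, datasets,
                                       rtol=search_rtol, atol=search_atol)

        def run_nm(x0, maxiter, xatol=1e-9, fatol=1e-13, obj=search_obj):
            return minimize(
                obj, x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "adaptive": True,
                         "xatol": xatol, "fatol": fatol},
            )

        candidates = rng.uniform(lo, hi, size=(screen_factor * n_starts, len(lo)))
        if include_center:
            candidates = np.vstack([candidates, (lo + hi) / 2.0])
        scores = np.array([search_obj(c) for c in candidates])
        order = np.argsort(scores, kind="stable")
        start_points = candidates[order[:n_starts]]

        rows = []
        chains = []  # (error, theta, start index)
        for i, x0 in enumerate(start_points):
            res = run_nm(x0, maxiter_start)
            rows.append({
                "start": i,
                "initial_error": float(scores[order[i]]),
                "final_error": float(res.fun),
                "converged": bool(np.isfinite(res.fun) and res.fun < PENALTY),
                "n_evaluations": int(res.nfev),
            })
            chains.append([float(res.fun), res.x.copy(), i])

        # successive halving: promote the most promising chains
        for keep, factor in ((max(1, n_starts // 3), 3),
                             (min(2, n_starts), 6)):
            chains.sort(key=lambda c: c[0])
            chains = chains[:keep]
            for chain in chains:
                res = run_nm(chain[1], maxiter_start * factor)
                if res.fun < chain[0]:
                    chain[0], chain[1] = float(res.fun), res.x.copy()
                rows[chain[2]]["final_error"] = chain[0]
                rows[chain[2]]["n_evaluations"] += int(res.nfev)

        chains.sort(key=lambda c: c[0])
        best_err, best_theta = chains[0][0], chains[0][1]

        # polish the champion with restarted local searches: one long round
        # at the search tolerance, the rest at the full integration
        # tolerance (the weakly identifiable directions only resolve there)
        def full_obj(x):
            return self._objective_log(x, lo, hi, datasets)

        for round_i in range(polish_rounds):
            first = round_i == 0
            res = run_nm(best_theta,
                         maxiter_polish if first else (maxiter_polish + 1) // 2,
                         xatol=1e-12, fatol=1e-16,
                         obj=search_obj if first else full_obj)
            if res.fun < best_err or round_i == 1:
                # the tolerance switch redefines the objective scale
                best_err, best_theta = float(res.fun), res.x.copy()

        # near the optimum the joint simplex degenerates along nearly flat
        # directions; cyclic one-dimensional Nelder-Mead refinements
        # resolve each parameter against the others
        for _ in range(max(0, coordinate_cycles)):
            improved_cycle = False
            for j in range(len(best_theta)):
                def coord_obj(v, j=j):
                    x = best_theta.copy()
                    x[j] = v[0]
                    return full_obj(x)

                res = minimize(
                    coord_obj, np.array([best_theta[j]]),
                    method="Nelder-Mead",
                    options={"maxiter": 60, "xatol": 1e-12, "fatol": 1e-16},
                )
                if res.fun < best_err - 1e-18:
                    best_err = float(res.fun)
                    best_theta[j] = float(res.x[0])
                    improved_cycle = True
            if not improved_cycle:
                break
        res = run_nm(best_theta, (maxiter_polish + 1) // 2,
                     xatol=1e-12, fatol=1e-16, obj=full_obj)
        if res.fun < best_err:
            best_err, best_theta = float(res.fun), res.x.copy()

        best_params = KineticParameters.from_array(
            10.0 ** np.clip(best_theta, lo, hi))
        split = {"estimation": objective(
            best_params, datasets, self.model, _sim_cache=self._cache)}
        if self.validation_datasets:
            split["validation"] = objective(
                best_params, self.validation_datasets, self.model,
                _sim_cache=self._cache)
        best_err = split["estimation"]
        starts = pd.DataFrame(rows)
        return CalibrationResult(
            best_params=best_params,
            best_error=best_err,
            starts=starts,
            split_errors=split,
            model=self.model,
            bounds=bounds,
            seed=seed,
        )

    # -- sensitivity -----------------------------------------------------
    def sensitivity_scan(
        self,
        param_name: str,
        values: np.ndarray,
        p_base: KineticParameters,
        refit_others: bool = False,
        delta: float = 0.05,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Error profile over a grid of one kinetic parameter.

        With ``refit_others`` the remaining parameters are re-optimized per
        grid value (single Nelder–Mead start at ``p_base``); otherwise they
        stay fixed.  The result marks the values within the ``delta``
        threshold interval {v : error(v) <= (1+delta) * min error}.
        """
        if param_name not in KineticParameters.NAMES:
            raise ValueError(f"unknown parameter {param_name!r}")
        if len(values) == 0:
            raise ValueError("empty grid")
        datasets = self.estimation_datasets
        errors = []
        for value in values:
            updated = p_base.to_dict()
            updated[param_name] = float(value)
            try:
                p = KineticParameters(**updated)
            except Exception:
                errors.append(np.nan)
                continue
            if refit_others:
                free = [n for n in KineticParameters.NAMES if n != param_name]
                x0 = np.log10([getattr(p, n) for n in free])

                def obj_free(x):
                    d = p.to_dict()
                    d.update({n: 10.0 ** xi for n, xi in zip(free, x)})
                    try:
                        return objective(
                            KineticParameters(**d), datasets, self.model,
                            _sim_cache=self._cache)
                    except Exception:
                        return PENALTY

                res = minimize(obj_free, x0, method="Nelder-Mead",
                               options={"maxiter": 800, "adaptive": True})
                errors.append(float(res.fun))
            else:
                errors.append(objective(p, datasets, self.model,
                                        _sim_cache=self._cache))
        errors = np.asarray(errors, dtype=float)
        finite = np.isfinite(errors)
        min_error = np.nanmin(errors) if finite.any() else np.nan
        frame = pd.DataFrame({param_name: np.asarray(values, dtype=float),
                              "error": errors})
        frame["in_interval"] = errors <= (1.0 + delta) * min_error
        return frame


def gam_scan(
    network,
    assignment: dict[str, str],
    exchange_declaration: dict[str, list[str]],
    gam_values: np.ndarray,
    datasets: list[Dataset],
    p: KineticParameters,
    delta: float = 0.10,
) -> pd.DataFrame:
    """Model error as a function of the growth-associated maintenance.

    For each GAM value the network is rebuilt, the biomass-synthesis
    sub-network re-reduced (the yield-optimal macroscopic reactions change
    with the maintenance cost) and the objective re-evaluated.  Rebuild
    failures are flagged and the scan continues.
    """
    from .network import apply_gam
    from .examples import reduce_to_macroreactions
    from .kinetics import build_reduced_model

    rows = []
    for gam in gam_values:
        row = {"gam": float(gam), "error": np.nan, "failed": False}
        try:
            net = apply_gam(network, float(gam))
            mrs = reduce_to_macroreactions(net, assignment, exchange_declaration)
            model = build_reduced_model(mrs)
            row["error"] = objective(p, datasets, model)
        except Exception as exc:
            logger.warning("GAM scan failed at %s: %s", gam, exc)
            row["failed"] = True
        rows.append(row)
    frame = pd.DataFrame(rows)
    min_error = frame["error"].min()
    frame["in_interval"] = frame["error"] <= (1.0 + delta) * min_error
    return frame
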