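"""Synthetic batch-experiment generator.

The study design emulated here: eighteen batch conditions spanning
heterotrophic growth on acetate, on butyrate and on mixtures, plus
autotrophic and mixotrophic growth under reference illumination, each
grown for about fifteen days and sampled daily in triplicate, with
multiplicative measurement noise and a detection floor on substrate
concentrations.  Half the conditions are labelled for estimation, half for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import Dataset, _CoreSimulator, objective
from .kinetics import KineticParameters, ReducedModel, reference_model
from .simulate import ExperimentCondition

REFERENCE_LIGHT = 136.0


@dataclass
class NoiseModel:
    """Multiplicative lognormal measurement noise with a detection floor.

    ``cv_multiplicative`` is the relative standard deviation of each
    observation; lognormal noise keeps concentrations positive.  Substrate
    readings below ``detection_floor`` (gC/L) report as zero.
    """

    cv_multiplicative: float = 0.05
    detection_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0 or self.detection_floor < 0:
            raise ValueError("noise parameters must be non-negative")


def make_table1_suite(x0_default: float = 0.02) -> list[ExperimentCondition]:
    """The eighteen-condition experimental design with estimation/validation
    roles: five acetate-only, four butyrate-only, five mixtures (all dark)
    and four illuminated (autotrophic/mixotrophic) conditions."""
    rows = [
        # (ace0, butyr0, light, role)
        (0.1, 0.0, 0.0, "estimation"),
        (0.25, 0.0, 0.0, "validation"),
        (0.30, 0.0, 0.0, "validation"),
        (0.5, 0.0, 0.0, "validation"),
        (1.0, 0.0, 0.0, "estimation"),
        (0.0, 0.1, 0.0, "estimation"),
        (0.0, 0.25, 0.0, "validation"),
        (0.0, 0.5, 0.0, "validation"),
        (0.0, 1.0, 0.0, "validation"),
        (0.25, 0.25, 0.0, "estimation"),
        (0.25, 0.5, 0.0, "validation"),
        (0.4, 0.1, 0.0, "validation"),
        (0.5, 0.9, 0.0, "estimation"),
        (0.9, 0.1, 0.0, "validation"),
        (0.0, 0.0, REFERENCE_LIGHT, "estimation"),
        (0.3, 0.0, REFERENCE_LIGHT, "estimation"),
        (0.0, 0.3, REFERENCE_LIGHT, "estimation"),
        (0.3, 0.3, REFERENCE_LIGHT, "estimation"),
    ]
    conditions = []
    for i, (ace0, butyr0, light, role) in enumerate(rows):
        mode = "light" if light > 0 else "dark"
        conditions.append(
            ExperimentCondition(
                ace0=ace0, butyr0=butyr0, x0=x0_default,
                incident_light=light, duration_days=15.0, role=role,
                name=f"cond{i + 1:02d}_{mode}_A{ace0:g}_B{butyr0:g}",
            )
        )
    assert sum(c.role == "estimation" for c in conditions) == 9
    assert sum(c.role == "validation" for c in conditions) == 9
    return conditions


def generate_experiment(
    condition: ExperimentCondition,
    true_params: KineticParameters,
    noise: NoiseModel,
    n_replicates: int = 3,
    sampling_days: np.ndarray | None = None,
    seed: int = 0,
    model: ReducedModel | None = None,
) -> list[Dataset]:
    """Simulate one condition and observe it with replicate noise.

    Observations are acetate and butyrate in gC/L and total biomass in g/L
    at the sampling times (default: daily).  Noise is multiplicative
    lognormal with the configured coefficient of variation, independent per
    replicate, observation and variable; substrate values below the
    detection floor report as zero.  Deterministic given ``seed``.
    """
    model = model or reference_model()
    times = (
        np.arange(0.0, condition.duration_days + 1e-9, 1.0)
        if sampling_days is None
        else np.asarray(sampling_days, dtype=float)
    )
    sim = _CoreSimulator(model)
    # same integrator settings as the calibration objective: noise-free
    # observations then match a simulation at the true parameters exactly
    clean = sim.observe(condition, true_params, times)
    rng = np.random.default_rng(seed)
    sigma = (
        np.sqrt(np.log1p(noise.cv_multiplicative ** 2))
        if noise.cv_multiplicative > 0
        else 0.0
    )
    datasets = []
    for rep in range(n_replicates):
        obs = pd.DataFrame({"time_days": times})
        for col in ("ACE_gC_L", "BUTYR_gC_L", "X_g_L"):
            if col not in clean.columns:
                continue
            values = clean[col].to_numpy(dtype=float)
            if sigma > 0:
                factors = np.exp(rng.normal(0.0, sigma, size=len(values)))
                values = values * factors
                # censoring is part of the measurement process; noise-free
                # generation returns the exact simulation
                if col != "X_g_L":
                    values = np.where(
                        values < noise.detection_floor, 0.0, values)
            obs[col] = values
        datasets.append(
            Dataset(condition=condition, observations=obs,
                    replicate_id=f"r{rep + 1}")
        )
    return datasets


def generate_table1_datasets(
    true_params: KineticParameters,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    x0_default: float = 0.02,
    conditions: list[ExperimentCondition] | None = None,
    model: ReducedModel | None = None,
) -> list[Dataset]:
    """The full synthetic campaign: every condition of the design, with
    per-condition sub-seeds derived deterministically from ``seed``."""
    noise = noise or NoiseModel()
    conditions = conditions or make_table1_suite(x0_default)
    datasets = []
    for i, condition in enumerate(conditions):
        datasets.extend(
            generate_experiment(
                condition, true_params, noise, n_replicates=n_replicates,
                seed=(seed * 1000 + i) % (2 ** 31 - 1), model=model,
            )
        )
    return datasets


def recovery_harness(
    seeds: list[int],
    noise_levels: list[float],
    true_params: KineticParameters | None = None,
    n_starts: int = 8,
    n_replicates: int = 3,
    conditions: list[ExperimentCondition] | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Generate-and-refit experiment: per noise level and parameter, the
    median relative estimation error across seeds.

    Each cell runs the full pipeline — synthesize the estimation campaign,
    fit from scratch — so the harness measures practical identifiability
    under the assumed noise structure, not just optimizer behaviour.
    """
    from .calibration import BatchGrowthModel

    true_params = true_params or KineticParameters()
    fit_kwargs = dict(fit_kwargs or {})
    conditions = conditions or [
        c for c in make_table1_suite() if c.role == "estimation"
    ]
    records = []
    for cv in noise_levels:
        for seed in seeds:
            datasets = generate_table1_datasets(
                true_params,
                NoiseModel(cv_multiplicative=cv),
                n_replicates=n_replicates,
                seed=seed,
                conditions=conditions,
            )
            result = BatchGrowthModel(datasets).fit(
                n_starts=n_starts, seed=seed, **fit_kwargs)
            for name in KineticParameters.NAMES:
                truth = getattr(true_params, name)
                est = getattr(result.best_params, name)
                records.append({
                    "noise_cv": cv,
                    "seed": seed,
                    "parameter": name,
                    "relative_error": abs(est - truth) / truth,
                    "log10_ratio": np.log10(est / truth),
                })
    frame = pd.DataFrame(records)
    return (
        frame.groupby(["noise_cv", "parameter"], as_index=False)
        .agg(median_relative_error=("relative_error", "median"),
             median_abs_log10_ratio=("log10_ratio",
                                     lambda s: float(np.median(np.abs(s)))))
    )
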