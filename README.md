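# drumalg

Dynamic metabolic modelling of heterotrophic and mixotrophic microalgal
growth on fermentative substrates (acetate and butyrate), built around a
dynamic-reduction workflow for central carbon metabolism.

Classical constraint-based modelling assumes the whole metabolic network is
at quasi-steady state (QSS), which breaks down when cells switch between
substrates or grow under self-shading light: some intracellular pools
genuinely accumulate. `drumalg` implements the alternative: split the
network into a small number of function/compartment sub-networks, assume
QSS *within* each, let the interface metabolites — succinate (SUC, leaving
the glyoxysome) and glyceraldehyde 3-phosphate (GAP, leaving the
chloroplast) — accumulate dynamically, and reduce each sub-network to
macroscopic bioreactions via elementary flux mode (EFM) analysis. The
result is a 14-species, 5-reaction kinetic model

```
dM/dt = K' · α(M) · B,      X(t) = M_SUC·SUC + M_GAP·GAP + M_B·B
```

with Michaelis–Menten acetate uptake, Haldane (substrate-inhibited)
butyrate uptake gated by a diauxic repression factor k_D/(ACE + k_D),
light-limited photosynthesis with Beer–Lambert self-shading, and
first-order biomass synthesis from each precursor — 10 kinetic parameters
in total, calibrated by multistart Nelder–Mead least squares.

The package is aimed at researchers modelling microalgal growth on
fermentation effluents (e.g. dark-fermenter digestate, mainly acetate +
butyrate) who need dynamic predictions: diauxic substrate switching,
butyrate self-inhibition, and mixotrophic rescue strategies.

## What's inside

| module | contents |
| --- | --- |
| `drumalg.network` | network data model, SBML I/O, element-balance audit, sub-network splitting, growth-associated maintenance (GAM) |
| `drumalg.efm` | EFM enumeration (double description with support-minimality), mode classification, yield-optimal selection, macroscopic-reaction derivation |
| `drumalg.kinetics` | the reduced model: K' matrix, the five rate laws, the 10-parameter set, unit conversions |
| `drumalg.simulate` | stiff batch integration with feed/light events, flux-map reconstruction, photosynthetic quotient, disinhibition scenarios |
| `drumalg.calibration` | `BatchGrowthModel.fit()` → `CalibrationResult` (multistart Nelder–Mead in log space), sensitivity and GAM scans |
| `drumalg.qss` | time-to-QSS detection, merged heterotrophic model, macroscopic bioreaction model variants, model comparison |
| `drumalg.synth` | synthetic batch campaigns (the 18-condition design, triplicates, lognormal noise, detection floor) |
| `drumalg.examples` | a synthetic core network whose reduction reproduces the reference macroreactions end to end |

## Worked example

```python
from drumalg import (ExperimentCondition, KineticParameters,
                     reference_model, simulate)
from drumalg.qss import detect_tqss

model = reference_model()          # 14 species x 5 macroreactions
params = KineticParameters()       # calibrated reference parameters

# dark batch: 0.25 gC/L acetate + 0.25 gC/L butyrate, 15 days
condition = ExperimentCondition(ace0=0.25, butyr0=0.25, x0=0.02)
traj = simulate(condition, model, params)

frame = traj.to_frame()
print(frame[frame.time_days.isin([0, 2, 6, 15])][
    ["time_days", "ACE_gC_L", "BUTYR_gC_L", "X_g_L"]
].round(6).to_string(index=False))
print("SUC time-to-QSS: %.1f minutes" %
      detect_tqss(traj, "SUC").t_qss_minutes)
```

prints

```
 time_days  ACE_gC_L  BUTYR_gC_L    X_g_L
       0.0      0.25    0.250000 0.020000
       2.0      0.00    0.233781 0.268593
       6.0      0.00    0.111810 0.382488
      15.0      0.00    0.000000 0.486893
SUC time-to-QSS: 2.0 minutes
```

Reading: acetate is gone by day 2 while butyrate is untouched (diauxie —
even traces of acetate repress butyrate uptake), after which the grown
biomass consumes the butyrate; every gram of substrate carbon yields
0.514 g of biomass carbon, and the succinate pool equilibrates within
minutes of inoculation.

The same objects drive the scenario and calibration layers:

```python
from drumalg import run_disinhibition_scenarios
print(run_disinhibition_scenarios(model, params))   # feed/light rescues

from drumalg.calibration import BatchGrowthModel
from drumalg.synth import NoiseModel, generate_table1_datasets
data = generate_table1_datasets(params, NoiseModel(0.05), seed=1)
result = BatchGrowthModel(data).fit(n_starts=20, seed=1)
print(result.summary())
```

A thin CLI wraps the same calls: `drumalg simulate|scenarios|fluxmap|fit|
qss|compare-models --help`.

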