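# Methods

## The model

`drumalg` models a mixotrophic chlorophyte growing in batch on acetate and
butyrate, with or without light. The central carbon network is split into
three sub-networks along compartment/function lines:

1. **Glyoxysome** — fatty-acid assimilation: acetate and butyrate are
   activated to acetyl-CoA and converted to succinate by the glyoxylate
   cycle.
2. **Chloroplast** — photosynthesis: the light reactions plus the Calvin
   cycle fix CO2 into glyceraldehyde 3-phosphate (GAP).
3. **Biomass synthesis** — everything else: glycolysis/gluconeogenesis,
   TCA cycle, oxidative phosphorylation, and the anabolic routes from
   succinate or GAP to functional biomass.

Each sub-network is assumed internally at quasi-steady state (QSS); only
the two interface metabolites, succinate (SUC) and GAP, plus the external
substrates and functional biomass B, have dynamics. Each sub-network is
reduced to macroscopic reactions by elementary flux mode (EFM) analysis:
the glyoxysome yields one mode per substrate (MR1, MR2), photosynthesis a
single mode (MR3, with the textbook 8-photon-per-carbon quota), and the
biomass sub-network many modes, from which the yield-optimal one per
precursor is selected — maximal biomass per substrate carbon, i.e. minimal
CO2 loss (MR4 from SUC, MR5 from GAP). Candidate modes for each precursor
are restricted to those consuming that precursor alone, so each substrate
gets a dedicated lumped reaction; ties (none occur in the shipped network)
would break by smaller support, then lexicographically.

The reduced model couples 14 species through the 14×5 matrix K′:

    dM/dt = K′ · α(M) · B
    X(t)  = M_SUC·SUC + M_GAP·GAP + M_B·B

with rate laws (all specific, per mol of functional biomass):

| rate | law | interpretation |
| --- | --- | --- |
| α₁ | k₁·ACE/(Ks₁+ACE) | Michaelis–Menten acetate uptake |
| α₂ | k₂·BUTYR/[BUTYR+(k₂/β₂)(BUTYR/Sopt−1)²] · k_D/(ACE+k_D) | Haldane substrate inhibition with an optimum at Sopt, times diauxic repression by acetate |
| α₃ | γ₃·(I/I_ref)·(1−e^{−β₃B})/(β₃B) | photosynthesis, linear in the Beer–Lambert depth-averaged light |
| α₄ | k₄·SUC | first-order biomass synthesis from succinate |
| α₅ | k₅·GAP | first-order biomass synthesis from GAP |

Ten parameters: k₁ = 0.379 M h⁻¹ M_B⁻¹, Ks₁ = 5.52e−5 M, k₂ = 3.61e−2
M h⁻¹ M_B⁻¹, β₂ = 2.58e5 h⁻¹ M_B⁻¹, Sopt = 1.93e−5 M, k_D = 5.39e−10 M,
γ₃ = 0.262 M h⁻¹ M_B⁻¹, β₃ = 2.48e3 M_B⁻¹, k₄ = 2.37e5 h⁻¹ M_B⁻¹,
k₅ = 28.3 h⁻¹ M_B⁻¹. Molar masses: SUC 118.09, GAP 170.06, biomass
186 g/mol; biomass carbon content 8.52139 mol C per mol, implied by the
carbon bookkeeping of MR4/MR5. γ₃ is defined at the reference incident
intensity I_ref = 136 µE m⁻² s⁻¹ and scales linearly with I (needed for
doubled-light scenarios). The exponent in α₃ is negative (1 − e^{−β₃B});
the attenuation factor at β₃B ≈ 8.5 is ≈ 0.117, the late-culture light
equilibrium. k₄ ≫ k₅ is deliberate: succinate is consumed essentially as
fast as it is made (QSS within minutes), while GAP accumulates under
varying light — the label assignment follows the stoichiometry (MR4
consumes SUC) and the observed fast-SUC/slow-GAP behaviour.

Bookkeeping species (CO2, O2, H2O, H, Pi, NH4, SO4, Mg, photons) are
integrated but exert no kinetic feedback — the cultures are designed to be
limited by carbon and light only. The photon row records cumulative light
consumption so that the state dimension stays 14.

## EFM enumeration

Enumeration is the canonical tableau double-description method: after
splitting reversible reactions, start from the unit rays of the flux cone
and impose each internal-metabolite QSS constraint in turn, combining rays
of opposite residual sign and keeping only support-minimal candidates.
Reaction processing order is sorted, so counts and output order are
reproducible. Modes supported entirely on reversible reactions equal
their negation and are reported once with a canonical orientation. A
configurable cap (default 100 000 rays) aborts pathological inputs.
Correctness is cross-checked in the test suite against an independent
brute-force extreme-ray search (exhaustive over support subsets) on random
networks.

## Growth-associated maintenance (GAM)

The default maintenance is 5.56 mol ATP per mol biomass (29.890 mol ATP
per kg at 186 g/mol). In the packaged network the biomass-assembly
reaction carries a fixed anabolic ATP demand plus the maintenance term;
`apply_gam` adjusts the maintenance component and the reduction pipeline
re-derives MR4/MR5, so raising GAM diverts more precursor carbon to
respiration and lowers the biomass yield monotonically. `gam_scan`
profiles model error over a maintenance grid and reports the
(1+δ)-threshold interval (δ = 0.10 by default for GAM).

## Simulation

Batch integration uses LSODA (the succinate balance makes the system
stiff: its relaxation rate is ≈ 4.146·k₄·B ≈ 10²–10³ h⁻¹) with
rtol 1e−8 / atol 1e−12 by default. The sampling grid is minute-resolved
for the first two hours (to resolve the succinate transient), ~6-minute
to day one, then hourly. Feed and light events restart the integration at
the event time; a feed of volume ratio r with concentration c_feed updates
every concentration as (c + r·c_feed)/(1+r). Initial SUC and GAP are zero
(autotrophically grown inoculum, transferred), initial biomass defaults to
x0 = 0.02 g/L — the inoculum size is a design choice, configurable per
condition, as no measured value is available.

Flux maps: each macroscopic reaction stores the elementary mode it came
from, scaled to its reference product; the full-network flux of reaction j
at time t is Σ_MR α_MR(t)·w_j(MR), per unit biomass. Internal metabolites
net to zero by construction.

The photosynthetic quotient PQ = (net O2 production)/(net CO2 uptake) is
1.0 when all fixed carbon accumulates as GAP and rises to ≈ 1.16 when GAP
is consumed at QSS; it is undefined (None) without net CO2 uptake. During
transients in which GAP is consumed faster than its QSS balance the
instantaneous PQ can exceed the QSS value.

## Calibration

`BatchGrowthModel.fit` minimizes a normalized least-squares objective:
residuals (sim − obs)/scale, with scale the per-dataset maximum of each
observed variable (acetate, butyrate in gC/L; total biomass in g/L) —
chosen so every channel carries comparable weight; the normalization is
recorded in the result metadata. Optimization is multistart Nelder–Mead
in log10-parameter space (the parameters span ~15 orders of magnitude):
log-uniform candidates inside the bounds (default ±3 decades around the
reference values) are screened with one objective evaluation each and the
best `n_starts` seed Nelder–Mead chains that compete under a
successive-halving budget — every chain runs a base iteration count, the
best third continues with a larger budget, the best two larger still —
and the champion is polished with restarted runs, the later ones at the
full integration tolerance, finishing with cyclic one-dimensional
Nelder–Mead refinements of each parameter (near the optimum the joint
simplex degenerates along nearly flat directions — notably k₄, whose
influence on the observables is limited to the small succinate term of
X(t); a line search along each axis resolves them). The default budgets are sized for a
laptop-scale calibration (minutes, not hours); they are ordinary
arguments and larger budgets refine the weakly identifiable directions
further. Failures at extreme candidates contribute a large finite
penalty (1e6) instead of aborting. Everything is deterministic given the
seed. Only datasets labelled `estimation` enter the objective;
validation errors are computed once, afterwards.

For calibration the ODE system is integrated over the five dynamically
coupled species only (ACE, BUTYR, SUC, GAP, B) — the bookkeeping rows
feed no rate law — at rtol 1e−7 / atol 1e−11 (search phases use 1e−6 /
1e−10), with a deterministic cap on integration steps per output interval
so that pathologically stiff candidate parameters fail fast into the
penalty instead of stalling the search. The synthetic-data generator
uses the same integrator settings as the reporting objective, so
noise-free data score exactly zero at the generating parameters.

Identifiability: k_D = 5.39e−10 M sits far below any measurable
concentration — the data constrain it only from above (any sufficiently
small value yields the same sharp diauxie), so recovery is judged on the
order of magnitude. k₄ is constrained only through the tiny succinate
contribution to X(t) (relative ~5e−4); on noise-free data it remains
identifiable, under realistic noise it is effectively a lower-bounded
parameter.

## Quasi-steady-state analysis

`detect_tqss` declares QSS at the earliest time after which
|net production| ≤ tol × gross production (default tol 0.05) holds for the
remainder of the pre-exhaustion phase, defined as the period during which
gross production stays above 1% of its maximum — this excludes the trivial
steady state after growth stops. For an exponential relaxation the
criterion gives t_QSS = ln(1/tol)/λ, which the tests verify against the
succinate relaxation rate. The criterion and tolerance are recorded in
every report.

Reduced variants: `merge_reactions` folds the succinate-consuming
biosynthesis into the assimilation reactions (weights 1/4.14597),
eliminating SUC as a state while keeping the assimilation kinetics — valid
once SUC is at QSS, i.e. minutes into a batch. `build_mbm` generalizes
this to any subset of {SUC, GAP}: eliminating both yields a classical
macroscopic bioreaction model under full QSS. Comparisons
(`compare_models`) report objective values and relative increases versus
the full model; on light-exposed data, forbidding GAP accumulation
degrades the fit badly (GAP is the light-driven carbon buffer), while
eliminating SUC is nearly free in any condition.

## Synthetic campaigns

The generator emulates the study design: 18 batch conditions — acetate
only (0.1–1 gC/L), butyrate only (0.1–1 gC/L), five mixtures, and four
illuminated (autotrophic/mixotrophic) conditions at 136 µE m⁻² s⁻¹ — each
~15 days, sampled daily, in triplicate, split 9/9 into estimation and
validation. Observables are acetate and butyrate (gC/L) and total biomass
(g/L). Noise is multiplicative lognormal with a 5% coefficient of
variation by default (chosen to match the scatter of typical
HPLC/dry-weight batch measurements; real measurement CVs for this system
are not available, so this is a sensitivity knob), with a 0.01 gC/L
detection floor on the substrate channels. Noise-free generation returns the exact simulation —
censoring is part of the measurement process, not of the model.

What the generator does *not* emulate: instrument-specific error structure
(carryover, dry-weight bias), replicate-level variation in inoculum or
initial substrate, pH/temperature drift, day/night cycles. Passing
recovery tests therefore demonstrates the internal consistency of the
pipeline under the assumed noise structure, not fit quality on real
laboratory measurements, which are not distributed with this package.

## The packaged core network

`drumalg.examples.core_network()` is a **synthetic** lumped network (14
reactions): it reproduces, through the full split→EFM→selection pipeline,
the exact reference macroscopic reactions, and exhibits the qualitative
features of the full-size network — several biomass modes per precursor
(including a deliberately wasteful route and mixed-substrate modes),
futile cycles, a tunable GAM. It is not the full-size genome-derived
core network, which is not redistributable here; its mode counts are its
own. Cofactor species (ATP/ADP/NADPH pools) carry no elemental
composition, so reactions touching them are reported as "unchecked" by
the element-balance audit — carbon audit of the carbon-carrying species
is complete and exact.

## Numerical choices and limitations

* Carbon balance is the hard stoichiometric invariant (≤1e−9 per K′
  column; ≤1e−6 relative drift along trajectories). H and O balances of
  the lumped reference reactions depend on protonation conventions that
  are not fully specified, so they are report-only.
* Trajectories are invariant to halving integrator tolerances (≤1e−6
  relative on X).
* Exhaustion thresholds: a substrate counts as exhausted below 1% of its
  initial value (QSS windows) or 5% of its post-event level (scenario
  reports).
* Scenario horizon is 20 days with the intervention at day 5 — the
  rescued cultures need ~8–14 days after the event to clear 0.5 gC/L
  butyrate.
* Compartments are tags, not volumes; transport is an ordinary reaction.
* No gas–liquid transfer, pH, temperature or day/night dynamics.
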