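# Methods

`tortmove` couples two computational engines for studying how a fenced
highway shapes Mojave desert tortoise (*Gopherus agassizii*) movement and
how culvert design could restore connectivity across it: a covariate-linked
hidden Markov movement model (HMM) fitted to 30-min GPS fixes, and a
two-state random-walk simulator on a resistance raster with an impassable
highway band pierced by permeable culverts.

## 1. The movement HMM

### Observation model

Each 30-min interval yields a step length `l_t` (straight-line distance
between consecutive fixes, metres) and a turning angle `θ_t` (change of
heading between consecutive steps, radians in (−π, π], undefined on the
first step of each track segment). Conditional on a latent behavioural
state `S_t ∈ {resting, traveling}`:

- `l_t | S_t = s ~ Gamma(mean μ_s(x_t), sd σ_s(x_t))`, with log links
  `log μ_s(x_t) = x_t' β_{μ,s}` and `log σ_s(x_t) = x_t' β_{σ,s}`;
- `θ_t | S_t = s ~ von Mises(0, κ_s)`, zero mean, state-specific
  concentration; κ never takes covariates.

The state sequence is a Markov chain whose off-diagonal transition
probabilities use a logit link, `logit γ_rt(x_t) = x_t' α_rt` (and
similarly γ_tr); each segment starts from the stationary distribution of
Γ(x) at its first covariate vector (a standard, parameter-free choice).

Covariate terms: an **hour-of-day** cosinor pair cos(2πh/24) + sin(2πh/24)
counted as one "Hour" term; **ambient temperature** (°C); **sex**
(0 = female, 1 = male); **log distance to highway** (natural log of the
perpendicular distance in metres, floored at 1 m); and the
**log-distance × sex** interaction. A single-cosine "Hour" mode exists
(`single_cosine=True`) but the pair is the default: a lone cosine pins the
diel activity peak to midnight, whereas observed activity peaks mid-day —
the pair estimates the phase, matching common movement-HMM practice.

### Data preparation

Tracks are split into segments wherever the inter-fix gap exceeds 1.5× the
nominal interval (45 min); step and turn metrics are undefined across gaps.
Step lengths are floored at 0.1 m (stationary animal + GPS jitter) rather
than adding a zero-inflation mass, keeping the strictly positive gamma;
the floor is configurable. Temperature and log-distance covariates are
z-scored internally before fitting and the centring constants are stored
with the parameters, so presets (raw scale) and fits (z-scored) share one
prediction path.

### Estimation

Direct maximum likelihood: the scaled forward recursion (numba-compiled,
renormalised every step so two-year sequences of 35k+ records cannot
underflow) is maximised by L-BFGS-B on the working scale (log for μ, σ, κ;
logit-linear transitions) from moment-based starting values (median split
of step lengths) with jittered restarts (default 10; the likelihood is
multimodal and label-switching is real). Invalid parameter evaluations
return a large finite penalty so the optimiser can recover. After fitting,
states are relabelled so the state with the larger mean step at mean
covariates is "traveling", and fits whose two states collapse
(relative mean difference < 1e-3) are flagged degenerate. Standard errors
come from the numerically differentiated Hessian at the optimum
(pseudo-inverse); `predict_step_mean` CIs are delta-method intervals,
symmetric on the log scale and therefore strictly positive.
`AIC = −2ℓ + 2k` exactly.

Model-selection ladders mirror the staged analysis: the seven non-empty
subsets of {Hour, Temp, Sex} on the step component (transitions constant),
the same seven on transitions (steps held at the full biological model),
both at once ("combined"), and a five-model highway extension (biological
model alone; + log-distance on steps, on transitions, on both; + the
sex interaction on both). When the highway term is included it enters the
gamma mean, the gamma SD and the transitions; a flag can restrict it.
A Julian-day quadratic seasonal term is deliberately not in the default
ladder (it found nothing in the original field analysis).

## 2. Synthetic tracks and the frozen presets

The field telemetry cannot be redistributed (federally listed species), so
`tortmove.synth` generates tracks with the statistical structure of the
fitted model. Published values encoded in the presets: resting means
4.4 m (male) / 4.2 m (female); traveling means 47.8 / 28.4 m at mean
covariates; constant transitions 0.098 (rest→travel) and 0.228
(travel→rest) per 30-min step; a temperature effect raising the traveling
mean by 50% from 5 to 45 °C, solved on the log link as
β_T = log(1.5)/40 ≈ 0.0101 per °C (only the ratio is published); and, in
highway mode, transition effects signed so that near the highway females
switch into and stay in the traveling state while males keep resting.

Values with no published estimate are synthetic fill, documented as
calibration constants, not published estimates: per-state gamma SDs
(set equal to the means, CV = 1), von Mises concentrations (mean resultant
lengths 0.5 resting / 0.707 traveling, κ ≈ 1.16 / 2.08), the diel
amplitude (0.25 on the log scale, peak 13:00), the highway coefficient
magnitudes (±0.3 on the logit scale per log-metre), and the preset
reference covariates (temperature 25 °C = the diel midpoint; distance
500 m, the middle of the observed 200–1000 m range). Presets are
hash-stamped (`HmmParams.fingerprint()`) so drift is detectable.

The generator's world: 15 animals (9 male / 6 female), 48 fixes/day, diel
temperature sinusoid (midpoint 25 °C, amplitude 10 °C, truncated noise
SD 2 °C, peak 15:00) clipped to the observed 5–45 °C window, start
positions 200–1000 m north of an east–west highway line. Positions
integrate the sampled headings and gamma steps, so distance-to-highway is
recomputed from the generated positions. Not emulated: GPS error, fix
failures, mortality censoring, aestivation phenology. A green round-trip
test therefore establishes estimator correctness under the model, not
robustness to real-data artefacts.

## 3. Resistance landscapes

Rasters hold resistance in [0, 1] (0 permeable, 1 impassable) at a fixed
0.6-m cell — the width of the smallest culvert, so culverts span whole
columns (0.61 m → 1 column, 1.83 m → 3; width/cell rounded to the nearest
odd count). `rescale_resistance` min-max rescales arbitrary grids and
leaves grids already in [0, 1] untouched. The regional
landscape-connectivity model used originally is external data; the default
synthetic base is flat resistance 0.2, and a reader for user-supplied
Esri ASCII grids is provided.

The highway is an east–west band of resistance-1 cells (exclusionary
fencing), rendered 30 m deep by default (typical divided-highway footprint;
no rasterised road depth is published — configurable). Culvert
interiors are 0.05 across the full band depth; "just outside" aprons are
0.25 collars, 3 m deep, on both mouths (values are published, the geometry
is not). Note the apron (0.25) is *less* permeable than the default
synthetic base (0.2); the published 0.05/0.25 coding refers to the real
landscape, where culverts sit in washes. Ten design scenarios are valid:
7/14/28 single culverts and 7/14 pairs, at widths 0.61 m and 1.83 m, evenly
spaced along a 17.5-km highway (length back-derived from the published density "7 culverts =
0.40/km", which makes all printed spacings — 2.5 km, 1.25 km, 625 m —
mutually consistent). Pair members sit 10 m apart centre-to-centre (not
stated; configurable). Real culverts follow washes; positional
irregularity is not modelled. Capture-plot geometry: 800-m-radius
semicircles anchored on the band edges north and south of each culvert
location.

## 4. The walker simulator

Walkers alternate between resting (true random walk, one 0.6-m cell per
step, uniform heading) and traveling (correlated random walk, successive
headings correlated with mean cosine 0.707, base step drawn from the
traveling-state gamma of the male preset capped at 45 m so walkers cannot
leap the barrier; a fixed-length mode exists) with the constant fitted
transition probabilities 0.098/0.228. The published description delegates the
resistance semantics to simulation software without printing equations;
the contract frozen here is:

1. state update by Bernoulli draw;
2. 24 candidate headings, evenly spaced with a per-step random rotation
   (avoids raster-lattice locking), weighted by the angular law — uniform
   when resting, wrapped-normal around the previous heading with
   σ = sqrt(−2 ln 0.707) ≈ 0.833 rad when traveling (the 24-point
   discretisation gives mean cosine ≈ 0.70, inside the ±0.02 check);
3. each candidate ray scored by Gaussian-kernel-weighted resistance
   (perceptual SD 8 m, truncated at 3 SD, sampled every cell along the
   ray); the explicit "standard deviation of 8 m" is followed — an
   accompanying parenthetical ("66% within ~25 map units") is not
   reconcilable with it at 0.6-m cells;
4. realised heading sampled with weight ∝ angular density × (1 − score);
   base length scaled by (1 − score at the chosen heading);
5. the step truncated at the last passable sample (quarter-cell
   increments) before any resistance-1 cell, so the fenced highway is a
   hard barrier crossable only through culverts.

A crossing event is a change of side of the band centreline between
consecutive positions; the connecting path must traverse culvert-interior
cells, and a side change that does not is a hard error (it would mean the
barrier leaks). Both integrity invariants — no position ever in a
resistance-1 cell, no culvert-free side change — are enforced inside the
engine on every step of every replicate.

Abundance is one negative-binomial draw (mean 70, size 13.08) per replicate
for the whole landscape — back-derived from the reported average of
2,451,644 steps per simulation ≈ 70 walkers × 35,040 steps; a per-plot
mode is available. Start positions are uniform over the plot semicircles;
initial states come from the stationary distribution
0.098/(0.098+0.228) ≈ 0.301.

An exact shortcut keeps full-scale runs tractable: cells whose entire
45-m reach sees constant resistance are precomputed (`_uniform_zone`), and
there ray scoring collapses to the local value and truncation to the full
step — identical draws, identical trajectories, ~2× faster on mostly-flat
landscapes.

### What the simulation tests do and do not establish

The published absolute crossing rates (order 1e-5 % of steps) depend on
the real regional resistance layer and full scale (10 scenarios × 1000
replicates × ~2.45M steps, days of CPU). They are deliberately not
reproduced. The test suite instead verifies the properties the design
conclusions rest on, at a fixed, seeded, scaled-down world chosen once:
2-km highway segment, 600-m-deep landscape, 9-m band, 250-m plots,
120 days, 50 replicates. The shallower band and near-highway plots raise
event counts from O(1) to O(10–100) per design so the monotonicity
comparisons (wider culverts ≥ narrower; more culverts ≥ fewer; zero
culverts = exactly zero) are resolved well above Monte-Carlo noise rather
than comparing handfuls of events.

## 5. Numerical choices

- Forward recursion: per-step renormalisation (no log-sum-exp needed);
  brute-force enumeration over all state sequences is the test oracle.
- Optimiser: L-BFGS-B, ftol 1e-10, gtol 1e-6, maxiter 500; finite-difference
  gradients; linear predictors clipped at ±30 before exponentiation.
- Hessian: central differences with step 1e-4·(1+|x|).
- Degenerate/boxed-in cases: a walker with zero total candidate weight
  stays in place; a walker enclosed in a single passable cell never leaves
  it (but may move within it).
- Out-of-raster cells count as resistance 1, so walkers cannot exit the
  modelled landscape.
- Determinism: every stochastic entry point takes a seed; replicate seeds
  derive from `numpy.random.SeedSequence`; the numba engine seeds its own
  generator, and identical seed + config reproduce bit-identical
  trajectories and summaries.

## 6. Known limitations

- Exact numeric parity with the original simulation package is a non-goal;
  the movement contract above is the specification.
- Two states maximum; no continuous-time HMM, spatial random effects,
  home-range estimation, mortality, aestivation phenology, or attraction
  beyond the resistance kernel.
- No CRS machinery: all inputs must share one projected metric CRS.
- The synthetic flat landscape understates real heterogeneity (washes,
  vegetation), so scaled-down crossing rates are not comparable in level
  to the published table — only the qualitative ordering is.
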