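# Methods

## Model structure and assumptions

The core is an anoxic heterotrophic growth model in the activated-sludge
tradition, formulated on an organic-carbon (TOC) basis. Growth on each
soluble donor pool follows dual-Monod kinetics — the product of a
donor-saturation factor and a nitrate-saturation factor — scaled by a
pool-specific maximum rate constant k3 and the biomass concentration.
Death is first order with constant bH. Three departures from the standard
formulation encode the electron-donor-limited subsurface setting:

1. **Donor categories.** Organic carbon is split by degradability into
   `glucose`, `plasticizer` (cement super-plasticizer extract),
   `biomass_derived` (soluble organics released from dead cells) and
   `humic` pools, each with its own k3 and half-saturation constant.
   Multi-pool growth is additive (parallel substrate utilization); no
   preferential switching is modelled, as none is observed at these rates.
2. **Direct recycling of dead-biomass carbon.** A fraction `f_recycle` of
   the death flux bH·xB re-enters solution immediately as
   `biomass_derived` donor, bypassing particulate hydrolysis. This matters
   when no easily degradable donor is present: a dense inoculum then
   sustains measurable denitrification on its own debris. The complement
   (1 − f_recycle) accumulates as inert solids.
3. **Direct NO₃⁻ → N₂.** Nitrite and ammonia intermediates are not
   tracked (their observed levels are three to four orders of magnitude
   below nitrate); reduced nitrogen accumulates in a cumulative N₂ pool.

Carbon from consumption splits x_yield : (1 − x_yield) between new biomass
and mineralized CO₂; together with the inert pool this makes total carbon
an exactly conserved quantity, and nitrate + cumulative N₂-N likewise for
nitrogen. Both closures are asserted in the test suite at 10× the
integrator's relative tolerance.

The N/C stoichiometry z couples nitrate reduction to respiration-driven
donor consumption only; the recycle influx is not an oxidation and reduces
no nitrate.

## Parameters

| parameter | units | default | basis |
|---|---|---|---|
| k3 (glucose) | d⁻¹ | 1.0 | low end of the typical ASM range for readily degradable substrate |
| k3 (plasticizer) | d⁻¹ | 0.1 | in-situ calibration result |
| k3 (biomass_derived) | d⁻¹ | 0.02 | ranked between plasticizer and humic per the observed degradability ordering |
| k3 (humic) | d⁻¹ | 0.001 | near-inert donor; an order below the dead-cell pool |
| bH | d⁻¹ | 0.005 | in-situ calibration result (bH/k3 = 5 %) |
| KsS | g-C/dm³ | 0.01 | not identifiable from the available data; small relative to the in-situ TOC (≈0.19), i.e. near-saturated operation — explicit config, never hidden |
| KsNO3 | g-N/dm³ | 0.001 | same reasoning; in-situ nitrate ≈0.12 g-N/dm³ |
| x_yield | – | 0.5 | the growth-fraction assumption used throughout the data preparation |
| z_nc | g-N/g-C | 1.0 | measured 0.86, taken as 1 |
| f_recycle | – | 0.5 | the partition of dead-cell carbon between soluble and inert fractions is unmeasured; a symmetric default, surfaced in every config |

Default integrator tolerances are rtol = 1e-8, atol = 1e-12 (LSODA);
cheap at these problem sizes and sharp enough to make the closure
invariants meaningful. The right-hand side is evaluated on the state
clipped at zero (Monod rates vanish there, so the floor is consistent);
if the integrator undershoots zero by more than the tolerances can
explain, the run fails loudly rather than being repaired.

## Data preparation

The in-situ observables are not the model state. The chain implemented in
`denitkin.prep`:

1. cells per NarG copy calibrated on paired solution TNC/qPCR
   measurements (ratio of paired sums by default; per-sample geometric
   mean available);
2. total cells = solution count + biofilm qPCR × cells-per-copy ×
   biofilm mass per circulating volume (the latter is a required,
   experiment-specific config with no default);
3. TOC-per-cell factor = −x·ΔTOC/Δcells between two baseline samples,
   attributing fraction x (default 0.5) of the solution-TOC decline to
   growth; cell counts × factor give biomass carbon;
4. N/C = ΔNO₃-N / ΔTOC.

Baseline samples are explicit configuration (default: first
post-injection to last). The shipped reference tables are internally
inconsistent about which baselines produced the printed experiment-wide
row — the TOC change matches a third-sample baseline, the cell-count
change a fourth-sample baseline, nitrate and biomass the second — which is
why the selection is user-facing rather than hard-coded, and why the
shipped prepared dataset carries the printed row verbatim. Raw-table cell
counts per cm³ are likewise not relatable to the prepared per-dm³ column
by a single volume factor; the prepared table is treated as authoritative
and ingestion exposes `tnc_volume_factor` (default 1000). Measurement
sigmas are ingested and carried but not propagated — no uncertainty model
accompanies the data.

**Identifiability note.** The x-assumption attributes the whole TOC
decline to respiration + growth. When bH > 0 and f_recycle > 0 part of
the decline is offset by recycled dead-cell carbon, so the derived
TOC-per-cell factor absorbs a bias of order ∫bH·xB dt / ΔTOC. The
round-trip identity (synthetic tables → preparation → generating
trajectory) is therefore exact only for growth-only truths (bH = 0), and
that is how the round-trip tests are constructed. At the in-situ scale
(bH/k3 = 5 % over 30 d) the bias is a few percent.

## Calibration

No fitting criterion accompanies the published parameter values, so the
package defines one: weighted least squares with biomass residuals on the
log scale (the trajectory spans about a decade) and chemistry residuals
linear, normalized by the mean observed level; default weights 1 for
biomass and nitrate, 0 for TOC. All residual series are dimensionless and
of comparable size, so neither observable dominates.

Optimization is deterministic: L-BFGS-B in log10-parameter space from a
fixed 3×3 multiplicative start grid (×0.2, ×1, ×5) around the
fixed-parameter center, best start wins. Bounds default to
k3 ∈ [1e-3, 10] d⁻¹ and bH ∈ [1e-5, 1] d⁻¹, spanning literature values
for municipal activated sludge down to this system's slow rates.
Half-saturation constants are fixed by default: five or six time points
cannot constrain them, and fitting them is flagged as ill-determined.

Noise-free self-consistency (simulate at a truth, refit, recover ≤1 %)
holds across sampled truths; the multi-start grid is what makes it hold
when nitrate exhaustion renders the landscape multi-modal. Refitting the
actual field data does **not** reproduce (0.1, 0.005) exactly — the
published values' half-saturation constants and objective are unknown —
but the refit never does worse than the published set under this loss
(the published center is itself a start), landing at k3 ≈ 0.08 d⁻¹ with
bH at its lower bound: the death constant is genuinely ill-determined by
five points when biomass only grows.

## Synthetic data

`denitkin.synth` inverts the preparation relations to manufacture
raw-shaped tables from simulated trajectories: biomass → total cells (via
the TOC-per-cell factor) → solution/biofilm partition (default 0.9 on the
biofilm, as the prepared data imply biofilm ≫ solution) → counts and qPCR
signals; nitrate → mmol/dm³; donor pools → solution TOC. Shipped presets
mirror the in-situ scenario (plasticizer extract, sampling at days 0.9,
3.9, 8.9, 17/18, 31) and the in-vitro run matrix series A–E, using a
documented 0.5 g-C/g dry-mass inoculum conversion and 0.40 g-C/g for
glucose where the charge sheets give dry mass.

Noise: counts and qPCR copies get multiplicative lognormal noise with
unit mean and configured CV (defaults from the reported sigma/value
ratios: 0.14 for direct counts, 0.5 for qPCR); chemistry gets additive
Gaussian noise truncated at zero. Identical seed and configuration give
byte-identical tables.

What the generator does *not* emulate: community composition shifts,
qPCR amplification bias, staining bias in direct counts, biofilm spatial
structure, and the raw-vs-prepared unit inconsistencies of the real
tables. Passing round-trip tests therefore demonstrates internal
consistency of the pipeline, not fidelity of the preparation assumptions
to any real flow cell.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script use the experimental
scale throughout: 5–6 time points over ≤50 days, 1–4 donor pools, state
dimension ≤9. Property suites use 50 random scenarios for the closure
checks, a fixed-step Euler oracle at dt = 1e-4 d for integrator
cross-validation (agreement to 1e-3 relative), and 20 sampled truths for
recovery. Ties and degeneracies: zero biomass is an exact fixed point;
zero-delta datasets raise degenerate-input errors rather than returning
NaNs; reported derived constants are rounded to 3 significant figures
while full precision is retained internally.

## Known limitations

- No pH, temperature, salinity or water-activity dependence of rates.
- No nitrite/ammonia intermediate kinetics; systems where these
  accumulate need a different reduction chain.
- No spatial transport or biofilm structure; the flow cell is treated as
  well mixed with a static biofilm compartment.
- Parameter uncertainty is not quantified (point estimates only); the
  recovery experiment reports spread under synthetic noise, which is not
  a posterior.
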