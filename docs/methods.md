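# Methods

## The virtual specimen

The specimen is a one-dimensional tensile element of gauge length `L0`
(grip-to-grip) with constant initial cross-section `A` (`πr²` for
cylindrical organs, thickness × width for peels; Poisson thinning is not
modelled, matching the constant-area convention of stress–strain analysis).
Its constitutive model is the minimal one that exhibits every behaviour the
workflow must handle — instantaneous elasticity, between-step relaxation,
tapering creep, yield, grip slippage and brittle rupture:

* **Standard linear solid.** An equilibrium spring `E_inf` in parallel with
  a Maxwell branch (`E_1`, retardation time `tau`). Instantaneous modulus
  `E_inf + E_1`; a held step relaxes exponentially to `E_inf·ε`.
* **Lockhart/Bingham plastic element.** Irreversible strain accrues only
  above the yield threshold: `d eps_p/dt = phi · max(0, σ − σ_Y)`, with
  `phi` an extensibility in 1/(MPa·s). Under constant stress this gives
  constant creep after the viscous transient — the creep-rate *taper* seen
  in windowed rates comes from that transient plus the controller dynamics.
* **Coulomb-threshold grip slip.** Above a holding force `F_hold` the
  specimen slides within its tags at `slip_rate · (F − F_hold)` µm/s. Slip
  subtracts from tissue strain: `ε = (x_grip − x_slip)/L0`.
* **Brittle rupture.** When `σ ≥ σ_ult` the transmitted force drops to zero
  permanently. The tissue strain seen by the landmarks freezes at its
  rupture value (the broken halves stop following the grips) while the tags
  continue to track the actuator.
* **Tension-only.** Force is clamped at ≥ 0; tag mounting cannot push.

No claim is made that real hypocotyls or peels follow this law — it is a
stand-in with the right qualitative structure, and quantitative tests are
phrased as *parameter recovery*: feed the pipeline a specimen with known
`E_inf`, `σ_ult`, `σ_Y`, and check the analysis returns them.

### Integration

`evolve` applies the grip displacement as a step at the start of each
interval (the screw moves fast relative to `tau`), then advances the state
with a fixed-substep scheme: the viscous branch is updated with its exact
exponential solution, the slow plastic/slip variables with a symmetric
(Strang-style) split — half step, viscous update, half step with rates
re-evaluated. The substep is capped at `tau/50` and additionally at
`10⁻³ / (phi·(E_inf+E_1))` and `10⁻³ / (slip_rate·(E_inf+E_1)·A/L0)`, the
inverse stress-decay rates the plastic and slip elements induce; without
the rate-aware caps the splitting bias reaches a few tenths of a percent of
force in strongly yielding regimes. As configured, the integrator agrees
with a brute-force explicit-Euler reference to better than 0.03 % relative
force error on randomized parameter sets (bound asserted in tests: 0.1 %).
The scheme is unconditionally stable and uses no ODE-library dependency.

## The virtual instrument

* **Actuator.** Screw drive, default 1 mm pitch and 200 full steps per
  revolution: 5 µm per step, optionally microstepped. Position is stored as
  an integer step count (nanometres are derived, never accumulated), so
  there is no drift and unit round-trips are lossless. Travel-limit
  violations raise before any motion. Backlash is zero by default (an
  optional parameter exists for robustness experiments).
* **Load cell.** Reading = `F / gain_true + offset_true + N(0, noise_sd)`,
  clamped at capacity with a saturation flag (real amplifiers clip). The
  default `noise_sd` of 0.01 units at 1000 µN/unit gain gives ~10 µN RMS
  force noise, chosen to match the stated resolution of the 10 g
  parallel-beam cells this models; no measured noise spectrum exists, so
  white Gaussian noise is an assumption. Re-orienting the cell from the
  vertical calibration pose to the horizontal working pose shifts the
  offset (the arm's weight); the calibration workflow re-zeroes after
  mounting, and the tests verify the cancellation.
* **Camera.** 8-bit grayscale frames, dark features on a bright field
  (India-ink polarity): two full-height tags whose separation follows the
  actuator, a specimen band, and anti-aliased circular dots at the landmark
  positions (which follow *tissue* strain only). Gaussian pixel noise,
  default sd 2 grey levels. Fields of view and scales are configured per
  scenario; the presets use 5 µm/px, which with ~4 mm landmark separation
  makes 0.05 px centroid error ≈ 0.007 pp of strain.

All randomness in a bench derives from one seed through a `SeedSequence`,
so complete experiments are reproducible from their configuration.

## Controller

Ramp mode moves one step, waits a fixed stabilization time (time-based, not
force-derivative-based), averages `n` bridge samples at 100 Hz, captures a
snapshot, and appends a record; on completion the actuator auto-returns to
start, after a stop it stays put. A wait time of −1 blocks on a
confirmation callback per step (external cameras); with an auto-confirming
callback the log is identical to `wait=0`.

Creep mode approaches at a constant rate (default one step per second)
until the measured force reaches the threshold, then samples once per
control period (default 1 s) and, whenever the reading falls below
threshold − deadband (deadband default 1 % of threshold), steps until the
reading is back above threshold − deadband/2. Correcting to mid-band rather
than to the band edge matters: with a noisy single-sample stop rule the
true force routinely parks just outside the band. One reading per control
iteration serves both the control decision and the log record. The step
quantum must be small against the band for holding to be possible; the
creep preset pairs a soft specimen (~60 µN per microstep at divisor 32)
with a 5 mN threshold (±50 µN band). Rupture is never acted on during a
run — the controller records the collapse, reports it in the end status,
and leaves localisation to the analysis.

## Tracking

Detection: global Otsu threshold (manual override available), connected
components, an area filter that also rejects the big tag blobs, and an
intensity-weighted centroid per component for sub-pixel localisation.
Matching: frame-to-frame nearest neighbour under a displacement gate
(default ¼ of the smallest initial pair separation). The matcher counts
perfect matchings in the candidate graph: zero → a landmark was lost
(error naming the frame), more than one → ambiguous (error), exactly one →
safe greedy assignment. Failing loudly was chosen over heuristics because a
silent identity swap corrupts strain without any visible symptom.

Strain uses Euclidean centroid distance × pixel scale,
`ε = (d − d_ref)/d_ref × 100`. The grip pathway divides actuator
displacement by an explicit reference length; when diagnosing slip, both
pathways use the landmark pair's initial separation so their difference is
the slip strain. The raw grip-pathway convention (displacement over initial
actuator extension) is also supported, since published worked examples use
it.

## Analysis

* `σ = F/A` in MPa (µN/µm² identity), initial area throughout.
* Linear region: the contiguous window of fixed span maximising linear-fit
  R², excluding windows at or beyond a rupture-scale force collapse; ties
  break to the earliest start; a warning fires if the chosen region extends
  past 20 % strain. The initial toe loses naturally on R².
* `E = Δσ/Δε` between the region endpoints (two-point convention;
  least-squares slope available as an option).
* Rupture: first sample having dropped ≥ 50 % below the running maximum
  (`drop_frac` configurable; "sudden drop" is not quantified elsewhere, so
  0.5 is a declared default). Ultimate stress: peak force before that drop
  over the initial area — accurate to one ramp step of stress by
  construction.
* Yield onset: first post-region sample deviating below the extrapolated
  linear fit by more than a relative tolerance (default 5 %); tolerance 0
  degenerately flags the first numerical wiggle, documented as such.
* Creep rates: non-overlapping 300 s windows anchored at the record start,
  boundary positions linearly interpolated, rate = (end − start)/window.
* Slippage: slip = grip − landmark strain per step; verdict
  "slip-dominated" when, at the end of the evaluated span, slip exceeds the
  tissue strain; negative slip beyond a 0.5 pp noise tolerance flags the
  two pathways as inconsistent.

## Simulated study conditions

The presets in `microext.presets` fix the scenarios used by the demo, the
tests and the acceptance script:

| scenario | geometry | E_inf / E_1 (MPa) | tau (s) | σ_Y / σ_ult (MPa) | slip |
|---|---|---|---|---|---|
| hypocotyl | cylinder r=100 µm, L0=5 mm | 300 / 150 | 3 | 2.5 / 3.0 | above 40 mN, 10⁻⁶ µm/s/µN |
| onion peel | 50 µm × 4 mm, L0=5 mm | 10 / 5 | 5 | 1.0 / 2.0 | above 100 mN |
| creep test | 50 µm × 4 mm, L0=5 mm | 6 / 4 | 5 | 0.015 / 1.0 | optional, above 3 mN |

Magnitudes are chosen to be representative of the tissues this class of
instrument is used on (hundreds of MPa for hypocotyls, ~10 MPa for
epidermal peels, few-MPa ultimate stresses, mN-scale forces) and to
exercise every code path: the hypocotyl ramp passes through elastic
loading, slip onset, yield and rupture in under a hundred steps. The
hypocotyl slip compliance is set so the ramp *outruns* the combined
slip + plastic flow and actually breaks the sample; at double the
compliance the stress asymptotes just below `σ_ult` and a ramp-to-break
never ends.

What the generator emulates: step-synchronized force/position/snapshot
logs, sensor noise and saturation, slip-divergent strain pathways,
relaxation between steps, constant-force creep, rupture. What it does not:
heterogeneous strain along the specimen, water-transport poroelasticity, 3D
geometry, vibration/EMI structure in the noise, backlash (off by default),
junction-style bright-line landmarks (dots only). Passing tests therefore
demonstrate that the *software* recovers known ground truth through a
realistic acquisition chain — not that real tissue follows the model.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to finish in
seconds while leaving the statistics meaningful: 20 randomized specimens ×
30-step ramps for modulus recovery (worst error ≈ 0.2 % against the 5 %
bound), 5 seeds for the slip-bias direction, ~20 min of simulated creep per
creep run, 200 seeds × 1000 samples for calibration recovery, 10 parameter
sets × 10-step schedules against a 20 000-substep Euler reference.

## Known limitations

* Yield-onset detection needs the stress to actually plateau within the
  recorded range; with very low extensibility the 5 % deviation may not be
  reached before rupture and the onset is reported as absent.
* The linear-region R² criterion assumes the curve contains a genuinely
  linear stretch longer than the span; on a short curve that is all toe or
  all plateau the selected window is the least-bad one, not a certified
  elastic region.
* `ultimate_stress` reports the last *recorded* pre-drop force; with coarse
  steps it understates the true threshold by up to one step's stress
  increment.
* The tracker requires a constant landmark count; occlusion or merging
  (dots closer than ~2 px) is an error, not a recoverable condition.
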