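# Methods

## Model and assumptions

The core object is the two-variable dimensionless IFFL

    dr/dτ = β·Φ(τ) − (γ_R · h(x) + γ_o) · r,      h(x) = xⁿ/(xⁿ + 1),
    dx/dτ = β·Φ(τ) − x,

driven by a square pulse train Φ with k pulses of duration D, period T and
start time τ₀. Both species are produced at the same maximal rate β; the
inhibitor x turns over with unit rate (it sets the time scale); the
reporter r is degraded basally at rate γ_o and, through the ultrasensitive
Hill term h, at up to γ_R once x crosses its half-activation threshold
x = 1. The phenomenological Hill form is taken as given — no mechanistic
derivation of the ultrasensitivity (oligomerization, titration, cascades)
is modelled. First-order kinetics are assumed for all endogenous
degradation. The dimensional model on molecular numbers [X], [R] is the
same structure with rates k₁, k₂, d_x, d_R, d_Ro and threshold K_x; the
map x = [X]/K_x, r = [R]·k₂/(k₁·K_x), τ = t·d_x carries one model onto the
other and is exposed as `nondimensionalize`.

Default parameters follow the reference operating point used throughout
the package: β = 1.2, γ_R = 10, γ_o = 0, n = 110, T = 4, D = 1, τ₀ = 1,
unit pulse amplitude. β slightly above 1 is the interesting regime — large
enough that a sustained input drives x over threshold (temporal
adaptation), small enough that short pulses do not.

## Input signals

Pulse windows are half-open [start, end): the end instant of a pulse
carries Φ = 0. The half-sine waveform places one arch
amplitude·sin(π(τ−start)/D) in each window, so Φ ≥ 0 and the window
bookkeeping is shared with the square case. A sustained input is a single
step of length D. `sustained_equivalent_amplitude` returns the time
average of Φ over [0, horizon]; the horizon is an explicit argument
because a finite pulse train has no unique "mean level" — the equal-mean
comparison fixture uses the conventional sustained level 0.337 for the
D = 1, T = 4 train rather than the infinite-horizon duty-cycle mean 0.3.

## Numerical integration

The forcing is discontinuous at every pulse edge, so trajectories are
integrated piecewise between consecutive edges, restarting the solver at
each edge with the previous endpoint. Edges are therefore sampled exactly
and the solver never steps across a discontinuity. Within segments LSODA
is used (switching to a stiff method automatically): at n = 110 the
induced-degradation term switches on over a ~1 % change in x, which makes
the reporter equation locally very stiff whenever x approaches 1. Defaults:
rtol = 1e−8, atol = 1e−10, stored sample spacing 0.02 (endpoint readouts
are linear interpolations between stored samples; at these spacings the
interpolation error is orders of magnitude below the solver tolerance).
Trial steps may take x infinitesimally negative; the Hill argument is
clamped at zero for evaluation. Initial conditions default to rest
(x = r = 0), matching all packaged scenarios. The default horizon is one
quiet period after the last pulse.

The Hill function is evaluated in log space as logistic(n·ln x): xⁿ
overflows double precision already at x ≈ 1.3 for n = 110, while the
logistic form is exact and bounded for any x ≥ 0.

## Calibration curves and classification

For a calibration curve the train template's T, D, τ₀, waveform and
amplitude are held fixed while k runs over ks (default 1–10); every
simulation is read at the same fixed τ_E, by default τ₀ + max(ks)·T, which
always falls in the quiet window after the last pulse of the largest
train. (The readout policy is configurable: with γ_o > 0 the absolute
readouts depend on τ_E, though the classification in the packaged
scenarios does not.) The line is fitted by ordinary least squares *with*
an intercept, since for γ_o > 0 the readout sequence is a partial
geometric sum that need not pass through the origin.

Raw OLS renders a perfectly flat response as R² = 0/0. Two degenerate
rules make "failure" well-defined and scale-aware: R² is reported as 0
when the readouts' total sum of squares falls below 1e−6·(mean readout)²,
or when the fitted |slope| falls below 1e−3·β·D·amplitude (one thousandth
of the ideal per-pulse increment). Classification: high_quality iff
R² ≥ 0.99, failure iff R² = 0 after the degenerate rules, low_quality
otherwise.

## Closed-form analytics

Because x is decoupled and linear, its per-cycle extrema obey the exact
recursion given in the README; all analytics derive from it. The peak
sequence is geometric with ratio e^−T and limit β(1−e^−D)/(1−e^−T), so the
finite/infinite decision for the counting capacity is made exactly from
the limit rather than by an iteration cap, and a finite capacity beyond
the iterated window is recovered from the closed form of the geometric
sequence. "Counting fails" is the strict inequality x_peak > 1; equality
is treated as not-failed. Border root-finds (duration at which the border
equality holds for given β, T) use bracketed Brent iteration to 1e−10 on
a monotone function. The closed-form endpoint r(τ_E) is valid while
induced degradation never fires; its γ_o → 0 limit is the proportional
law k·β·D.

## Parameter sweeps and the border

Each sweep cell runs a full calibration curve and stores R² and slope.
Cells with D ≥ T (or D ≤ 0) are not valid pulse trains and are stored as
NaN/"invalid"; β = 0 and γ_R = 0 cells are evaluated normally and fall out
of the degenerate rules where appropriate. Sweep evaluation is cell-wise
independent and deterministic.

At finite period the true counting border is the indefinite-counting
equality (1−e^−D)/(1−e^−T) = 1/β, not its long-period limit
D* = ln(β/(β−1)); at T = 4 the two differ by 0.088 at β = 1.2 (1.704 vs
1.792) and by less at larger β. The border-agreement checks therefore
compare the simulated high-quality→loss flip against the exact finite-T
border at a 0.05 duration step, and against D* at a 0.1 step — the scale
of the long-period approximation error. Packaged sweep fixtures use a
0.25 grid step to keep a full map to ~10³ simulations; finer grids are a
CLI flag away and change nothing but resolution.

## Stochastic model

The Langevin simulator works on molecular numbers with fixed-step
Euler–Maruyama: each species' deterministic rate gains an additive
Gaussian white-noise term of amplitude ξ (increment std ξ·√dt per step),
and species are clamped at zero from below. Additive noise of fixed
amplitude is the operative choice here: it leaves the *relative*
perturbation large when production rates are ~5 molecules per unit time
and negligible at ~500, which is exactly the molecular-number dependence
the counting mechanism is probed for. Noise proportional to √(propensity)
with the same ξ would grow with molecule number and suppress the
high-copy-number recovery of counting. Default dt = D/100; a stability
guard rejects dt·d_x ≥ 0.5 and dt > D/10. Replicate readouts are averaged
before fitting; all randomness flows from one recorded seed through
`numpy.random.Generator`, so runs are exactly reproducible.

## Architecture variants

The variant right-hand sides are defined by this package as the minimal
realizations of the described architectures (state order: inputs first,
reporter last):

* **positive_feedback** (x, r): the threshold moves into production of x,
  dx/dτ = β·Φ + α·h(x) − x, and degradation of R is bilinear,
  dr/dτ = β·Φ − (γ_R·x + γ_o)·r. Once a long pulse drives x past the
  threshold the feedback latches x near α and the bilinear term removes R;
  short pulses leave the latch unarmed and counting proceeds.
* **delay_inhibition** (x1, x, r): a first-order stage
  dx1/dτ = β′·Φ − δ·x1 feeds dx/dτ = β″·x1 − x; the reporter is produced
  directly from the input at rate β″ and degraded as in the base model.
* **delay_activation** (x, r1, r): dr1/dτ = β′·Φ − γ_R1·r1 feeds
  dr/dτ = β″·r1 − (γ_R·h(x) + γ_o)·r, with x driven directly by the input
  at rate β″.
* **repression** (x, r): dr/dτ = β·Φ·(1 − h(x)) − γ_o·r with no induced
  degradation; for large β the reporter gains a fixed early-pulse
  increment while x is still sub-threshold, and long pulses leave x above
  threshold across the short OFF phase, freezing R.

Each variant reproduces the qualitative counting/resetting split of its
scenario (counting at D = 1, loss at the long duration) under the caption
parameter sets packaged as fixtures.

## What the packaged scenarios do and do not show

All inputs are idealized square or half-sine trains with identical pulses;
real pathway inputs have jitter in timing, amplitude and shape, and the
only stochasticity modelled is additive white noise on the two-species
dimensional model. Extrinsic noise, bursting, cell-to-cell parameter
variation, resource coupling and embedding of the motif in a larger
network are all outside the model, so a passing suite shows the *mechanism*
behaves as the analytics predict under these idealized conditions, not
that any particular biological pathway counts pulses. The closed-form
analytics apply to the base architecture only; the variants are simulated,
not solved.

## Problem sizes

Calibration curves use 1–10 pulses (1–4 for the ideal-counting scenario),
horizon ≈ 45 time units; sweeps in the test suite use a handful of cells
and shortened pulse ranges, with full maps behind the fixtures/CLI;
stochastic runs use dt = 0.01 over the same horizon. These sizes keep any
scenario at seconds on one core while leaving the measured quantities
well inside their tolerance of the asymptotic values.
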