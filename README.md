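# ifflkit — pulse counting by incoherent feedforward loops

Many signalling pathways tell oscillatory inputs apart from sustained ones:
pulsed p53 arrests the cell cycle where sustained p53 triggers apoptosis,
pulsed cAMP drives amoeba development where continuous cAMP stalls it. A
recurring circuit behind this decoding is the incoherent feedforward loop
(IFFL): an input S activates both an output R and an inhibitor X of that
output. `ifflkit` simulates and analyses the regime in which such a loop
acts as a *pulse counter* — the endpoint output level grows stepwise and
linearly with the number of input pulses — and maps the kinetic conditions
under which counting succeeds, saturates, or fails.

## The model

In dimensionless form (concentrations in units of the inhibitor's
half-activation threshold K_x, time in units of its turnover 1/d_x):

    dr/dτ = β·Φ(τ) − (γ_R · xⁿ/(xⁿ+1) + γ_o) · r
    dx/dτ = β·Φ(τ) − x

Φ(τ) is a square (or half-sine) train of k pulses of duration D and period
T starting at τ₀ = 1; β is the maximal synthesis rate of X and R, γ_R the
maximal induced degradation rate of R by X, γ_o the basal degradation rate
of R, and n ≈ 110 makes the induced degradation switch-like. While each
pulse leaves the peak of x below the threshold x = 1, R keeps everything it
produced and the readout r(τ_E) at a fixed time τ_E is proportional to the
number of pulses (r = k·β·D for γ_o = 0). Once a pulse drives x past the
threshold, R is wiped each cycle and counting fails. The per-cycle peaks of
x obey an exact recursion,

    x_basal,i = x_peak,i−1 · e^−(T−D),   x_peak,i = β − (β − x_basal,i)·e^−D,

which yields the counting capacity n_c (first peak above 1), the
indefinite-counting condition (1−e^−D)/(1−e^−T) < 1/β and, in the long
period limit, the counting border β = 1/(1−e^−D).

Counting quality is measured by an ordinary least-squares fit of r(τ_E)
against k: R² ≥ 0.99 is high-quality counting, a flat response is reported
as R² = 0 (failure), anything between is low-quality (saturating) counting.
The package also includes the dimensional (molecular-number) model with its
non-dimensionalization map, a Langevin simulator with additive noise of
amplitude ξ, and the alternative architectures (positive-feedback
ultrasensitivity, delayed inhibition or activation arm, repression-based
threshold).

## Worked example

A slightly unstable reporter (γ_o = 0.01) driven by 1–10 short pulses:

```sh
$ ifflkit calibrate --beta 1.2 --gamma-r 10 --gamma-o 0.01 -T 4 -D 1 --ks 1-10 -o demo
tauE: 41.0
slope: 0.9912023984814006
intercept: -0.4138569362375355
r_squared: 0.997449859102976
counting_class: high_quality
artifacts written to demo
```

Each additional pulse raises the endpoint reporter by ≈ 0.99 (slightly
below the ideal β·D = 1.2 because of basal decay), and the calibration line
explains 99.7 % of the readout variance — the loop counts these pulses with
high quality. The per-k readouts are in `demo/calibration.csv`, the full
configuration and summary in `demo/meta.json`. The same analysis with
`--gamma-o 0.05` drops R² to 0.94 (low quality), and with `-D 3` the
response is flat and reported as failure.

The closed-form side of the toolkit:

```sh
$ ifflkit capacity --beta 1.2 -T 4 -D 1.75
nc: 2
indefinite: False
```

i.e. with D = 1.75 the inhibitor's second peak already crosses the
threshold: the loop can count at most two such pulses.

Every figure-scale scenario (time courses, calibration curves, β×D and
γ_R×D sweep maps, border curves, stochastic runs, architecture variants) is
packaged as a named fixture; `ifflkit fixtures` lists them and
`ifflkit run <name> -o outdir` re-runs one end to end. The same
functionality is available from Python via `ifflkit.calibration_curve`,
`ifflkit.integrate`, `ifflkit.counting_capacity`, etc.

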