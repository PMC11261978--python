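# chemosense

Information rates in bacterial chemosensing: how close does a swimming
*Escherichia coli* cell come to the physical limit set by counting the
ligand molecules that reach its receptors?

A cell climbing a shallow exponential attractant gradient (log-slope `g`)
needs to estimate the behaviorally relevant signal
`s(t) = d log c/dt = g·vx(t)` from what it can observe. The first physically
observable quantity is the stochastic molecule arrival rate `r(t)` at the
receptor patch (Poisson, mean `kD·c(t)` with `kD = 4Dl`); the quantity the
cell actually has is its CheA kinase activity `a(t)`, a linearly filtered,
adapted, and internally noisy transform of `r`. For each observer the
sensing accuracy is a transfer-entropy (equivalently predictive-information)
rate, which for these Gaussian channels depends only on the stationary
posterior variance of `s` given the channel's past:

    İ = (1/τ_v) · ρ²/(1−ρ²),      ρ² = 1 − σ²_{s|past}/σ_s².

`chemosense` computes both rates exactly by stationary Kalman–Bucy (causal
Wiener) filtering, together with the closed-form small-signal theory
(`İ_r ≈ γ_r/4τ_v` with `γ_r = 2r₀g²σ_v²τ_v³`, and its kinase analogue in
`γ_a = G_r²r₀²g²σ_v²τ_v/D_n`), an agent-based run-and-tumble simulator with
Poisson arrivals and kinase dynamics, the single-cell parameter-inference
procedures (velocity-autocorrelation fits, step-response MAP fits,
Bayesian OU-noise fits, MWC gain fit, robust population medians), and
seeded synthetic-data generators that stand in for the tracking and FRET
experiments. It is intended for quantitative biologists studying sensory
limits and for anyone who wants the full chain from molecule-counting
physics to gradient-climbing behavior in testable code.

The headline result this package reproduces: with population-median
parameters, the kinase encoding carries `η = İ_a/İ_r ≈ 0.014` of the
physical limit at a 1 µM background in vanishing gradients — two orders of
magnitude below the limit — rising only to roughly a tenth of it in the
steepest measured gradient (`g = 0.4 mm⁻¹`). Chemosensing is limited by
internal signaling noise, not by molecule-arrival physics, and simulated
cells steering by kinase activity climb gradients slower than ideal
molecule-counting cells by exactly the predicted factor
`v_a/v_r = √(İ_a/İ_r)`.

## Worked example

```python
from chemosense import (PhysicalConstants, SwimSignalParams, KinaseParams,
                        info_summary, nats_to_bits)

const = PhysicalConstants(kD=1.2e5)               # 1/(s·uM), = 4·D·l
swim = SwimSignalParams(sigma_v2=146.0, tau_v=1.19, g=0.1, c0=1.0)
kin = KinaseParams(G_r=2.28 / 1.2e5, tau_2=7.4, D_n=8.1e-4, tau_n=8.7)

s = info_summary(swim, kin, const)
print(f"gamma_r = {s.gamma_r:.3f}")
print(f"physical limit  I_r = {s.I_r:.4f} nats/s ({nats_to_bits(s.I_r):.4f} bits/s)")
print(f"kinase encoding I_a = {s.I_a:.5f} nats/s ({nats_to_bits(s.I_a):.5f} bits/s)")
print(f"eta = I_a/I_r = {s.eta:.4f}")
```

prints

```
gamma_r = 0.590
physical limit  I_r = 0.0463 nats/s (0.0669 bits/s)
kinase encoding I_a = 0.00173 nats/s (0.00250 bits/s)
eta = I_a/I_r = 0.0374
```

Read: in a `g = 0.1 mm⁻¹` gradient at 1 µM aspartate, an ideal
molecule-counting sensor on this swimming cell could acquire ~0.07 bits/s
about the signal; the kinase activity encodes ~0.0025 bits/s, under 4% of
the limit. The dimensionless arrival SNR `γ_r = 0.59` is far below the
16/3 threshold the classic single-run argument would demand — yet simulated
cells at these parameters still climb the gradient, because drift
accumulates inaccurate tumble decisions over many runs.

The CLI exposes the same machinery: `chemosense theory` writes
`İ_r/g², İ_a/g², η` tables over a background grid, `chemosense
simulate-tracks | fit-swim`, `simulate-fret | fit-response`,
`make-fixtures | fit-noise`, `fit-mwc` run the inference pipelines on
simulated or user-supplied CSV data, and `chemosense reproduce-fig4` runs
the estimator-trace and drift-speed experiments.

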