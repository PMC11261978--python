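# Methods

`chemosense` quantifies how much behaviorally relevant information a
chemotaxing bacterium extracts from its chemical environment, and compares
two observers of the same swimming cell: an ideal sensor that counts every
ligand molecule arriving at the receptor patch, and the cell's own CheA
kinase activity. This note records the models, the numerical machinery, the
synthetic-data conditions, and the choices made where the design was open.

## Signal model

In a static exponential gradient with log-slope `g` (accepted in 1/mm at all
interfaces, converted to 1/um internally), the behaviorally relevant signal
is the rate of change of log concentration along the trajectory,
`s(t) = g*vx(t)`, where `vx` is the up-gradient velocity. In shallow
gradients the run-tumble statistics are unperturbed at leading order, so `s`
is approximated as a stationary Gaussian (Ornstein-Uhlenbeck) process with
variance `g^2*sigma_v^2` and correlation time `tau_v`. The typical-cell
values `sigma_v^2 = 146 (um/s)^2`, `tau_v = 1.19 s` are used throughout; the
packaged config reuses them at all three backgrounds (0.1, 1, 10 uM) because
the background dependence is weak and only the 1 uM values are available to
the package. Baseline kinase activity `a0 = 0.3` and median run fraction
`P_run = 0.85` are package defaults chosen as typical single-cell FRET and
tracking values; neither enters the information rates.

## The two observation channels

**Molecule arrivals.** A perfectly absorbing disk of radius `l = 60 nm`
(the receptor array) in a ligand field with diffusivity `D = 800 um^2/s`
captures molecules at rate `kD*c` with `kD = 4*D*l ~ 1.16e5 /s/uM`
(the rounded literature value 1.2e5 is used wherever measured parameters are
quoted against it). For `r0*tau_v >> 1` the Poisson arrival process is
approximated by a Gaussian: observation `y_r = r - r0 = r0*L + sqrt(r0)*xi`,
where `L` is the log-concentration deviation (`dL/dt = s`) and `xi` unit
white noise. The absorbing-sensor convention is used; a sensor that cannot
distinguish rebinding events would sit lower by an O(1) factor.

**Kinase activity.** Linear response with perfect adaptation:
`a = a0 - K_r * (r - r0) + eta_n`, kernel
`K_r(t) = G_r[(1/tau_1)e^(-t/tau_1) - (1/tau_2)e^(-t/tau_2)]` for `t >= 0`,
equal-area lobes. The fast time is taken as `tau_1 = 0` exactly: the fast
lobe becomes a delta function, which routes the instantaneous response to
arrival noise into a white observation-noise component of intensity
`G_r^2*r0`, correlated with the process noise driving the adaptation filter
state `F` (`dF = (-F/tau_2 + r - r0)dt`). This avoids a stiff small-`tau_1`
regularization and slightly overestimates the kinase information rate.
Internal noise `eta_n` is OU with diffusivity `D_n` and correlation time
`tau_n` (stationary variance `D_n*tau_n`). A channel with a finite `tau_1`
would have a noise-free observation (no stationary filter) and is rejected
explicitly.

## Information rates

Both channels are linear-Gaussian, so the transfer-entropy rate from signal
to observations equals the predictive-information rate and depends only on
the stationary posterior variance `P_ss` of `s` given the channel's past:
with `rho2 = 1 - P_ss/sigma_s^2`,

    Idot = (1/tau_v) * rho2 / (1 - rho2)   [nats/s],

which reduces to `rho2/tau_v` for small `rho2`. `P_ss` solves the stationary
Kalman-Bucy (causal Wiener) Riccati equation with the correlated
process/observation noise term.

**Solver.** The production solver discretizes the channel exactly (van Loan)
at `dt = tau_min/5000`, absorbs the cross term, and runs a
structure-preserving doubling (SDA) iteration to the stabilizing fixed
point, followed by Richardson extrapolation in `dt` (the averaged-observation
discretization error is O(dt)). States are rescaled to O(1) and the
observation to unit noise before solving; the weakly observed, marginally
stable log-concentration mode makes generic dense ARE solvers (QZ-based)
return non-stabilizing branches on this problem, while doubling covers the
slow mode's horizon in ~60 iterations. Two independent checks are built in:

* an exact closed form for the arrival channel, derived by hand from the
  2-state Riccati system: `rho2_rs = (u/(2+u))^2`,
  `u = sqrt(1 + 2*sqrt(gamma_r)) - 1`, where
  `gamma_r = 2*r0*g^2*sigma_v^2*tau_v^3`. Expanding gives
  `rho2 ~ gamma_r/4` with leading relative correction `-2*sqrt(gamma_r)` —
  so the familiar small-signal form is 2% high already at `gamma_r = 1e-4`
  and ~18% high at `1e-2`;
* a plain fixed-point discrete Riccati recursion on a fine grid
  (`dt = 1e-3*tau_v`), the brute-force arbiter, with an iteration floor
  covering the slow mode's closed-loop relaxation.

The `sqrt(gamma_r)` correction also sets how fast `eta = Idot_a/Idot_r`
becomes gradient-independent: at `g = 1e-3 /mm` the residual g-dependence is
~1.4%, at `1e-4 /mm` below 0.2%. "g -> 0" quantities are evaluated at
`g = 1e-3 /mm` with a convergence check against `1e-4 /mm` at 2% tolerance.

**Small-signal closed forms.** The kinase-channel form
`(1/4 tau_v) * gamma_r/(1 + gamma_r/gamma_a)^2` (with
`gamma_a = G_r^2*r0^2*g^2*sigma_v^2*tau_v/D_n`) is provided in two algebraic
readings (`form="algebraic"` and `form="interpolating"`, the latter
`(1/4 tau_v)*gamma_a*gamma_r/(gamma_a+gamma_r)` which additionally matches
the internal-noise-dominated limit `gamma_a/(4 tau_v)`). They agree when the
SNRs are well separated; the engine is authoritative for all quantitative
results. At the 1 uM medians the engine gives `eta = 0.0142` in the
vanishing-gradient limit, and a maximum of `eta = 0.12` at
(c0 = 1 uM, g = 0.4/mm) over the measured grid — roughly a tenth of the
physical limit at one-significant-figure precision, versus two orders of
magnitude below it in shallow gradients.

## Run-and-tumble simulation

Agents run at constant speed, reorient by rotational diffusion
(`D_rot = 0.062 rad^2/s`) during runs, tumble at a base rate into pauses of
mean duration `tumble_duration_mean` with zero velocity, and exit tumbles
into a direction drawn from a von Mises-Fisher (3-D) or von Mises (2-D)
distribution whose concentration is solved from the configured mean cosine
(0.33 by default). The default configuration
(`speed = 23.35 um/s`, `run_rate = 1.135 /s`, `tumble_duration_mean =
0.155 s`) was calibrated once, by fitting the ensemble vx autocorrelation,
to reproduce the typical-cell values `sigma_v^2 ~ 146 (um/s)^2`,
`tau_v ~ 1.19 s`, `P_run ~ 0.85`; it is then frozen. Motion uses
`dt = 10 ms`; arrival counts are drawn per motion step (Poisson counts over
10 ms are distributionally identical to aggregated 1 ms draws). The
gradient is an exact exponential profile, so position feeds back on the
observed concentration mechanically; in the shallow regime this feedback is
negligible for the signal statistics.

**Chemotaxis readouts.** The tumble rate is modulated linearly by a
standardized causal readout, `lambda = lambda0*(1 - beta*z)` clipped at
zero, `beta = 0.25`. For the ideal cell `z` is the stationary causal filter
estimate of `s` from binned arrivals; for the kinase-limited cell, the
causal estimate from simulated activity (same arrival stream plus internal
noise). A raw readout option (`readout="activity"`, the standardized
instantaneous activity deviation) is retained, but at the integration step
its variance is dominated by the white arrival-noise component, so it does
not approximate the optimal decoder that the drift-ratio prediction
`v_a/v_r = sqrt(Idot_a/Idot_r)` presumes; the causal-estimate readouts are
the default experimental surface. Drift is the cell-and-time-averaged `vx`
after a 20 s burn-in, with the SEM over cells.

## Inference procedures

* **Run-fraction binning:** trajectories with at least two detected tumbles
  are kept; cells within +/-0.01 of the (optionally reweighted) median
  `P_run` form the analysis bin. The diffusivity-bias reweighting is
  exposed as a per-cell weight hook, uniform by default — a documented
  fidelity gap.
* **Velocity autocorrelation:** per-cell `V_i(t)`, duration-weighted
  average, SEM from the weighted between-cell spread.
* **Exponential fit:** Gaussian likelihood over lags in `[2*delta_t, 10 s]`
  with log-uniform priors; MAP by Nelder-Mead in log space, uncertainties as
  1.4826*mad of affine-invariant ensemble MCMC draws. Because the lag
  errors of an autocorrelation are strongly correlated, the posterior
  spread understates replicate scatter; the package's recovery tests follow
  the tracking protocol and spread fits over replicate sub-experiments
  (`mcmc=False` fast path).
* **Step-response fit:** up and down block averages fit jointly
  (pooled, SEM-weighted) to the double-exponential step solution with
  parameters (G, tau_1, tau_2, a0); a fitted `tau_1` below half the
  sampling interval is unidentifiable and pinned to the delta-lobe
  convention.
* **Noise fit:** exact scalar Kalman marginal likelihood of baseline + OU +
  white measurement noise (numba-jitted recursion), log-uniform priors with
  `tau_n` bounded below by the sampling interval (an OU faster than the
  sampling is indistinguishable from measurement noise); MAP + MCMC spread.
  A significant linear trend (slope > 3 sigma with AR(1)-inflated errors)
  flags non-stationarity.
* **Population summary:** medians across cells with variance
  `(1.4826*mad(theta_MAP))^2/N + sum_k sigma_k^2/N^2` (cell-to-cell spread
  plus mean single-cell uncertainty).
* **MWC gain fit:** `kD*G_r(c0) = G_inf/(c0 + K_i)` fit by least squares on
  log gains (equalizing weight across the order-of-magnitude gain range),
  deterministic multi-start Nelder-Mead over a log grid of `K_i`. The three
  measured gains {3.2, 2.28, 0.251} yield `K_i` near 0.81 uM, though the
  printed medians are rounded, so exact reproduction is not expected; the
  MWC-implied gain at 1 uM (1.93/kD) likewise differs from the directly
  measured 2.28/kD.
* **Error propagation:** first-order, central finite differences (relative
  step 1e-5), correlations neglected. Propagating the printed parameter
  SEMs through the engine gives an `eta` uncertainty of order 2e-3.

MCMC settings (16 walkers, 500-600 steps, 150-200 burn-in) are sized for
smooth 2-4 parameter posteriors at desk runtimes; MAP values are independent
of the MCMC seed, and only the robust spread of draws is contractual.

## Synthetic data

Three seeded generators emulate the experiment types, with per-cell
parameters drawn log-normally around the medians (default CV 0.3, an
assumption — the real phenotype distribution is not specified beyond
"a range"):

* **Swimming populations:** run-tumble trajectories; default schedule
  draws exponential track durations (mean 7.6 s, 2 s floor) until the total
  time reaches 2.7e4 s.
* **Step responses:** 7.5 s pre + 30 s stimulus blocks, 10 up and 10 down,
  sampled at 0.75 s; kernel step solution plus OU noise plus white
  measurement noise, with the default measurement noise set so a single
  block has response SNR ~ 2 (so block averaging matters); saturating
  bookends anchor the activity normalization. A 25 s block-display variant
  exists in some descriptions of this protocol; the schedule here follows
  the stimulus timing and is configurable.
* **Noise traces:** 1200 s at 1 Hz, baseline + OU + measurement noise,
  optional filtered-arrival floor.

What the generators do **not** emulate: photobleaching, focal drift,
segmentation errors, ligand consumption, tracker misdetection of tumbles
(run/tumble labels are emitted directly; a pluggable detector interface
accepts external labels). Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise models, not robustness
to those instrument artifacts.

## Problem sizes in the test suite

The acceptance-level checks run at desk scale: drift simulations use 200
cells x 500 s per condition at five gradient steepnesses; recovery uses 20
replicates per experiment type with 6 cells (or 6 sub-experiments of ~600 s
total tracking) each. Recovery targets are the sample medians of the drawn
cells (estimator consistency), with the population-summary uncertainty;
swim recovery uses the Markovian motility limit (no rotational diffusion,
no persistence, instantaneous tumbles) where the target values are exact,
and a homogeneous population, since with instantaneous tumbles the
run-fraction binning cannot separate speed phenotypes.

## Known limitations

* Only the `tau_1 = 0` kinase channel is representable in the engine; the
  finite-`tau_1` channel is noise-free at high frequency and needs a
  different observation model.
* The Gaussian approximation of arrivals requires `r0*tau_v >> 1`; a
  warning fires below 10. Exact point-process filtering is out of scope.
* Nonstationary backgrounds (time-varying `c0`) and the full information
  spectrum beyond the rate at zero forecasting lag are not modeled.
* Absolute drift speeds depend on the tumble-modulation rule and gain,
  which are implementation choices; only the ratio between readouts is
  compared against theory.
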