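"""Seeded generators emulating the three single-cell experiment types.

Each generator draws per-cell parameters log-normally around population
medians (configurable coefficient of variation), produces data through the
physical simulator or the kinase response model, and returns the ground
truth alongside, so the whole inference pipeline can be exercised and its
calibration checked without any experimental data.

The three experiment types:

* swimming populations: run-tumble trajectories for velocity statistics;
* step-response series: FRET-style activity during repeated small up/down
  concentration steps around a background, with saturating-stimulus
  bookends that define the activity normalization;
* noise traces: long constant-background activity recordings for the slow
  internal-noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .params import KinaseParams, PhysicalConstants, SwimSignalParams
from .simulate import (ArrivalSeries, RunTumbleConfig, Trajectory,
                       simulate_ensemble, simulate_kinase)
from .theory import step_response

__all__ = ["GeneratorSpec", "StepResponseData", "gen_swim_population",
           "gen_step_response_experiment", "gen_noise_traces"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of one synthetic experiment.

    ``truth`` holds the population-median parameters; ``cv`` the log-normal
    cell-to-cell coefficient of variation; ``timing`` overrides the
    experiment schedule defaults (documented per generator).
    """

    experiment: str                   # swim | step_response | noise_trace
    n_cells: int = 10
    seed: int = 0
    cv: float = 0.3
    timing: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in ("swim", "step_response", "noise_trace"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def _lognormal_around(median: float, cv: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws with the given median and coefficient of variation."""
    if cv == 0.0 or median == 0.0:
        return np.full(n, median)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return median * np.exp(sigma * rng.standard_normal(n))


def gen_swim_population(spec: GeneratorSpec,
                        config: RunTumbleConfig | None = None
                        ) -> tuple[list[Trajectory], dict[str, Any]]:
    """Run-tumble trajectories for a variable population of cells.

    Timing defaults follow the tracking protocol: mean trajectory duration
    ~7.6 s (exponential, with a 2 s detection floor) and at least 2.7e4 s of
    total trajectory time; scale down with ``timing={'total_time': ...,
    'mean_duration': ...}`` for desk-sized runs. Per-cell speed and run rate
    are drawn log-normally around the configured medians.
    """
    cfg = config or RunTumbleConfig()
    rng = np.random.default_rng(spec.seed)
    timing = {"mean_duration": 7.6, "min_duration": 2.0,
              "total_time": 2.7e4, **spec.timing}
    durations: list[float] = []
    total = 0.0
    while total < timing["total_time"]:
        d = max(rng.exponential(timing["mean_duration"]), timing["min_duration"])
        durations.append(d)
        total += d
    n_tracks = len(durations)
    speeds = _lognormal_around(cfg.speed, spec.cv, n_tracks, rng)
    run_rates = _lognormal_around(cfg.run_rate, spec.cv, n_tracks, rng)
    trajectories: list[Trajectory] = []
    # batch trajectories of similar length together for vectorized stepping
    order = np.argsort(durations)
    batch = 128
    for start in range(0, n_tracks, batch):
        idx = order[start:start + batch]
        dur = max(durations[j] for j in idx)
        trajs = simulate_ensemble(
            cfg, dur, len(idx), seed=int(rng.integers(2 ** 31)),
            speed=speeds[idx], run_rate=run_rates[idx])
        for j, traj in zip(idx, trajs):
            n = int(round(durations[j] / cfg.dt))
            trajectories.append(Trajectory(
                times=traj.times[:n], positions=traj.positions[:n],
                vx=traj.vx[:n], state=traj.state[:n]))
    truth = {"config": cfg, "speeds": speeds, "run_rates": run_rates,
             "n_tracks": n_tracks, "total_time": total,
             "p_run_nominal": cfg.p_run_nominal}
    return trajectories, truth


@dataclass
class StepResponseData:
    """One cell's step-response recording."""

    t_block: np.ndarray       # s, within-block time, stimulus onset at 0
    up_blocks: np.ndarray     # (n_blocks, n_samples) activity
    down_blocks: np.ndarray
    fret_min: float
    fret_max: float
    delta_r_rel: float        # relative arrival-rate step size


def gen_step_response_experiment(spec: GeneratorSpec,
                                 kin: KinaseParams | None = None,
                                 swim: SwimSignalParams | None = None,
                                 constants: PhysicalConstants | None = None
                                 ) -> tuple[list[StepResponseData], dict[str, Any]]:
    """FRET-style step-response series around a background concentration.

    Schedule defaults: 7.5 s pre-stimulus + 30 s stimulus per block, 10 up
    and 10 down blocks, samples every 0.75 s. Responses come from the
    response-kernel step solution with per-cell (G, tau_2) plus OU internal
    noise and white measurement noise; saturating-stimulus bookends provide
    the FRET normalization anchors.
    """
    kin = kin or KinaseParams(G_r=2.28 / 1.2e5)
    swim = swim or SwimSignalParams()
    constants = constants or PhysicalConstants(kD=1.2e5)
    rng = np.random.default_rng(spec.seed)
    timing = {"pre": 7.5, "post": 30.0, "sample": 0.75, "n_blocks": 10,
              "delta_c_rel": 0.05, "meas_noise_sd": None, **spec.timing}
    dt = timing["sample"]
    t_block = np.arange(-timing["pre"], timing["post"], dt)
    r0 = constants.arrival_rate(swim.c0)
    delta_r_rel = timing["delta_c_rel"]  # relative rate step == relative conc step
    step_amp = kin.G_r * r0 * delta_r_rel
    if step_amp > 0.5 * kin.a0:
        import warnings
        warnings.warn("step size drives the activity excursion beyond the "
                      "linear regime", stacklevel=2)
    gains = _lognormal_around(kin.G_r, spec.cv, spec.n_cells, rng)
    tau2s = _lognormal_around(kin.tau_2, spec.cv, spec.n_cells, rng)
    # default measurement noise: single-block response SNR ~ 2
    meas_sd = timing["meas_noise_sd"]
    if meas_sd is None:
        meas_sd = step_amp / 2.0
    cells: list[StepResponseData] = []
    phin = np.exp(-dt / kin.tau_n)
    innov_sd = np.sqrt(kin.noise_variance * (1.0 - phin ** 2))
    for j in range(spec.n_cells):
        kin_j = KinaseParams(G_r=gains[j], tau_2=tau2s[j], tau_1=kin.tau_1,
                             D_n=kin.D_n, tau_n=kin.tau_n, a0=kin.a0)
        mean_up = kin.a0 + step_response(t_block, kin_j, delta_r_rel * r0)
        mean_down = kin.a0 + step_response(t_block, kin_j, -delta_r_rel * r0)
        blocks = []
        for mean in (mean_up, mean_down):
            b = np.empty((timing["n_blocks"], t_block.size))
            for i in range(timing["n_blocks"]):
                n_state = rng.normal(0.0, np.sqrt(kin.noise_variance))
                ou = np.empty(t_block.size)
                for k in range(t_block.size):
                    ou[k] = n_state
                    n_state = phin * n_state + innov_sd * rng.standard_normal()
                b[i] = mean + ou + meas_sd * rng.standard_normal(t_block.size)
            blocks.append(b)
        cells.append(StepResponseData(
            t_block=t_block.copy(), up_blocks=blocks[0], down_blocks=blocks[1],
            fret_min=0.0, fret_max=1.0, delta_r_rel=delta_r_rel))
    truth = {"G_r": gains, "tau_2": tau2s, "kin": kin, "r0": r0,
             "G_times_kD": gains * constants.kD, "meas_noise_sd": meas_sd,
             "delta_r_rel": delta_r_rel}
    return cells, truth


def gen_noise_traces(spec: GeneratorSpec, kin: KinaseParams | None = None,
                     swim: SwimSignalParams | None = None,
                     constants: PhysicalConstants | None = None,
                     include_arrival_noise: bool = False
                     ) -> tuple[list[np.ndarray], dict[str, Any]]:
    """Long constant-background activity traces with slow OU noise.

    Defaults follow the recording protocol: ~1200 s per cell sampled at
    1.0 s. Traces are a0 + OU(D_n, tau_n) + white measurement noise;
    optionally the filtered-arrival noise floor is added by simulating the
    kinase response to constant-background Poisson arrivals.
    """
    kin = kin or KinaseParams(G_r=2.28 / 1.2e5)
    swim = swim or SwimSignalParams()
    constants = constants or PhysicalConstants(kD=1.2e5)
    rng = np.random.default_rng(spec.seed)
    timing = {"duration": 1200.0, "sample": 1.0, "meas_noise_sd": 0.01,
              **spec.timing}
    dt = timing["sample"]
    n = int(round(timing["duration"] / dt))
    Dns = _lognormal_around(kin.D_n, spec.cv, spec.n_cells, rng)
    tauns = _lognormal_around(kin.tau_n, spec.cv, spec.n_cells, rng)
    traces: list[np.ndarray] = []
    for j in range(spec.n_cells):
        phin = np.exp(-dt / tauns[j])
        var_n = Dns[j] * tauns[j]
        innov_sd = np.sqrt(var_n * (1.0 - phin ** 2))
        n_state = rng.normal(0.0, np.sqrt(var_n))
        ou = np.empty(n)
        for k in range(n):
            ou[k] = n_state
            n_state = phin * n_state + innov_sd * rng.standard_normal()
        trace = kin.a0 + ou + timing["meas_noise_sd"] * rng.standard_normal(n)
        if include_arrival_noise:
            c = np.full(n, swim.c0)
            arr = ArrivalSeries(
                times=np.arange(n) * dt,
                counts=rng.poisson(constants.kD * swim.c0 * dt, n).astype(float),
                c_of_t=c, dt=dt, r0=constants.arrival_rate(swim.c0))
            kin_j = KinaseParams(G_r=kin.G_r, tau_2=kin.tau_2, tau_1=kin.tau_1,
                                 D_n=0.0, tau_n=kin.tau_n, a0=0.0)
            _, resp, _ = simulate_kinase(arr, kin_j,
                                         seed=int(rng.integers(2 ** 31)))
            trace = trace + resp
        traces.append(trace)
    truth = {"D_n": Dns, "tau_n": tauns, "a0": kin.a0,
             "meas_noise_sd": timing["meas_noise_sd"], "dt": dt}
    return traces, truth
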