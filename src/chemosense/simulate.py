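"""Agent-based run-and-tumble simulation with molecule arrivals and kinase dynamics.

Cells swim at constant speed during runs, reorient by rotational diffusion
continuously and by tumbles of finite duration with a prescribed mean
reorientation cosine. In an exponential ligand gradient c(x) = c0*exp(g*x)
the up-gradient velocity vx generates the behaviorally relevant signal
s = g*vx. Molecule arrivals are Poisson with rate kD*c(t); kinase activity
follows the adapted linear response to arrival-rate deviations plus slow
internal OU noise. Chemotaxis is simulated by modulating the tumble rate
with a standardized causal readout of either channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0, i1

from . import gauss_info
from .params import (KinaseParams, PhysicalConstants, SwimSignalParams,
                     PER_MM_TO_PER_UM)

__all__ = [
    "RunTumbleConfig", "Trajectory", "ArrivalSeries", "DriftResult",
    "simulate_run_tumble", "simulate_ensemble", "signal_from_trajectory",
    "concentration_along", "simulate_arrivals", "simulate_kinase",
    "simulate_chemotaxis",
]


@dataclass(frozen=True)
class RunTumbleConfig:
    """Run-and-tumble motility parameters.

    Defaults are calibrated so that the ensemble vx statistics reproduce the
    typical-cell values sigma_v^2 ~ 146 (um/s)^2, tau_v ~ 1.19 s and
    P_run ~ 0.85 used throughout the package.
    """

    speed: float = 23.35              # um/s
    run_rate: float = 1.135           # 1/s, tumble initiation rate
    tumble_duration_mean: float = 0.155  # s
    directional_persistence: float = 0.33  # mean cosine of tumble reorientation
    rot_diffusion: float = 0.062      # rad^2/s during runs
    dimensions: int = 3
    dt: float = 0.01                  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.dimensions not in (2, 3):
            raise ValueError("dimensions must be 2 or 3")
        if not -1.0 <= self.directional_persistence <= 1.0:
            raise ValueError("directional_persistence is a mean cosine in [-1, 1]")
        if self.tumble_duration_mean < 0:
            raise ValueError("tumble_duration_mean must be >= 0 (0 means "
                             "single-step reorientations)")
        scales = [1.0 / self.run_rate if self.run_rate > 0 else np.inf,
                  self.tumble_duration_mean if self.tumble_duration_mean > 0 else np.inf]
        if self.dt > min(scales) / 5.0:
            raise ValueError(f"dt={self.dt} too coarse for the run/tumble time scales")
        if self.rot_diffusion * self.dt > 0.05:
            warnings.warn("dt is coarse relative to rotational diffusion",
                          stacklevel=2)

    @property
    def p_run_nominal(self) -> float:
        """Run-time fraction implied by the mean run and tumble durations."""
        mean_run = 1.0 / self.run_rate if self.run_rate > 0 else np.inf
        if not np.isfinite(mean_run):
            return 1.0
        return mean_run / (mean_run + self.tumble_duration_mean)


@dataclass
class Trajectory:
    """Single-cell trajectory on a uniform grid."""

    times: np.ndarray        # s
    positions: np.ndarray    # (n, dim) um
    vx: np.ndarray           # um/s, up-gradient (x) velocity
    state: np.ndarray        # bool, True during runs

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def p_run(self) -> float:
        return float(np.mean(self.state)) if self.state.size else np.nan

    @property
    def n_tumbles(self) -> int:
        """Number of distinct tumble episodes (run->tumble transitions)."""
        s = self.state.astype(int)
        return int(np.sum((s[:-1] == 1) & (s[1:] == 0)))


@dataclass
class ArrivalSeries:
    """Binned molecule-arrival observations."""

    times: np.ndarray        # s, left bin edges
    counts: np.ndarray       # molecules per bin (ints in poisson mode)
    c_of_t: np.ndarray       # uM
    dt: float                # s
    r0: float                # 1/s, background arrival rate

    @property
    def rates(self) -> np.ndarray:
        """Arrival rate samples, counts/dt (1/s)."""
        return self.counts / self.dt


@dataclass(frozen=True)
class DriftResult:
    """Chemotactic drift estimate for one condition."""

    g: float                 # 1/mm
    vd: float                # um/s
    sem: float               # um/s
    n_cells: int
    t_total: float           # s of simulated (post-burn-in) time
    readout: str
    clipped_fraction: float  # fraction of steps with the tumble rate clipped at 0


# ---------------------------------------------------------------------------
# reorientation distributions

def _kappa_from_mean_cosine(alpha: float, dimensions: int) -> float:
    """Concentration parameter of the reorientation distribution.

    3-D: von Mises-Fisher with mean cosine coth(k) - 1/k; 2-D: von Mises
    with mean cosine I1(k)/I0(k). alpha = 0 means uniform reorientation.
    """
    if abs(alpha) < 1e-12:
        return 0.0
    if alpha < 0:
        raise NotImplementedError("retrograde persistence not supported")
    if dimensions == 3:
        f = lambda k: (1.0 / np.tanh(k) - 1.0 / k) - alpha
    else:
        f = lambda k: i1(k) / i0(k) - alpha
    return brentq(f, 1e-8, 1e4)


def _sample_cos_vmf(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample cos(theta) from the 3-D von Mises-Fisher polar angle."""
    u = rng.random(n)
    if kappa == 0.0:
        return 2.0 * u - 1.0
    # inverse CDF of p(w) ~ exp(kappa w) on [-1, 1]
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _reorient3(e: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """New unit vectors at vMF-distributed angles around the old ones."""
    n = e.shape[0]
    w = _sample_cos_vmf(kappa, n, rng)
    # random unit vector orthogonal to e
    xi = rng.standard_normal((n, 3))
    xi -= (np.sum(xi * e, axis=1, keepdims=True)) * e
    norm = np.linalg.norm(xi, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    perp = xi / norm
    s = np.sqrt(np.clip(1.0 - w ** 2, 0.0, None))
    return w[:, None] * e + s[:, None] * perp


def _sample_vm_angle(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample reorientation angles from a von Mises distribution (2-D)."""
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, n)
    return rng.vonmises(0.0, kappa, n)


class _MotilityState:
    """Vectorized run-tumble state for an ensemble of cells."""

    def __init__(self, config: RunTumbleConfig, n_cells: int,
                 rng: np.random.Generator,
                 speed: np.ndarray | None = None,
                 run_rate: np.ndarray | None = None,
                 tumble_duration_mean: np.ndarray | None = None):
        self.cfg = config
        self.n = n_cells
        self.rng = rng
        d = config.dimensions
        self.speed = np.broadcast_to(
            config.speed if speed is None else speed, (n_cells,)).astype(float)
        self.run_rate = np.broadcast_to(
            config.run_rate if run_rate is None else run_rate, (n_cells,)).astype(float)
        self.tumble_mean = np.broadcast_to(
            config.tumble_duration_mean if tumble_duration_mean is None
            else tumble_duration_mean, (n_cells,)).astype(float)
        self.kappa = _kappa_from_mean_cosine(config.directional_persistence, d)
        if d == 3:
            e = rng.standard_normal((n_cells, 3))
            self.e = e / np.linalg.norm(e, axis=1, keepdims=True)
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi, n_cells)
            self.e = np.column_stack([np.cos(theta), np.sin(theta)])
        self.running = rng.random(n_cells) < config.p_run_nominal
        self.x = np.zeros((n_cells, d))

    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """Advance one dt; returns (vx, running) before the move."""
        cfg, rng = self.cfg, self.rng
        dt = cfg.dt
        run = self.running
        # rotational diffusion during runs
        if cfg.rot_diffusion > 0 and np.any(run):
            sig = np.sqrt(2.0 * cfg.rot_diffusion * dt)
            if cfg.dimensions == 3:
                xi = rng.standard_normal((self.n, 3)) * sig
                xi -= np.sum(xi * self.e, axis=1, keepdims=True) * self.e
                e_new = self.e + xi
                e_new /= np.linalg.norm(e_new, axis=1, keepdims=True)
                self.e = np.where(run[:, None], e_new, self.e)
            else:
                dth = rng.standard_normal(self.n) * sig
                c, s = np.cos(dth), np.sin(dth)
                ex = c * self.e[:, 0] - s * self.e[:, 1]
                ey = s * self.e[:, 0] + c * self.e[:, 1]
                self.e = np.where(run[:, None],
                                  np.column_stack([ex, ey]), self.e)
        v = np.where(run[:, None], self.speed[:, None] * self.e, 0.0)
        vx = v[:, 0].copy()
        self.x += v * dt
        # transitions (evaluated after the move, effective next step)
        u = rng.random(self.n)
        start_tumble = run & (u < self.run_rate * dt)
        with np.errstate(divide="ignore"):
            exit_prob = np.where(self.tumble_mean > 0,
                                 dt / np.maximum(self.tumble_mean, 1e-300), 1.0)
        end_tumble = (~run) & (u < exit_prob)
        if np.any(end_tumble):
            idx = np.where(end_tumble)[0]
            if cfg.dimensions == 3:
                self.e[idx] = _reorient3(self.e[idx], self.kappa, rng)
            else:
                ang = _sample_vm_angle(self.kappa, idx.size, rng)
                c, s = np.cos(ang), np.sin(ang)
                ex = c * self.e[idx, 0] - s * self.e[idx, 1]
                ey = s * self.e[idx, 0] + c * self.e[idx, 1]
                self.e[idx] = np.column_stack([ex, ey])
        self.running = np.where(start_tumble, False,
                                np.where(end_tumble, True, run))
        return vx, run

    def modulated_step(self, tumble_rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Like step() but with per-cell tumble initiation rates."""
        saved = self.run_rate
        self.run_rate = tumble_rate
        out = self.step()
        self.run_rate = saved
        return out


def simulate_ensemble(config: RunTumbleConfig, duration: float, n_cells: int,
                      seed: int | None = None, **param_overrides
                      ) -> list[Trajectory]:
    """Simulate ``n_cells`` independent run-tumble trajectories.

    ``param_overrides`` may supply per-cell arrays for ``speed``,
    ``run_rate`` and ``tumble_duration_mean`` (cell-to-cell variability).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_steps = int(round(duration / config.dt))
    if n_steps == 0 or n_cells == 0:
        return [Trajectory(times=np.zeros(0), positions=np.zeros((0, config.dimensions)),
                           vx=np.zeros(0), state=np.zeros(0, dtype=bool))
                for _ in range(n_cells)]
    st = _MotilityState(config, n_cells, rng, **param_overrides)
    vx = np.empty((n_steps, n_cells))
    run = np.empty((n_steps, n_cells), dtype=bool)
    pos = np.empty((n_steps, n_cells, config.dimensions))
    for k in range(n_steps):
        pos[k] = st.x
        vx[k], run[k] = st.step()
    times = np.arange(n_steps) * config.dt
    return [Trajectory(times=times.copy(), positions=pos[:, j],
                       vx=vx[:, j], state=run[:, j])
            for j in range(n_cells)]


def simulate_run_tumble(config: RunTumbleConfig, duration: float,
                        seed: int | None = None) -> Trajectory:
    """Simulate a single run-tumble trajectory of the given duration."""
    return simulate_ensemble(config, duration, 1, seed=seed)[0]


def signal_from_trajectory(traj: Trajectory, g: float) -> np.ndarray:
    """Behaviorally relevant signal s(t) = g*vx(t), with g in 1/mm (s in 1/s)."""
    return g * PER_MM_TO_PER_UM * traj.vx


def concentration_along(traj: Trajectory, g: float, c0: float) -> np.ndarray:
    """Ligand concentration c(t) = c0*exp(g*x(t)) along the trajectory (uM)."""
    return c0 * np.exp(g * PER_MM_TO_PER_UM * traj.positions[:, 0])


def simulate_arrivals(c_of_t: np.ndarray, constants: PhysicalConstants,
                      dt: float, seed: int | None = None,
                      mode: str = "poisson", c0: float | None = None
                      ) -> ArrivalSeries:
    """Molecule arrival counts per bin for a concentration time series.

    ``poisson`` mode draws counts with mean kD*c(t)*dt; ``gaussian`` mode
    returns the matched Gaussian approximation (mean kD*c*dt, variance
    r0*dt). ``c0`` defaults to the series mean and sets r0.
    """
    c = np.asarray(c_of_t, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    mean_counts = constants.kD * c * dt
    if np.any(mean_counts > 1e12):
        raise ValueError("kD*c*dt overflows sensible count sizes; reduce dt")
    if c0 is None:
        c0 = float(np.mean(c))
    r0 = constants.arrival_rate(c0)
    if mode == "poisson":
        counts = rng.poisson(mean_counts).astype(float)
    elif mode == "gaussian":
        counts = mean_counts + np.sqrt(r0 * dt) * rng.standard_normal(c.shape)
    else:
        raise ValueError("mode must be 'poisson' or 'gaussian'")
    times = np.arange(c.size) * dt
    return ArrivalSeries(times=times, counts=counts, c_of_t=c, dt=dt, r0=r0)


def simulate_kinase(arrivals: ArrivalSeries, kin: KinaseParams,
                    seed: int | None = None,
                    clip_warn_fraction: float = 0.01
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Kinase activity responding to an arrival series, plus internal noise.

    Integrates the adaptation filter driven by arrival-rate deviations and
    adds internal OU noise with the exact exponential-decay update. Returns
    ``(a_clipped, a_raw, clipped_fraction)``: the activity clipped to [0, 1]
    for output, the unclipped linear-model activity, and the fraction of
    samples clipped. A large clipped fraction means the linear model left
    its domain of validity and triggers a warning.
    """
    dt = arrivals.dt
    if kin.tau_1 != 0.0 and kin.tau_1 < 2.0 * dt:
        raise ValueError("tau_1 must be 0 or at least 2*dt to be resolved")
    rng = np.random.default_rng(seed)
    r = arrivals.rates
    dr = r - arrivals.r0
    n_steps = r.size

    # adaptation filter(s): exact one-pole update for piecewise-constant input,
    # F[k+1] = phi*F[k] + tau*(1-phi)*dr[k], run through an IIR filter
    from scipy.signal import lfilter

    def _one_pole(tau: float, x: np.ndarray) -> np.ndarray:
        phi = np.exp(-dt / tau)
        return lfilter([0.0, tau * (1.0 - phi)], [1.0, -phi], x)

    F2 = _one_pole(kin.tau_2, dr)
    if kin.tau_1 == 0.0:
        fast = dr
    else:
        fast = _one_pole(kin.tau_1, dr) / kin.tau_1
    response = -kin.G_r * fast + (kin.G_r / kin.tau_2) * F2

    # internal OU noise, exact discrete update n[k+1] = phi*n[k] + innov
    phin = np.exp(-dt / kin.tau_n)
    var_n = kin.D_n * kin.tau_n
    innov_sd = np.sqrt(var_n * (1.0 - phin ** 2))
    n0 = rng.normal(0.0, np.sqrt(var_n)) if var_n > 0 else 0.0
    eps = innov_sd * rng.standard_normal(n_steps)
    eps[0] = n0  # stationary initial condition propagated by the same pole
    noise = lfilter([1.0], [1.0, -phin], eps)

    a_raw = kin.a0 + response + noise
    a_clipped = np.clip(a_raw, 0.0, 1.0)
    clipped = float(np.mean(a_clipped != a_raw))
    if clipped > clip_warn_fraction:
        warnings.warn(
            f"{100 * clipped:.1f}% of kinase samples clipped to [0, 1]: the "
            "linear response model is leaving its validity range", stacklevel=2)
    return a_clipped, a_raw, clipped


# ---------------------------------------------------------------------------
# chemotaxis with information-limited readouts

def _discrete_filter_matrices(channel, dt):
    disc = gauss_info.discretize(channel, dt)
    P = gauss_info._sda_filter_dare(disc.Ad, disc.Qd, disc.C, disc.Rd, disc.Md)
    Sigma = float(disc.C @ P @ disc.C) + disc.Rd
    Kbar = (disc.Ad @ P @ disc.C + disc.Md) / Sigma
    PC = P @ disc.C
    P_filt = P - np.outer(PC, PC) / Sigma
    gain_f = PC / Sigma
    return disc.Ad, disc.C, Kbar, gain_f, P_filt


def simulate_chemotaxis(config: RunTumbleConfig, swim: SwimSignalParams,
                        kin: KinaseParams, constants: PhysicalConstants,
                        readout: str, duration: float, n_cells: int,
                        seed: int | None = None,
                        modulation_gain: float = 0.25,
                        burn_in: float = 20.0) -> DriftResult:
    """Drift speed of cells whose tumble rate follows a causal signal readout.

    Each cell's tumble initiation rate is lambda(t) = lambda0*(1 - beta*z(t))
    clipped at zero, where z is the standardized readout:

    * ``"arrival"``: the causal optimal estimate of s from molecule arrivals
      (an ideal cell that counts molecules);
    * ``"kinase"``: the causal optimal estimate of s from kinase activity
      (a cell limited to its internal encoding);
    * ``"activity"``: the raw standardized kinase deviation -(a - a0).

    The modulation gain beta is kept small so the response stays in the
    shallow-signal regime where drift is linear in the readout correlation.
    """
    if readout not in ("arrival", "kinase", "activity"):
        raise ValueError("readout must be 'arrival', 'kinase' or 'activity'")
    if swim.c0 <= 0:
        raise ValueError("chemotaxis simulation needs a positive background")
    rng = np.random.default_rng(seed)
    dt = config.dt
    g_um = swim.g_per_um
    r0 = constants.arrival_rate(swim.c0)
    lam0 = config.run_rate

    n_steps = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))
    st = _MotilityState(config, n_cells, rng)

    use_kinase = readout in ("kinase", "activity")
    if readout == "arrival":
        ch = gauss_info.build_arrival_channel(swim, constants)
    elif readout == "kinase":
        ch = gauss_info.build_kinase_channel(swim, kin, constants)
    if readout != "activity":
        Ad, C, Kbar, gain_f, P_filt = _discrete_filter_matrices(ch, dt)
        i_s = ch.s_index
        est_var = max(ch.sigma_s2 - P_filt[i_s, i_s], 1e-300)
        est_sd = np.sqrt(est_var)
        xhat = np.zeros((n_cells, ch.n_states))
    else:
        # stationary std of the binned activity deviation
        est_sd = np.sqrt(kin.noise_variance + kin.G_r ** 2 * r0 / dt)

    if use_kinase:
        phi2 = np.exp(-dt / kin.tau_2)
        phin = np.exp(-dt / kin.tau_n)
        innov_sd = np.sqrt(kin.noise_variance * (1.0 - phin ** 2))
        F2 = np.zeros(n_cells)
        n_state = rng.normal(0.0, np.sqrt(kin.noise_variance), n_cells)

    z = np.zeros(n_cells)
    vx_sum = np.zeros(n_cells)
    n_kept = 0
    clipped = 0
    for k in range(n_steps):
        lam = lam0 * (1.0 - modulation_gain * z)
        clipped += int(np.sum(lam < 0.0))
        np.clip(lam, 0.0, None, out=lam)
        vx, running = st.modulated_step(lam)
        if k >= n_burn:
            vx_sum += vx
            n_kept += 1
        c = swim.c0 * np.exp(g_um * st.x[:, 0])
        counts = rng.poisson(constants.kD * c * dt)
        dr = counts / dt - r0
        if use_kinase:
            da = -kin.G_r * dr + (kin.G_r / kin.tau_2) * F2 + n_state
            F2 = phi2 * F2 + kin.tau_2 * (1.0 - phi2) * dr
            n_state = phin * n_state + innov_sd * rng.standard_normal(n_cells)
        if readout == "activity":
            z = -da / est_sd
        else:
            y = dr if readout == "arrival" else da
            innov = y - xhat @ C
            s_filt = xhat[:, i_s] + gain_f[i_s] * innov
            xhat = xhat @ Ad.T + innov[:, None] * Kbar[None, :]
            z = s_filt / est_sd

    frac_clipped = clipped / (n_steps * n_cells)
    if frac_clipped > 0.05:
        warnings.warn(
            f"tumble rate clipped at zero in {100 * frac_clipped:.1f}% of "
            "steps; reduce modulation_gain", stacklevel=2)
    vx_mean = vx_sum / max(n_kept, 1)
    vd = float(np.mean(vx_mean))
    sem = float(np.std(vx_mean, ddof=1) / np.sqrt(n_cells)) if n_cells > 1 else np.nan
    return DriftResult(g=swim.g, vd=vd, sem=sem, n_cells=n_cells,
                       t_total=n_kept * dt * n_cells, readout=readout,
                       clipped_fraction=frac_clipped)
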