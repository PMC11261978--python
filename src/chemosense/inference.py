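"""Parameter estimation from trajectory and kinase-activity data.

Mirrors the measurement pipeline used on single-cell tracking and FRET
data: cells are binned by run-time fraction; velocity autocorrelations are
duration-weighted, fit with decaying exponentials; single-cell step
responses and slow-noise traces are fit by maximizing Gaussian-likelihood
posteriors with log-uniform priors, with MCMC-sampled uncertainties; and
population medians carry a robust two-term uncertainty combining
cell-to-cell spread with single-cell estimation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import emcee
import numpy as np
from scipy.optimize import minimize

from .simulate import Trajectory

__all__ = [
    "CellEstimate", "PopulationSummary", "prun_select",
    "velocity_autocorrelation", "fit_exponential_autocorr",
    "fit_step_response", "normalize_activity", "fit_noise_params",
    "population_summary", "fit_mwc", "robust_sigma", "median_uncertainty",
]

MAD_TO_SD = 1.4826  # matches the standard deviation for Gaussian samples


def robust_sigma(samples: np.ndarray) -> float:
    """Outlier-robust spread 1.4826*mad of a sample set."""
    samples = np.asarray(samples, dtype=float)
    return MAD_TO_SD * float(np.median(np.abs(samples - np.median(samples))))


@dataclass
class CellEstimate:
    """Single-cell MAP estimates with posterior-sample uncertainties."""

    theta_map: dict[str, float]
    sigma_theta: dict[str, float]
    n_obs: int
    samples: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for k, v in self.sigma_theta.items():
            if v is not None and v < 0:
                raise ValueError(f"sigma_theta[{k}] must be >= 0")


@dataclass
class PopulationSummary:
    """Population-median parameters with the two-term robust uncertainty."""

    theta_median: dict[str, float]
    sigma_median: dict[str, float]
    n_cells: int


def median_uncertainty(theta_maps: np.ndarray, sigma_cells: np.ndarray) -> float:
    """Variance of a population-median estimate.

    sigma^2 = (1/N)*(1.4826*mad(theta_MAP))^2 + (1/N^2)*sum_k sigma_k^2:
    the first term is cell-to-cell variation, the second the mean
    contribution of single-cell estimation error. Returns the standard
    error (square root).
    """
    theta_maps = np.asarray(theta_maps, dtype=float)
    sigma_cells = np.asarray(sigma_cells, dtype=float)
    n = theta_maps.size
    if n < 2:
        raise ValueError("population summary needs at least 2 cells")
    var = (robust_sigma(theta_maps) ** 2 / n
           + float(np.sum(sigma_cells ** 2)) / n ** 2)
    return float(np.sqrt(var))


def population_summary(cell_estimates: Sequence[CellEstimate]) -> PopulationSummary:
    """Median parameters over cells with the robust two-term uncertainty."""
    if len(cell_estimates) < 2:
        raise ValueError("population summary needs at least 2 cells")
    keys = list(cell_estimates[0].theta_map)
    med, sig = {}, {}
    for k in keys:
        maps = np.array([c.theta_map[k] for c in cell_estimates])
        sigs = np.array([c.sigma_theta.get(k, 0.0) or 0.0 for c in cell_estimates])
        med[k] = float(np.median(maps))
        sig[k] = median_uncertainty(maps, sigs)
    return PopulationSummary(theta_median=med, sigma_median=sig,
                             n_cells=len(cell_estimates))


# ---------------------------------------------------------------------------
# swimming statistics

def prun_select(trajectories: Sequence[Trajectory], window: float = 0.01,
                weights: Callable[[Trajectory], float] | None = None
                ) -> tuple[list[Trajectory], float]:
    """Cells in the median run-fraction bin.

    Keeps trajectories with at least two detected tumbles, computes the
    population-median P_run (optionally reweighted per cell to correct for
    diffusivity-dependent detection bias; uniform by default), and returns
    the trajectories whose P_run lies within ``window`` of the median.
    """
    kept = [t for t in trajectories if t.n_tumbles >= 2]
    if not kept:
        raise ValueError("no trajectory has two or more detected tumbles")
    pruns = np.array([t.p_run for t in kept])
    w = np.array([1.0 if weights is None else weights(t) for t in kept])
    order = np.argsort(pruns)
    cum = np.cumsum(w[order])
    median = float(pruns[order][np.searchsorted(cum, 0.5 * cum[-1])])
    selected = [t for t, p in zip(kept, pruns) if abs(p - median) <= window]
    if not selected:
        raise ValueError("median P_run bin is empty")
    return selected, median


def velocity_autocorrelation(trajectories: Sequence[Trajectory],
                             max_lag: float = 10.0, delta_t: float | None = None
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Duration-weighted average vx autocorrelation over cells.

    Per cell, V_i(t) = <vx(t')vx(t'+t)>; cells are averaged weighted by
    trajectory duration. Returns (lags, V, sem) where the SEM is the
    weighted between-cell spread. Trajectories shorter than the maximum lag
    contribute only their available lags.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    dt = float(np.diff(trajectories[0].times[:2])[0]) if delta_t is None else delta_t
    n_lags = int(round(max_lag / dt)) + 1
    acc = np.zeros(n_lags)
    acc_w = np.zeros(n_lags)
    acc2 = np.zeros(n_lags)
    count = np.zeros(n_lags)
    for traj in trajectories:
        v = traj.vx
        n = v.size
        if n < 2:
            continue
        m = min(n_lags, n)
        # biased-normalization correlation: divide by the full sample count
        corr = np.correlate(v, v, mode="full")[n - 1:n - 1 + m]
        norm = n - np.arange(m)
        vi = corr / norm
        w = traj.duration
        acc[:m] += w * vi
        acc_w[:m] += w
        acc2[:m] += w * vi ** 2
        count[:m] += 1
    if not np.any(acc_w > 0):
        raise ValueError("all trajectories too short for the requested lags")
    valid = acc_w > 0
    V = np.full(n_lags, np.nan)
    sem = np.full(n_lags, np.nan)
    V[valid] = acc[valid] / acc_w[valid]
    var_between = acc2[valid] / acc_w[valid] - V[valid] ** 2
    with np.errstate(invalid="ignore"):
        sem[valid] = np.sqrt(np.clip(var_between, 0.0, None)
                             / np.maximum(count[valid], 1))
    lags = np.arange(n_lags) * dt
    return lags, V, sem


def _map_then_mcmc(log_post, x0_log, n_walkers=16, n_steps=500, n_burn=150,
                   seed=0, labels=None):
    """MAP by Nelder-Mead in log-parameter space, then a short ensemble MCMC.

    Returns (theta_map, sigma_theta, samples) as dicts keyed by ``labels``;
    uncertainties are the robust spread 1.4826*mad of the posterior draws.
    """
    x0_log = np.asarray(x0_log, dtype=float)
    neg = lambda x: -log_post(x)
    res = minimize(neg, x0_log, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    xmap = res.x
    ndim = xmap.size
    rng = np.random.default_rng(seed)
    p0 = xmap + 1e-3 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    theta = np.exp(xmap)
    draws = np.exp(chain)
    labels = labels or [f"theta{i}" for i in range(ndim)]
    theta_map = {k: float(v) for k, v in zip(labels, theta)}
    sigma = {k: robust_sigma(draws[:, i]) for i, k in enumerate(labels)}
    samples = {k: draws[:, i] for i, k in enumerate(labels)}
    return theta_map, sigma, samples


def fit_exponential_autocorr(lags: np.ndarray, V: np.ndarray, sem: np.ndarray,
                             fit_window: tuple[float, float] | None = None,
                             delta_t: float = 0.05, seed: int = 0,
                             keep_samples: bool = False,
                             mcmc: bool = True) -> CellEstimate:
    """Fit V(t) = sigma_v^2 * exp(-t/tau_v) over the window [2*delta_t, 10 s].

    Gaussian likelihood with per-lag SEMs and log-uniform priors; MAP point
    estimate plus MCMC-sampled robust uncertainties. The per-lag errors of
    an empirical autocorrelation are strongly correlated across lags, so the
    posterior spread understates replicate-to-replicate scatter; experiment
    replication (fit each replicate, spread over replicates) is the honest
    uncertainty for these two parameters. ``mcmc=False`` skips the sampling
    and returns only the MAP values (for replicate-based workflows).
    """
    lags = np.asarray(lags, float)
    V = np.asarray(V, float)
    sem = np.asarray(sem, float)
    lo, hi = fit_window if fit_window is not None else (2.0 * delta_t, 10.0)
    mask = (lags >= lo) & (lags <= hi) & np.isfinite(V) & np.isfinite(sem)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable lags in the fit window")
    t, y, s = lags[mask], V[mask], np.maximum(sem[mask], 1e-12)
    if not np.any(y > 0):
        raise ValueError("autocorrelation is non-positive everywhere in the window")

    def log_post(x):
        if np.any(np.abs(x) > 50):
            return -np.inf
        sv2, tau = np.exp(x)
        model = sv2 * np.exp(-t / tau)
        return -0.5 * float(np.sum(((y - model) / s) ** 2))

    v0 = max(float(np.interp(0.0, t, y)), 1e-6)
    pos = y > 0
    tau0 = max(float(-1.0 / np.polyfit(t[pos], np.log(y[pos]), 1)[0]), 1e-3)
    x0 = np.log([v0, tau0])
    labels = ["sigma_v2", "tau_v"]
    if not mcmc:
        from scipy.optimize import minimize
        res = minimize(lambda x: -log_post(x), x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        theta = np.exp(res.x)
        return CellEstimate(theta_map=dict(zip(labels, map(float, theta))),
                            sigma_theta={k: 0.0 for k in labels},
                            n_obs=int(mask.sum()))
    theta_map, sigma, samples = _map_then_mcmc(
        log_post, x0, seed=seed, labels=labels)
    return CellEstimate(theta_map=theta_map, sigma_theta=sigma,
                        n_obs=int(mask.sum()),
                        samples=samples if keep_samples else None)


# ---------------------------------------------------------------------------
# kinase step responses

def normalize_activity(fret: np.ndarray, fret_min: float, fret_max: float
                       ) -> np.ndarray:
    """Affine rescale of a FRET signal to kinase activity.

    a(t) = (FRET(t) - FRET_min)/(FRET_max - FRET_min); values outside [0, 1]
    are permitted (and reported) rather than clipped.
    """
    if not fret_max > fret_min:
        raise ValueError("fret_max must exceed fret_min")
    a = (np.asarray(fret, float) - fret_min) / (fret_max - fret_min)
    out = float(np.mean((a < 0) | (a > 1)))
    if out > 0.05:
        warnings.warn(f"{100 * out:.1f}% of normalized activity outside [0, 1]",
                      stacklevel=2)
    return a


def step_response_model(t: np.ndarray, G: float, tau_1: float, tau_2: float,
                        delta_r_rel: float, sign: float) -> np.ndarray:
    """Mean activity deviation after a relative arrival-rate step at t = 0.

    ``G`` is the dimensionless gain (kD*Gr) expressed per relative rate
    change: for t >= 0 the deviation is
    -sign*G*delta_r_rel*(exp(-t/tau_2) - exp(-t/tau_1)); zero pre-stimulus.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(t, sign).shape)
    pos = t >= 0
    tp = t[pos]
    fast = np.exp(-tp / tau_1) if tau_1 > 0 else 0.0
    sgn = sign[pos] if np.ndim(sign) else sign
    out[pos] = -sgn * G * delta_r_rel * (np.exp(-tp / tau_2) - fast)
    return out


def fit_step_response(t: np.ndarray, up_mean: np.ndarray, up_sem: np.ndarray,
                      down_mean: np.ndarray, down_sem: np.ndarray,
                      delta_r_rel: float, seed: int = 0,
                      tau1_floor: float = 1e-3,
                      keep_samples: bool = False) -> CellEstimate:
    """MAP + MCMC fit of (G, tau_1, tau_2, a0) to averaged step responses.

    ``up_mean``/``down_mean`` are a cell's responses averaged over the
    repeated up/down stimulus blocks, aligned to stimulus onset at t = 0;
    both directions are fit jointly (pooled, SEM-weighted). ``delta_r_rel``
    is the relative arrival-rate step size |delta_r|/r0. When the fitted
    tau_1 pins to the sampling floor it is reported as unresolved (0).
    """
    t = np.asarray(t, float)
    resp = np.concatenate([up_mean, down_mean])
    sems = np.maximum(np.concatenate([up_sem, down_sem]), 1e-12)
    signs = np.concatenate([np.ones_like(up_mean), -np.ones_like(down_mean)])
    tt = np.concatenate([t, t])

    def log_post(x):
        if np.any(np.abs(x) > 30):
            return -np.inf
        G, tau1, tau2, a0 = np.exp(x)
        if tau1 >= tau2:
            return -np.inf
        model = a0 + step_response_model(tt, G, tau1, tau2, delta_r_rel, signs)
        return -0.5 * float(np.sum(((resp - model) / sems) ** 2))

    a0_guess = max(float(np.mean(resp[tt <= 0])) if np.any(tt <= 0)
                   else float(np.mean(resp)), 1e-3)
    amp = max(float(np.max(np.abs(resp - a0_guess))), 1e-4)
    x0 = np.log([amp / max(delta_r_rel, 1e-6), tau1_floor * 2, 5.0, a0_guess])
    theta_map, sigma, samples = _map_then_mcmc(
        log_post, x0, seed=seed, labels=["G", "tau_1", "tau_2", "a0"],
        n_steps=600, n_burn=200)
    sample_dt = float(np.median(np.diff(t)))
    if theta_map["tau_1"] < 0.5 * sample_dt:
        # a fast time below the sampling interval is unidentifiable: pin to
        # the delta-lobe convention used downstream
        theta_map["tau_1"] = 0.0
        sigma["tau_1"] = 0.0
    return CellEstimate(theta_map=theta_map, sigma_theta=sigma,
                        n_obs=resp.size, samples=samples if keep_samples else None)


# ---------------------------------------------------------------------------
# slow-noise statistics via exact scalar Kalman marginal likelihood

def _ou_kalman_loglik_py(y: np.ndarray, dt: float, D_n: float, tau_n: float,
                         meas_var: float) -> float:
    """Exact marginal log-likelihood of an OU + white-measurement-noise trace.

    Scalar Kalman recursion over the demeaned samples; also serves as the
    brute-force reference filter in tests.
    """
    phi = np.exp(-dt / tau_n)
    q = D_n * tau_n * (1.0 - phi * phi)
    mean = y.mean()
    P = D_n * tau_n  # stationary prior
    m = 0.0
    ll = 0.0
    for k in range(y.size):
        obs = y[k] - mean
        S = P + meas_var
        innov = obs - m
        ll -= 0.5 * (np.log(2.0 * np.pi * S) + innov * innov / S)
        K = P / S
        m = phi * (m + K * innov)
        P = phi * phi * (1.0 - K) * P + q
    return ll


try:  # jit the likelihood loop; the pure-python fallback is identical
    from numba import njit

    _ou_kalman_loglik = njit(cache=True)(_ou_kalman_loglik_py)
except ImportError:  # pragma: no cover
    _ou_kalman_loglik = _ou_kalman_loglik_py


def fit_noise_params(activity: np.ndarray, dt: float = 1.0, seed: int = 0,
                     trend_warn_sigma: float = 3.0,
                     keep_samples: bool = False) -> CellEstimate:
    """Bayesian fit of slow-noise parameters (D_n, tau_n) to a constant-background trace.

    The trace is modeled as baseline + OU(D_n, tau_n) + white measurement
    noise; the marginal likelihood comes from the exact scalar Kalman
    recursion, priors are log-uniform, and uncertainties are the robust
    spread of MCMC posterior draws. A strong linear trend is flagged as
    non-stationarity.
    """
    y = np.asarray(activity, float)
    if y.size < 50:
        raise ValueError("trace too short to constrain the noise parameters")
    t = np.arange(y.size) * dt
    coeffs = np.polyfit(t, y, 1)
    slope = coeffs[0]
    resid = y - np.polyval(coeffs, t)
    # slope error inflated for residual autocorrelation (AR(1) effective n)
    r1 = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
    r1 = min(max(r1, 0.0), 0.999)
    infl = np.sqrt((1.0 + r1) / (1.0 - r1))
    slope_sd = infl * np.std(resid) / np.sqrt(np.sum((t - t.mean()) ** 2))
    if abs(slope) > trend_warn_sigma * slope_sd:
        warnings.warn("activity trace has a significant linear trend; the "
                      "stationary noise model may be inappropriate", stacklevel=2)

    var_tot = float(np.var(y))

    def log_post(x):
        if np.any(np.abs(x) > 40):
            return -np.inf
        D_n, tau_n, mv = np.exp(x)
        # tau_n below the sampling interval is indistinguishable from
        # measurement noise; bound the prior to the identifiable region
        if tau_n > y.size * dt or tau_n < dt:
            return -np.inf
        return _ou_kalman_loglik(y, dt, D_n, tau_n, mv)

    x0 = np.log([max(var_tot, 1e-8) / 10.0, 10.0, max(var_tot, 1e-8) / 10.0])
    theta_map, sigma, samples = _map_then_mcmc(
        log_post, x0, seed=seed, labels=["D_n", "tau_n", "meas_var"],
        n_steps=500, n_burn=150)
    return CellEstimate(theta_map=theta_map, sigma_theta=sigma, n_obs=y.size,
                        samples=samples if keep_samples else None)


# ---------------------------------------------------------------------------
# MWC gain fit

def fit_mwc(gains_by_background: Sequence[tuple[float, float]],
            n_grid: int = 25) -> tuple[float, float]:
    """Fit kD*Gr(c0) = G_inf/(c0 + K_i) to measured gains, in log space.

    Minimizes the sum of squared differences between log measured and log
    predicted gains (so order-of-magnitude-smaller gains carry equal
    weight), with a deterministic multi-start Nelder-Mead over a log grid
    of K_i. Returns (G_inf, K_i).
    """
    data = [(float(c), float(g)) for c, g in gains_by_background]
    if len(data) < 2:
        raise ValueError("need gains at two or more backgrounds")
    if any(g <= 0 or c <= 0 for c, g in data):
        raise ValueError("backgrounds and gains must be positive")
    c0s = np.array([c for c, _ in data])
    logg = np.log([g for _, g in data])

    def loss(x):
        lg_inf, lk_i = x
        if abs(lg_inf) > 30 or abs(lk_i) > 30:
            return 1e30
        pred = lg_inf - np.log(c0s + np.exp(lk_i))
        return float(np.sum((logg - pred) ** 2))

    best = None
    for lk0 in np.log(np.geomspace(c0s.min() / 10, c0s.max() * 10, n_grid)):
        lg0 = float(np.mean(logg + np.log(c0s + np.exp(lk0))))
        res = minimize(loss, np.array([lg0, lk0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return float(np.exp(best.x[0])), float(np.exp(best.x[1]))
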