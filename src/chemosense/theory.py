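"""Closed-form small-signal theory of the two chemosensing channels.

The physical limit on how fast a swimming cell can acquire behaviorally
relevant information is set by stochastic molecule arrivals at its receptors;
the cell's own encoding is the CheA kinase activity. Both channels admit
dimensionless signal-to-noise ratios (gamma_r, gamma_a) and small-signal
information rates in closed form; this module collects those forms plus the
correlation functions, response kernels, power spectra and the Berg-Purcell
run-averaging threshold. The numeric state-space engine (:mod:`gauss_info`)
is the authority for quantities outside the small-signal regime.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .params import (KinaseParams, MWCGain, PhysicalConstants,
                     SwimSignalParams, diffusive_capture_rate)

__all__ = [
    "diffusive_capture_rate", "gamma_r", "gamma_a",
    "info_rate_physical_smallsignal", "info_rate_kinase_smallsignal",
    "mwc_gain_Gr", "response_kernel", "step_response",
    "noise_autocorrelation", "signal_autocorrelation", "psd_decomposition",
    "berg_purcell_exceeds_threshold", "correlated_window_factor",
    "nats_to_bits",
]

LN2 = math.log(2.0)


def nats_to_bits(rate_nats: float) -> float:
    """Convert an information rate from nats/s to bits/s."""
    return rate_nats / LN2


def gamma_r(swim: SwimSignalParams, constants: PhysicalConstants) -> float:
    """Dimensionless SNR of the molecule-arrival channel.

    gamma_r = 2*r0*g^2*sigma_v^2*tau_v^3 with r0 = kD*c0 and g in 1/um.
    Larger backgrounds, steeper gradients, faster swimming and longer runs
    all raise the arrival-channel SNR.
    """
    r0 = constants.arrival_rate(swim.c0)
    return 2.0 * r0 * swim.sigma_s2 * swim.tau_v ** 3


def gamma_a(swim: SwimSignalParams, kin: KinaseParams,
            constants: PhysicalConstants) -> float:
    """Dimensionless SNR of the kinase-activity channel.

    gamma_a = G_r^2*r0^2*g^2*sigma_v^2*tau_v / D_n. An ideal sensor with no
    internal noise (D_n = 0) returns +inf rather than raising.
    """
    r0 = constants.arrival_rate(swim.c0)
    numer = kin.G_r ** 2 * r0 ** 2 * swim.sigma_s2 * swim.tau_v
    if kin.D_n == 0.0:
        return math.inf if numer > 0 else 0.0
    return numer / kin.D_n


def info_rate_physical_smallsignal(gamma_r_value: float, tau_v: float) -> float:
    """Small-signal physical limit on the information rate, gamma_r/(4*tau_v) nats/s.

    Valid for gamma_r << 1; warns (does not fail) above 0.5.
    """
    if gamma_r_value < 0 or tau_v <= 0:
        raise ValueError("gamma_r must be >= 0 and tau_v > 0")
    if gamma_r_value > 0.5:
        warnings.warn(
            f"gamma_r={gamma_r_value:.3g} is outside the small-signal regime; "
            "the closed form overestimates the rate", stacklevel=2)
    return gamma_r_value / (4.0 * tau_v)


def info_rate_kinase_smallsignal(gamma_r_value: float, gamma_a_value: float,
                                 tau_v: float, form: str = "algebraic") -> float:
    """Small-signal information rate encoded in kinase activity, nats/s.

    Two readings of the closed form are provided:

    * ``"algebraic"`` (default): (1/(4*tau_v)) * gamma_r / (1 + gamma_r/gamma_a)^2,
      which reduces exactly to the physical limit as gamma_a -> inf.
    * ``"interpolating"``: (1/(4*tau_v)) * gamma_a*gamma_r / (gamma_a + gamma_r),
      which additionally tends to gamma_a/(4*tau_v) as gamma_a/gamma_r -> 0.

    Both agree when the two SNRs are well separated; the state-space engine is
    the reference for quantitative work.
    """
    if gamma_r_value < 0 or gamma_a_value < 0 or tau_v <= 0:
        raise ValueError("SNRs must be >= 0 and tau_v > 0")
    if gamma_r_value == 0.0:
        return 0.0
    if gamma_a_value == 0.0:
        return 0.0
    if form == "algebraic":
        if math.isinf(gamma_a_value):
            return gamma_r_value / (4.0 * tau_v)
        return gamma_r_value / (4.0 * tau_v) / (1.0 + gamma_r_value / gamma_a_value) ** 2
    if form == "interpolating":
        if math.isinf(gamma_a_value):
            return gamma_r_value / (4.0 * tau_v)
        return (gamma_a_value * gamma_r_value
                / (gamma_a_value + gamma_r_value)) / (4.0 * tau_v)
    raise ValueError(f"unknown form {form!r}; use 'algebraic' or 'interpolating'")


def mwc_gain_Gr(c0: float, mwc: MWCGain, constants: PhysicalConstants) -> float:
    """Arrival-rate gain G_r(c0) implied by the two-state receptor model.

    G_r = (1/r0)*G(c0) = G_inf / (kD*(c0 + K_i)); constant gain in the
    linear-sensing regime c0 << K_i, G_r ~ G_inf/r0 in the log-sensing
    regime c0 >> K_i.
    """
    if c0 <= 0:
        raise ValueError("gain is defined against a strictly positive background")
    return mwc.G_inf / (constants.kD * (c0 + mwc.K_i))


def response_kernel(t: np.ndarray, kin: KinaseParams) -> np.ndarray:
    """Kinase response kernel to arrival-rate deviations.

    K_r(t) = G_r*[(1/tau_1)exp(-t/tau_1) - (1/tau_2)exp(-t/tau_2)] for t >= 0,
    zero for t < 0. The two lobes have equal unit area, so the kernel
    integrates to zero: perfect adaptation. tau_1 = 0 makes the fast lobe an
    exact delta function, which has no finite-t representation; evaluating
    the kernel then returns only the slow lobe and :func:`step_response`
    carries the delta exactly.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0.0
    slow = (1.0 / kin.tau_2) * np.exp(-t[pos] / kin.tau_2)
    if kin.tau_1 > 0.0:
        fast = (1.0 / kin.tau_1) * np.exp(-t[pos] / kin.tau_1)
    else:
        fast = 0.0  # delta lobe at t=0, not representable pointwise
    out[pos] = kin.G_r * (fast - slow)
    return out


def step_response(t: np.ndarray, kin: KinaseParams, delta_r: float) -> np.ndarray:
    """Activity deviation after a step of size ``delta_r`` in arrival rate at t=0.

    a(t) - a0 = -delta_r * integral_0^t K_r(u) du
              = -delta_r * G_r * (exp(-t/tau_2) - exp(-t/tau_1)),
    with exp(-t/tau_1) -> 0 for tau_1 = 0 (instantaneous drop, slow recovery).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0.0
    fast = np.exp(-t[pos] / kin.tau_1) if kin.tau_1 > 0.0 else 0.0
    out[pos] = -delta_r * kin.G_r * (np.exp(-t[pos] / kin.tau_2) - fast)
    return out


def noise_autocorrelation(t: np.ndarray, kin: KinaseParams) -> np.ndarray:
    """Internal-noise autocorrelation D_n*tau_n*exp(-|t|/tau_n) (activity^2)."""
    t = np.asarray(t, dtype=float)
    return kin.D_n * kin.tau_n * np.exp(-np.abs(t) / kin.tau_n)


def signal_autocorrelation(t: np.ndarray, swim: SwimSignalParams) -> np.ndarray:
    """Signal autocorrelation g^2*sigma_v^2*exp(-|t|/tau_v) (1/s^2)."""
    t = np.asarray(t, dtype=float)
    return swim.sigma_s2 * np.exp(-np.abs(t) / swim.tau_v)


def _kernel_ft(omega: np.ndarray, kin: KinaseParams) -> np.ndarray:
    """Fourier transform of the response kernel, Khat(omega)."""
    omega = np.asarray(omega, dtype=float)
    fast = (1.0 / (1.0 + 1j * omega * kin.tau_1)) if kin.tau_1 > 0.0 else 1.0
    slow = 1.0 / (1.0 + 1j * omega * kin.tau_2)
    return kin.G_r * (fast - slow)


def psd_decomposition(omega: np.ndarray, swim: SwimSignalParams,
                      kin: KinaseParams, constants: PhysicalConstants
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise power spectra of kinase activity at one background.

    Returns ``(slow_noise, filtered_arrivals, total)`` over angular
    frequencies ``omega`` (rad/s):

    * slow internal noise: 2*D_n*tau_n^2/(1 + omega^2*tau_n^2);
    * molecule-arrival noise filtered through the response kernel:
      |Khat(omega)|^2 * r0 (high-pass: adaptation removes DC, plateau
      G_r^2*r0 at high frequency when tau_1 = 0);
    * their sum.

    Spectra are two-sided in omega; integrating over omega/(2*pi) recovers
    the stationary variances.
    """
    omega = np.asarray(omega, dtype=float)
    r0 = constants.arrival_rate(swim.c0)
    slow = 2.0 * kin.D_n * kin.tau_n ** 2 / (1.0 + (omega * kin.tau_n) ** 2)
    filtered = np.abs(_kernel_ft(omega, kin)) ** 2 * r0
    return slow, filtered, slow + filtered


BERG_PURCELL_THRESHOLD = 16.0 / 3.0


def berg_purcell_exceeds_threshold(gamma_r_value: float) -> bool:
    """Whether gamma_r exceeds the single-run estimation threshold 16/3.

    The classic argument requires a cell to resolve the concentration change
    over a single run, which in these variables reads gamma_r > 16/3. Cells
    climb gradients well below this threshold by accumulating inaccurate
    tumble decisions over many runs.
    """
    if gamma_r_value < 0:
        raise ValueError("gamma_r must be non-negative")
    return gamma_r_value > BERG_PURCELL_THRESHOLD


def correlated_window_factor(tau_v: float, T: float) -> float:
    """(tau_v/T)^3: information gained by averaging over the full signal
    correlation time tau_v instead of independent windows of duration T < tau_v.
    """
    if not tau_v > T > 0:
        raise ValueError(
            "requires tau_v > T > 0: the factor quantifies the advantage of "
            "averaging over the signal correlation time relative to shorter "
            "independent windows")
    return (tau_v / T) ** 3
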