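"""Parameter containers and structured-config loading.

Unit conventions used throughout the package:

* lengths in micrometers, times in seconds, concentrations in micromolar;
* gradient steepness ``g`` is accepted in 1/mm at every interface (the unit
  measurements are usually quoted in) and converted to 1/um internally;
* kinase activity is dimensionless (normalized to [0, 1]);
* information is carried in nats/s internally, with bits/s conversion helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Avogadro-derived conversion: molecules per um^3 at 1 uM.
MOLECULES_PER_UM3_PER_UM = 602.214

#: mm^-1 -> um^-1
PER_MM_TO_PER_UM = 1e-3


def diffusive_capture_rate(D: float, l: float,
                           molecules_per_um3_per_uM: float = MOLECULES_PER_UM3_PER_UM) -> float:
    """Diffusion-limited capture rate constant of an absorbing disk sensor.

    A perfectly absorbing circular patch of radius ``l`` on the cell surface
    captures molecules diffusing with diffusivity ``D`` at rate 4*D*l*c.

    Parameters
    ----------
    D : float
        Ligand diffusivity, um^2/s.
    l : float
        Sensor (receptor array) radius, um.

    Returns
    -------
    float
        Capture rate constant kD in 1/(s*uM).
    """
    if D <= 0 or l <= 0:
        raise ValueError(f"D and l must be strictly positive, got D={D}, l={l}")
    return 4.0 * D * l * molecules_per_um3_per_uM


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the ligand-capture problem.

    ``kD`` defaults to the first-principles value 4*D*l (per-uM units); an
    explicit value may be supplied to reproduce rounded literature numbers.
    """

    D: float = 800.0            # um^2/s
    l: float = 0.06             # um
    molecules_per_um3_per_uM: float = MOLECULES_PER_UM3_PER_UM
    kD: float | None = None     # 1/(s*uM); derived from D, l when None

    def __post_init__(self) -> None:
        if self.D <= 0 or self.l <= 0 or self.molecules_per_um3_per_uM <= 0:
            raise ValueError("PhysicalConstants fields must be strictly positive")
        if self.kD is None:
            object.__setattr__(
                self, "kD",
                diffusive_capture_rate(self.D, self.l, self.molecules_per_um3_per_uM))
        elif self.kD <= 0:
            raise ValueError("kD must be strictly positive")

    def arrival_rate(self, c0: float) -> float:
        """Mean molecule arrival rate r0 = kD*c0 at background c0 (uM)."""
        return self.kD * c0


@dataclass(frozen=True)
class SwimSignalParams:
    """Swimming statistics and the implied signal model.

    In a static exponential gradient of log-slope ``g`` the behaviorally
    relevant signal is s(t) = g*vx(t); with exponentially correlated
    up-gradient velocity this makes s an Ornstein-Uhlenbeck process with
    variance g^2*sigma_v2 and correlation time tau_v.
    """

    sigma_v2: float = 146.0     # (um/s)^2, variance of vx
    tau_v: float = 1.19         # s, velocity/signal correlation time
    P_run: float = 0.85         # fraction of time in the run state
    g: float = 0.05             # 1/mm, gradient steepness
    c0: float = 1.0             # uM, background concentration

    def __post_init__(self) -> None:
        if self.sigma_v2 <= 0 or self.tau_v <= 0:
            raise ValueError("sigma_v2 and tau_v must be strictly positive")
        if not 0.0 <= self.P_run <= 1.0:
            raise ValueError("P_run must lie in [0, 1]")
        if self.g < 0 or self.c0 < 0:
            raise ValueError("g and c0 must be non-negative")

    @property
    def g_per_um(self) -> float:
        """Gradient steepness in 1/um."""
        return self.g * PER_MM_TO_PER_UM

    @property
    def sigma_s2(self) -> float:
        """Signal variance g^2*sigma_v2, units 1/s^2."""
        return self.g_per_um ** 2 * self.sigma_v2

    def with_g(self, g: float) -> "SwimSignalParams":
        return replace(self, g=g)

    def with_c0(self, c0: float) -> "SwimSignalParams":
        return replace(self, c0=c0)


@dataclass(frozen=True)
class KinaseParams:
    """Linear-response and noise parameters of the kinase channel.

    ``G_r`` is the gain of kinase activity to molecule arrival *rate*; it
    carries units of seconds (activity per unit rate), so G_r*r0 is
    dimensionless. The response kernel is a fast depressing lobe (time tau_1,
    exactly a delta function when tau_1 = 0) balanced by a slow adaptive lobe
    (time tau_2); the balanced lobes give perfect adaptation. Internal noise
    is an OU process with diffusivity D_n and correlation time tau_n.
    """

    G_r: float                  # s (activity per unit arrival rate)
    tau_2: float = 7.4          # s, adaptation time
    tau_1: float = 0.0          # s, fast response time (0 => delta lobe)
    D_n: float = 8.1e-4         # 1/s, internal-noise diffusivity
    tau_n: float = 8.7          # s, internal-noise correlation time
    a0: float = 0.3             # baseline activity, dimensionless

    def __post_init__(self) -> None:
        if self.G_r < 0:
            raise ValueError("G_r must be non-negative")
        if self.tau_1 < 0 or self.tau_2 <= self.tau_1:
            raise ValueError("require tau_2 > tau_1 >= 0")
        if self.D_n < 0:
            raise ValueError("D_n must be non-negative")
        if self.tau_n <= 0:
            raise ValueError("tau_n must be strictly positive")
        if not 0.0 <= self.a0 <= 1.0:
            raise ValueError("a0 must lie in [0, 1]")

    @property
    def noise_variance(self) -> float:
        """Stationary variance of the internal noise, D_n*tau_n."""
        return self.D_n * self.tau_n


@dataclass(frozen=True)
class MWCGain:
    """Two-state (MWC) receptor gain model G(c0) = G_inf*c0/(c0 + K_i)."""

    G_inf: float = 3.5          # dimensionless asymptotic gain
    K_i: float = 0.81           # uM, inactive-state dissociation constant

    def __post_init__(self) -> None:
        if self.G_inf <= 0 or self.K_i <= 0:
            raise ValueError("G_inf and K_i must be strictly positive")

    def gain(self, c0: float) -> float:
        """Dimensionless gain G(c0)."""
        return self.G_inf * c0 / (c0 + self.K_i)


@dataclass(frozen=True)
class InfoSummary:
    """Information-rate summary for one (background, gradient) condition."""

    gamma_r: float              # arrival-channel SNR, dimensionless
    gamma_a: float              # kinase-channel SNR, dimensionless
    rho2_rs: float              # squared correlation, signal vs arrival estimate
    rho2_as: float              # squared correlation, signal vs kinase estimate
    I_r: float                  # nats/s, physical limit
    I_a: float                  # nats/s, kinase-encoded rate
    eta: float                  # I_a / I_r
    r0: float = 0.0             # 1/s, background arrival rate

    def __post_init__(self) -> None:
        if self.I_r < 0 or self.I_a < 0:
            raise ValueError("information rates must be non-negative")
        for name in ("rho2_rs", "rho2_as"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")


# ---------------------------------------------------------------------------
# Structured config

_CONFIG_KEYS = {
    "D_um2_per_s", "l_um", "sigma_v2", "tau_v", "P_run", "G_r_times_kD",
    "tau_1", "tau_2", "D_n", "tau_n", "G_inf", "K_i", "c0_uM", "g_per_mm",
    "a0", "kD", "backgrounds", "uncertainty",
}


@dataclass(frozen=True)
class ParameterSet:
    """One fully specified condition (constants + swim + kinase + MWC)."""

    constants: PhysicalConstants
    swim: SwimSignalParams
    kinase: KinaseParams
    mwc: MWCGain | None = None
    uncertainty: Mapping[str, float] = field(default_factory=dict)


def _build_one(flat: Mapping[str, Any]) -> ParameterSet:
    constants = PhysicalConstants(
        D=float(flat.get("D_um2_per_s", 800.0)),
        l=float(flat.get("l_um", 0.06)),
        kD=(float(flat["kD"]) if "kD" in flat else None),
    )
    swim = SwimSignalParams(
        sigma_v2=float(flat["sigma_v2"]),
        tau_v=float(flat["tau_v"]),
        P_run=float(flat.get("P_run", 0.85)),
        g=float(flat.get("g_per_mm", 0.05)),
        c0=float(flat["c0_uM"]),
    )
    kinase = KinaseParams(
        G_r=float(flat["G_r_times_kD"]) / constants.kD,
        tau_1=float(flat.get("tau_1", 0.0)),
        tau_2=float(flat["tau_2"]),
        D_n=float(flat["D_n"]),
        tau_n=float(flat["tau_n"]),
        a0=float(flat.get("a0", 0.3)),
    )
    mwc = None
    if "G_inf" in flat and "K_i" in flat:
        mwc = MWCGain(G_inf=float(flat["G_inf"]), K_i=float(flat["K_i"]))
    return ParameterSet(constants=constants, swim=swim, kinase=kinase, mwc=mwc,
                        uncertainty=dict(flat.get("uncertainty", {})))


def load_config(path: str | Path) -> list[ParameterSet]:
    """Load a YAML parameter config into one ParameterSet per background.

    Top-level keys are shared defaults; an optional ``backgrounds`` list of
    mappings overrides them per background (at minimum ``c0_uM`` and
    ``G_r_times_kD``). Unknown keys are rejected so unit mistakes surface at
    parse time.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} did not parse to a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; "
                         f"allowed keys are {sorted(_CONFIG_KEYS)}")
    shared = {k: v for k, v in raw.items() if k != "backgrounds"}
    blocks = raw.get("backgrounds")
    if not blocks:
        return [_build_one(shared)]
    out = []
    for block in blocks:
        unknown = set(block) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown background keys {sorted(unknown)}")
        merged = dict(shared)
        merged.update(block)
        out.append(_build_one(merged))
    return out


def default_config_path() -> Path:
    """Path of the packaged median-parameter fixture config."""
    return Path(__file__).parent / "data" / "measured_medians.yaml"


def load_default_parameters() -> list[ParameterSet]:
    """Packaged population-median parameter sets for c0 in {0.1, 1, 10} uM."""
    return load_config(default_config_path())
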