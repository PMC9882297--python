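"""Configuration objects for the synthetic-data generators and the pipeline.

Units are uniform across the package: lengths in nm, times in s, genomic
separations in kb.  Every generator takes an explicit integer seed and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = [
    "SimulationConfig",
    "SurrogateConfig",
    "StateKinetics",
    "MeasurementModel",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the bead-spring (Rouse) chain simulator.

    The chain is an ideal harmonic-spring polymer with local friction.
    ``bond_scale`` is the root-mean-square length of one bond (nm) and
    ``bond_relaxation`` the relaxation time of a single bond (s); the
    per-bead diffusivity follows as ``bond_scale**2 / (3 * bond_relaxation)``
    (nm^2/s).  Genomic separations (kb) are mapped to bead separations via
    ``kb_per_bond``.
    """

    n_beads: int = 160
    bond_scale: float = 200.0       # nm per bond
    bond_relaxation: float = 1.0    # s
    dt: float = 0.1                 # integration step, s
    frame_interval: float = 2.0     # sampling step, s
    duration: float = 1280.0        # total sampled time, s
    separations: tuple[float, ...] = (80.0, 160.0, 320.0, 640.0)  # kb
    kb_per_bond: float = 10.0
    n_trajectories: int = 100
    noise_scale: float = 1.0        # multiplies the thermal noise amplitude
    seed: int = 0

    @property
    def diffusivity(self) -> float:
        """Free-bead diffusivity D (nm^2/s) implied by bond scale and time."""
        return self.bond_scale**2 / (3.0 * self.bond_relaxation)

    def bead_separations(self) -> list[int]:
        return [max(1, round(s / self.kb_per_bond)) for s in self.separations]

    def __post_init__(self) -> None:
        if self.dt > self.bond_relaxation / 10.0 + 1e-12:
            raise ValueError(
                f"dt={self.dt} exceeds bond_relaxation/10="
                f"{self.bond_relaxation / 10.0}; the Euler scheme is unstable"
            )
        ratio = self.frame_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("frame_interval must be an integer multiple of dt")
        if max(self.bead_separations()) >= self.n_beads:
            raise ValueError(
                "n_beads must exceed the largest requested bead separation "
                f"({max(self.bead_separations())})"
            )


@dataclass
class SurrogateConfig:
    """Parameters of the stationary Gaussian-process surrogate generator.

    The separation vector R(t) is drawn per axis from a stationary Gaussian
    process with stretched-exponential autocovariance
    ``C(t) = (<R^2>(s)/3) * exp(-(t/tau)**beta)`` where
    ``<R^2>(s) = r2_prefactor * s**(2*inv_d)``,
    ``Gamma(s) = gamma_prefactor * s**alpha`` and
    ``tau(s) = (<R^2>(s)/Gamma(s))**(1/beta)``.

    Defaults reproduce the anomalous regime measured in the fly embryo:
    beta=0.52, 1/d=0.31, alpha=0.27, which imply a relaxation-time scaling
    exponent gamma = (2*inv_d - alpha)/beta ~= 0.67.
    """

    beta: float = 0.52
    inv_d: float = 0.31
    alpha: float = 0.27                 # diffusivity exponent, Gamma(s) ~ s**alpha
    gamma_prefactor: float = 9500.0     # nm^2 / s^beta at s = 1 kb
    r2_prefactor: float = 26000.0       # nm^2 / kb^(2*inv_d)
    separations: tuple[float, ...] = (58.0, 149.0, 190.0, 330.0, 595.0)  # kb
    frame_interval: float = 28.0        # s
    duration: float = 1792.0            # s (~30 min, 64 frames)
    n_trajectories: int = 150
    include_locus_motion: bool = True   # also synthesize per-locus positions
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if not 0.0 < self.inv_d <= 1.0:
            raise ValueError("inv_d must lie in (0, 1]")
        if self.gamma_prefactor <= 0 or self.r2_prefactor <= 0:
            raise ValueError("prefactors must be positive")
        for s in self.separations:
            if not math.isfinite(self.tau(s)) or self.tau(s) <= 0:
                raise ValueError(f"derived relaxation time at s={s} kb is not positive")

    def mean_square_distance(self, s: float) -> float:
        """Equilibrium <R^2>(s) in nm^2."""
        return self.r2_prefactor * s ** (2.0 * self.inv_d)

    def diffusivity(self, s: float) -> float:
        """Two-locus diffusivity Gamma(s) in nm^2/s^beta."""
        return self.gamma_prefactor * s**self.alpha

    def tau(self, s: float) -> float:
        """Relaxation time tau(s) = (<R^2>/Gamma)^(1/beta) in s."""
        return (self.mean_square_distance(s) / self.diffusivity(s)) ** (1.0 / self.beta)

    @property
    def gamma_exponent(self) -> float:
        """Ground-truth relaxation-time scaling exponent (2/d - alpha)/beta."""
        return (2.0 * self.inv_d - self.alpha) / self.beta


@dataclass
class StateKinetics:
    """Kinetic scheme of the three topological states.

    O_off -> P_off fires with ``pairing_rate`` only while the inter-locus
    distance is below ``capture_radius`` (pairing is reaction-limited given
    proximity).  While paired, the separation vector is re-drawn from an OU
    tether whose stationary mean distance is ``tether_center``.  P_off <-> P_on
    is a telegraph process; direct O_off <-> P_on transitions are forbidden.

    Default rates encode a ~12 min focal-contact lifetime and a ~10 min median
    transcriptional lifetime with a ~50% conditional on-fraction.
    """

    capture_radius: float = 500.0        # nm
    pairing_rate: float = 1.5e-3         # 1/s, fires only while R < capture_radius
    unpairing_rate: float = 1.0 / 720.0  # 1/s  (12 min mean contact lifetime)
    on_rate: float = math.log(2) / 600.0   # 1/s, P_off -> P_on
    off_rate: float = math.log(2) / 600.0  # 1/s, P_on -> P_off (10 min median)
    tether_center: float = 375.0         # nm, mean paired distance (350-400 nm)
    tether_relaxation: float = 60.0      # s, OU relaxation time of the tether

    def __post_init__(self) -> None:
        for name in ("pairing_rate", "unpairing_rate", "on_rate", "off_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 300.0 <= self.tether_center <= 450.0:
            # soft contract: typical paired distances are 350-400 nm
            import warnings

            warnings.warn(
                "tether_center outside the typical 300-450 nm paired range",
                stacklevel=2,
            )

    @property
    def tether_sigma(self) -> float:
        """Per-axis OU stationary sd so the mean radial distance is the center.

        For a 3-D isotropic Gaussian the mean radial distance is
        ``2*sigma*sqrt(2/pi)``.
        """
        return self.tether_center / (2.0 * math.sqrt(2.0 / math.pi))


@dataclass
class MeasurementModel:
    """Measurement model: localization noise, missing frames, intensities."""

    sigma_loc: float = 30.0        # nm per axis, per locus
    missing_prob: float = 0.1
    background_mean: float = 100.0  # a.u.
    background_sd: float = 20.0
    active_mean: float = 300.0      # a.u. (10 background sd above background)
    active_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate -> infer -> kinetics ->
    dynamics -> report).  A single global seed deterministically derives
    per-stage substreams."""

    outdir: str = "run"
    seed: int = 0
    generator: str = "surrogate"            # "surrogate" or "rouse"
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    kinetics: StateKinetics = field(default_factory=StateKinetics)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    overlay_states: bool = True
    # state inference
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-8
    hmm_restarts: int = 5
    # dynamics
    m2_model: str = "stretched"             # "rouse" or "stretched"
    m2_beta: float = 0.5                    # beta used when m2_model="rouse"
    vcc_delta: float = 300.0                # s, velocity coarse-graining interval
    n_bootstrap: int = 200
    fit_range: tuple[float, float] | None = None  # kb range for scaling fits
    stages: tuple[str, ...] = ("simulate", "infer", "kinetics", "dynamics", "report")
    min_points: int = 10
    log_level: str = "INFO"


_NESTED = {
    "surrogate": SurrogateConfig,
    "simulation": SimulationConfig,
    "kinetics": StateKinetics,
    "measurement": MeasurementModel,
}


def _to_plain(obj):
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config, path) -> None:
    """Serialize any of the config dataclasses to a YAML file."""
    payload = {"__type__": type(config).__name__, **_to_plain(asdict(config))}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path, cls=None):
    """Load a config dataclass from YAML; the class is inferred if omitted."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    name = payload.pop("__type__", None)
    if cls is None:
        registry = {
            c.__name__: c
            for c in (
                SimulationConfig,
                SurrogateConfig,
                StateKinetics,
                MeasurementModel,
                PipelineConfig,
            )
        }
        if name not in registry:
            raise ValueError(f"cannot infer config class from {name!r}")
        cls = registry[name]
    kwargs = {}
    valid = {f.name: f for f in fields(cls)}
    for key, value in payload.items():
        if key not in valid:
            raise ValueError(f"unknown field {key!r} for {cls.__name__}")
        if key in _NESTED and cls is PipelineConfig and isinstance(value, dict):
            value = _NESTED[key](**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
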