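"""Parameter containers for the ELL pair model.

Units follow the field convention for point-neuron models: voltages in mV,
currents in uA/cm^2, conductances in mS/cm^2, capacitance in uF/cm^2, and
times in ms internally.  Configuration files may give protocol durations in
seconds; they are converted on load.

The defaults are the published parameter set of the two superficial-pyramidal
(SP) cell network: a homogeneous pair of noisy leaky integrate-and-fire cells
with a depolarizing afterpotential (DAP) burst mechanism, each contacted by
its own bank of 100 spiking granule cells through plastic AMPA synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = [
    "SPParams",
    "GranuleParams",
    "PlasticityParams",
    "NoiseParams",
    "StimulusSpec",
    "ProtocolSpec",
    "ModelConfig",
    "load_config",
    "save_config",
]


@dataclass
class SPParams:
    """Superficial pyramidal (SP) cell parameters.

    The DAP constants ``A, B`` are dimensionless, ``D, E, tau`` are in ms and
    ``alpha`` in uA/cm^2; together they control the dynamic dendritic
    refractory period that terminates bursts.
    """

    C: float = 1.0            # uF/cm^2
    g_leak: float = 0.14      # mS/cm^2
    E_leak: float = -68.8     # mV
    I: float = 0.313          # uA/cm^2, constant bias
    sigma: float = 0.412      # uA/cm^2, SP noise SD
    kappa: float = 0.21       # uA/cm^2, stimulus amplitude
    V_threshold: float = -65.0
    V_rest: float = -68.8
    r_s: float = 0.7          # ms, absolute somatic refractory period
    g_GABA: float = 0.14      # mS/cm^2, constant inhibitory conductance
    E_GABA: float = -68.8
    E_AMPA: float = 0.0
    g_max: float = 0.024      # mS/cm^2, maximal AMPA conductance
    tau_AMPA: float = 5.26    # ms
    # DAP constants
    A: float = 0.6
    B: float = 2.0
    D: float = 0.7            # ms, baseline dendritic refractory period
    E: float = 24.5           # ms, dendritic refractory recovery time constant
    gamma: float = 0.2
    alpha: float = 10.9       # uA/cm^2
    tau: float = 7.0          # ms, DAP alpha-function time constant

    def __post_init__(self) -> None:
        for name in ("C", "g_leak", "g_GABA", "g_max", "tau_AMPA", "r_s", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"SPParams.{name} must be >= 0")
        if self.V_rest > self.V_threshold:
            raise ValueError("V_rest must be <= V_threshold")


@dataclass
class GranuleParams:
    """Granule cell parameters.

    Granule cells use the same integrate-and-fire formalism, threshold, reset
    and absolute refractory period as the SP cells; only the noise SD ``rho``
    and the stimulus drive differ.  ``g_relay`` is the DP-to-granule relay
    gain on the sinusoidal drive: with the bare SP stimulus amplitude the
    quasi-static peak voltage sits fractionally below threshold, so the relay
    gain is what lets a deterministic granule cell phase-lock (firing over
    roughly a third of the cycle around its preferred phase) while staying
    silent without stimulation.
    """

    rho: float = 0.412        # uA/cm^2, granule noise SD
    count_per_sp: int = 100
    g_relay: float = 2.0      # dimensionless DP->granule relay gain

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.count_per_sp < 1:
            raise ValueError("count_per_sp must be >= 1")


@dataclass
class PlasticityParams:
    """Anti-Hebbian burst plasticity (depression) + slow potentiation.

    ``eta_g``/``L_Wg`` are the gain and window length for g-spike SP bursts
    (g = 2 or 4); ``tau_w`` is the non-associative potentiation time constant
    in seconds.
    """

    eta_2: float = 0.0018
    eta_4: float = 0.0036
    L_W2: float = 10.0        # ms
    L_W4: float = 100.0       # ms
    tau_w: float = 4900.0     # s

    def __post_init__(self) -> None:
        for name in ("eta_2", "eta_4", "L_W2", "L_W4", "tau_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"PlasticityParams.{name} must be >= 0")


@dataclass
class NoiseParams:
    """Correlated-noise structure.

    ``c`` is the correlation coefficient between the composed noise inputs to
    the two SP cells (sqrt(c) is the shared fraction in amplitude); ``e`` is
    the fraction of each granule cell's noise inherited from the deep-pyramidal
    stream (which is identical to the SP stream of its column).  Streams are
    Gaussian white noise passed through a causal low-pass Butterworth filter
    and rescaled to unit variance.
    """

    c: float = 0.25
    e: float = 1.0
    cutoff_hz: float = 500.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("e must lie in [0, 1]")


@dataclass
class StimulusSpec:
    """Sinusoidal amplitude-modulation stimulus."""

    f: float = 4.0            # Hz
    kappa: float = 0.21       # uA/cm^2
    geometry: str = "global"  # "local" | "global"
    duration_s: float = 100.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("stimulus frequency f must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.geometry not in ("local", "global"):
            raise ValueError("geometry must be 'local' or 'global'")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f


@dataclass
class ProtocolSpec:
    """Experiment protocol: geometry, training, trial bookkeeping.

    Local geometry disables feedback entirely (g_max = g_GABA = 0, granule
    cells silent, no training).  Global geometry trains the parallel-fiber
    weights to equilibrium, freezes them, then runs the evaluation trials.
    """

    geometry: str = "global"
    training_duration_s: float = 1000.0
    n_trials: int = 100
    trial_duration_s: float = 100.0
    freeze_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("local", "global"):
            raise ValueError("geometry must be 'local' or 'global'")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


@dataclass
class ModelConfig:
    """Bundle of all model parameters, loadable from YAML."""

    sp: SPParams = field(default_factory=SPParams)
    gc: GranuleParams = field(default_factory=GranuleParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    dt_ms: float = 0.05       # Euler-Maruyama step

    def replace(self, **groups) -> "ModelConfig":
        """Return a copy with dataclass-level replacements, e.g.
        ``cfg.replace(noise=replace(cfg.noise, c=1.0))``."""
        return replace(self, **groups)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML file keyed by printed symbol
    names (``g_max``, ``tau_AMPA``, ``c``, ``e``, ``rho``, ``f`` ...)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig(
        sp=SPParams(**raw.get("sp", {})),
        gc=GranuleParams(**raw.get("gc", {})),
        plasticity=PlasticityParams(**raw.get("plasticity", {})),
        noise=NoiseParams(**raw.get("noise", {})),
        stimulus=StimulusSpec(**raw.get("stimulus", {})),
        dt_ms=raw.get("dt_ms", 0.05),
    )


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
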