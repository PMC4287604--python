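"""Spike-train container shared by the simulator, surrogates and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain"]


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) for one neuron in one trial.

    Times must be strictly increasing and lie in ``[0, duration_ms)``.
    """

    spike_times: np.ndarray
    duration_ms: float
    neuron_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] >= self.duration_ms:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.spike_times.size

    @property
    def rate_hz(self) -> float:
        return 1000.0 * len(self) / self.duration_ms
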