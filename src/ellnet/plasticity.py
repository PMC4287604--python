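"""Burst classification and anti-Hebbian burst plasticity.

Depression: when the SP cell fires a burst, every parallel-fiber weight whose
presynaptic burst time falls inside the timing window is depressed,

    w <- max(0, w - eta_g * K(t_pre - t_post; L_Wg)),   g in {2, 4}

with K a box kernel of total length L_Wg (see :func:`btdp_window`) and the
presynaptic burst times taken analytically as the times at which each granule
cell's delayed sinusoidal drive peaks.  Potentiation: a slow non-associative
relaxation toward the upper bound,  dw/dt = (1 - w) / tau_w,  keeps weights
from all reaching zero.

Burst classification is an exclusive-assignment online rule run on each new
spike: the new spike plus the three preceding ones form a 4-spike burst if
none is already in a burst and the first and last are within 45 ms; failing
that, the 4th- and 5th-most-recent spikes form a 2-spike burst if neither is
already in a burst and they are within 15 ms.  The deferral of the 2-spike
test guarantees that no spike that may yet join a 4-spike burst is consumed
by a 2-spike burst; the 4-spike burst takes priority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (BURST2_ISI_MS, BURST4_SPAN_MS, NetworkState,
                    granule_max_phase_times, run_network)
from .noise import NoiseBundle
from .params import ModelConfig, PlasticityParams

__all__ = [
    "BurstEvent",
    "classify_bursts",
    "btdp_window",
    "depress_weights",
    "potentiate_weights",
    "train_negative_image",
    "DEFAULT_SNAPSHOT_TIMES_S",
]

# weight-profile snapshot schedule: 0-5.5 s every 0.5 s, plus steady state
DEFAULT_SNAPSHOT_TIMES_S = tuple(np.arange(0.0, 5.6, 0.5))


@dataclass(frozen=True)
class BurstEvent:
    onset_time: float      # ms; time of the first spike in the burst
    size: int              # 2 or 4
    members: tuple         # spike indices into the classified train


def classify_bursts(spike_times) -> list[BurstEvent]:
    """Exclusive 2-/4-spike burst assignment with 4-spike priority."""
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    in_burst = np.zeros(t.size, dtype=bool)
    events: list[BurstEvent] = []
    for n in range(t.size):
        if n >= 3:
            quad = range(n - 3, n + 1)
            if (not any(in_burst[q] for q in quad)
                    and t[n] - t[n - 3] <= BURST4_SPAN_MS):
                for q in quad:
                    in_burst[q] = True
                events.append(BurstEvent(t[n - 3], 4, tuple(quad)))
                continue
        if n >= 4:
            i4, i5 = n - 3, n - 4
            if (not in_burst[i4] and not in_burst[i5]
                    and t[i4] - t[i5] <= BURST2_ISI_MS):
                in_burst[i4] = in_burst[i5] = True
                events.append(BurstEvent(t[i5], 2, (i5, i4)))
    events.sort(key=lambda ev: ev.onset_time)
    return events


def btdp_window(delta_ms, L_ms: float):
    """Timing kernel of the depression rule: 1 inside the box |delta| <= L/2.

    Single audit point for the window shape; ``delta_ms`` is
    t_burst,pre - t_burst,post.
    """
    delta_ms = np.asarray(delta_ms, dtype=float)
    out = (np.abs(delta_ms) <= L_ms / 2.0).astype(float)
    return out if out.ndim else float(out)


def depress_weights(weights, burst: BurstEvent, presyn_burst_times,
                    params: PlasticityParams, period_ms: float | None = None):
    """Apply the burst-triggered depression to a weight vector.

    ``presyn_burst_times`` holds one presynaptic burst time per granule cell
    (ms).  When ``period_ms`` is given, timing differences are wrapped to
    (-period/2, period/2] — the presynaptic maxima recur every cycle.
    Weights are clipped at 0; returns a new array.
    """
    w = np.asarray(weights, dtype=float).copy()
    eta = params.eta_4 if burst.size == 4 else params.eta_2
    window = params.L_W4 if burst.size == 4 else params.L_W2
    delta = np.asarray(presyn_burst_times, dtype=float) - burst.onset_time
    if period_ms is not None:
        delta = (delta + period_ms / 2.0) % period_ms - period_ms / 2.0
    w -= eta * btdp_window(delta, window)
    return np.clip(w, 0.0, None)


def potentiate_weights(weights, dt_s: float, params: PlasticityParams):
    """Closed-form relaxation of dw/dt = (1 - w)/tau_w over ``dt_s`` seconds."""
    if params.tau_w <= 0:
        raise ValueError("tau_w must be > 0")
    w = np.asarray(weights, dtype=float)
    decay = np.exp(-dt_s / params.tau_w)
    return 1.0 - (1.0 - w) * decay


def train_negative_image(cfg: ModelConfig, duration_s: float = 1000.0,
                         seed=0, snapshot_times_s=DEFAULT_SNAPSHOT_TIMES_S,
                         chunk_steps: int = 100_000) -> dict:
    """Train parallel-fiber weights under global stimulation.

    All weights start at 1 and evolve under the combined depression +
    potentiation dynamics while the full network runs.  Returns a dict with
    ``snapshot_times_s``, ``snapshots`` (list of (2, n_gc) weight arrays),
    ``final_weights`` and ``sp_spikes`` (whole-run SP spike times).

    Raises :class:`FloatingPointError` if any voltage diverges.
    """
    state = NetworkState.initial(cfg)
    bundle = NoiseBundle(cfg.noise, cfg.gc.count_per_sp, cfg.dt_ms, seed,
                         with_granules=True)
    times = sorted(set(float(t) for t in snapshot_times_s
                       if 0.0 <= t <= duration_s) | {0.0})
    snaps, snap_times = [], []
    sp_all = [[], []]
    t_done = 0.0
    for t_snap in times:
        seg = t_snap - t_done
        if seg > 0:
            spikes, _, state = run_network(
                cfg, seg * 1000.0, bundle, state=state, feedback_on=True,
                plastic=True, chunk_steps=chunk_steps)
            for j in range(2):
                sp_all[j].append(spikes[j] + t_done * 1000.0)
            t_done = t_snap
        snap_times.append(t_snap)
        snaps.append(state.weights.copy())
    if duration_s > t_done:
        spikes, _, state = run_network(
            cfg, (duration_s - t_done) * 1000.0, bundle, state=state,
            feedback_on=True, plastic=True, chunk_steps=chunk_steps)
        for j in range(2):
            sp_all[j].append(spikes[j] + t_done * 1000.0)
    if not np.all(np.isfinite(state.weights)):
        raise FloatingPointError("synaptic weights diverged during training")
    return {
        "snapshot_times_s": np.asarray(snap_times),
        "snapshots": snaps,
        "final_weights": state.weights.copy(),
        "sp_spikes": [np.concatenate(s) if s else np.zeros(0) for s in sp_all],
        "granule_phase_times_ms": granule_max_phase_times(
            cfg.gc.count_per_sp, cfg.stimulus.f),
    }
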