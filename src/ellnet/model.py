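"""Core network dynamics: two SP cells with DAP bursting + granule banks.

The network is a pair of noisy leaky integrate-and-fire superficial pyramidal
(SP) cells, each receiving (i) a half-wave-rectified sinusoidal stimulus,
(ii) correlated low-pass Gaussian noise, (iii) a depolarizing afterpotential
(DAP) current that produces intrinsic bursting, and — in the global
(feedback-on) geometry — (iv) a constant GABA conductance and (v) excitatory
AMPA input from its own bank of spiking granule cells through plastic
parallel-fiber weights.

SP voltage (cell i):

    C dV/dt = -g_leak (V - E_leak) + I + sigma xi_SP_i(t)
              + F(kappa sin(2 pi f t)) + DAP_i(t)
              - g_GABA (V - E_GABA) - sum_s g_AMPA_i_s(t) (V - E_AMPA)

with F the half-wave rectifier (isolated in :func:`rectified_stimulus`).
Threshold crossing (V >= V_threshold at the end of a step) resets V to
V_rest, where it is clamped for the absolute somatic refractory period r_s.

DAP mechanism: the DAP is a function of the last two somatic spike times
only.  A spike at t_n launches, r_s later, an alpha-function current
amp * s(t - t_n - r_s, tau) with s(t, a) = (t/a) exp(1 - t/a), provided the
dendrite is not refractory (t_n - t_{n-1} > r_d); a dendritic failure
produces no DAP, and each new spike replaces the previous spike's DAP.
Successive dendritic successes potentiate the amplitude,
amp = alpha (A + gamma k), and multiply the dendritic refractory period,
r_d <- B r_d, while between spikes r_d relaxes back to its baseline,
dr_d/dt = (D - r_d)/E.  The growth of r_d eventually exceeds the DAP-driven
inter-spike interval; the dendritic failure then shuts the DAP off and ends
the burst (resetting the potentiation counter k), which is what limits
bursts to a few spikes and enforces a noise-driven inter-burst interval.

Granule cell i (bank of SP j): same integrate-and-fire formalism, threshold,
reset and refractory period, driven by the deep-pyramidal relay of the
stimulus delayed by d_i = (i-1)/N * (1000/f) ms so the bank tiles one
stimulus period:

    C dV/dt = -g_leak (V - E_leak) + I
              + F(g_relay kappa sin(2 pi f (t - d_i))) + rho xi_PF_i(t)

Granule cells are silent in the absence of stimulation and during local
stimulation (feedback off).  Integration is Euler-Maruyama at dt = 0.05 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ModelConfig, SPParams
from .spiketrains import SpikeTrain

__all__ = [
    "rectified_stimulus",
    "alpha_function",
    "dap_current",
    "ampa_conductance",
    "granule_delays",
    "granule_max_phase_times",
    "NetworkState",
    "simulate_chunk",
    "run_network",
]

E_NAT = float(np.e)

# burst-definition windows of the plasticity rule (classification constants,
# distinct from the plasticity windows L_Wg)
BURST2_ISI_MS = 15.0
BURST4_SPAN_MS = 45.0


def rectified_stimulus(x):
    """Half-wave rectifier F(x): x for x > 0, else 0.

    Single audit point for where the rectifier sits in the voltage equation:
    it is applied to the sinusoidal stimulus drive only.
    """
    return np.maximum(x, 0.0)


def alpha_function(t, a):
    """s(t, a) = (t/a) exp(1 - t/a) for t >= 0 (0 otherwise); peak 1 at t=a."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0.0, (t / a) * np.exp(1.0 - t / a), 0.0)
    return out if out.ndim else float(out)


def granule_delays(count: int, f_hz: float) -> np.ndarray:
    """Per-cell delays d_i = (i-1)/count * period, tiling one period.

    The multiset {d_i} uniformly covers [0, 1000/f) ms, so each granule cell
    responds at its own phase of the sinusoid; doubling f halves every delay.
    """
    if f_hz <= 0:
        raise ValueError("stimulus frequency must be > 0")
    period_ms = 1000.0 / f_hz
    return np.arange(count) / count * period_ms


def granule_max_phase_times(count: int, f_hz: float) -> np.ndarray:
    """Time (mod period) at which each granule cell's sinusoidal drive peaks.

    Used as the analytic presynaptic burst times of the plasticity rule."""
    period_ms = 1000.0 / f_hz
    return (granule_delays(count, f_hz) + period_ms / 4.0) % period_ms


def dap_current(spike_times, t, p: SPParams) -> float:
    """Event-based reference evaluation of the DAP current at time ``t``.

    ``spike_times`` are the somatic spike times (ms, increasing) up to ``t``.
    Returns 0 before the first spike.  Only the most recent spike carries a
    DAP (each spike replaces the previous one's); the dendritic refractory
    recursion runs over the whole history.  This closed-form path is
    independent of the step-based kernel and is used to cross-check it.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    r_d = p.D
    t_upd = -np.inf
    k = 0
    t_last = -np.inf
    current_amp = 0.0
    current_t = -np.inf
    for ts in spike_times:
        if ts > t:
            break
        # relax r_d from its last event to this spike
        if np.isfinite(t_upd):
            r_d = p.D + (r_d - p.D) * np.exp(-(ts - t_upd) / p.E)
        if ts - t_last > r_d:
            current_amp = p.alpha * (p.A + p.gamma * k)
            current_t = ts
            k += 1
            r_d *= p.B
        else:
            current_amp = 0.0
            current_t = -np.inf
            k = 0
        t_upd = ts
        t_last = ts
    if not np.isfinite(current_t):
        return 0.0
    return float(current_amp * alpha_function(t - current_t - p.r_s, p.tau))


def ampa_conductance(presyn_times, t, w: float, p: SPParams) -> float:
    """Closed-form AMPA conductance g_max w sum_k H(t - t_k) exp(-(t-t_k)/tau_AMPA)."""
    presyn_times = np.asarray(presyn_times, dtype=float)
    dt = t - presyn_times
    return float(p.g_max * w * np.sum(np.exp(-dt[dt > 0] / p.tau_AMPA)))


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _kernel(  # noqa: C901 - single hot loop on purpose
    n_steps, dt, t0,
    # SP params
    C, g_leak, E_leak, Ibias, sigma, kappa, V_th, V_rest, r_s,
    g_GABA, E_GABA, E_AMPA, g_max, tau_AMPA,
    A, B, D, E, gamma, alpha, tau,
    f_hz,
    # granule
    feedback_on, n_gc, rho, g_relay, delays,
    # noise (2, n) and (2*n_gc, n) [dummy 1-row when feedback off]
    xi_sp, xi_gc,
    # plasticity
    plastic, eta_2, eta_4, L_W2, L_W4, tau_w_ms, t_pre_phase, period_ms,
    # mutable state
    V, refr_end, t_last, t_prev, z1, z2, r_d, k_dend, pend_t, pend_amp,
    hist_t, hist_flag, hist_n,
    V_gc, refr_gc, gsyn, w,
    # outputs
    sp_times, sp_counts, gc_times, gc_cell, gc_count, record_gc,
):
    """Advance the network ``n_steps`` Euler-Maruyama steps from time ``t0``.

    Returns 0 on success, (1 + cell index) if a voltage went non-finite.
    """
    two_pi_f = 2.0 * np.pi * f_hz / 1000.0  # rad per ms
    syn_decay = np.exp(-dt / tau_AMPA)
    pot_rate = 0.0 if tau_w_ms <= 0.0 else dt / tau_w_ms

    for step in range(n_steps):
        t = t0 + step * dt
        t_next = t + dt

        # granule bank update ------------------------------------------------
        if feedback_on:
            for j in range(2):
                for i in range(n_gc):
                    gsyn[j, i] *= syn_decay
                    if t_next < refr_gc[j, i]:
                        V_gc[j, i] = V_rest
                        continue
                    drive = g_relay * kappa * np.sin(two_pi_f * (t - delays[i]))
                    if drive < 0.0:
                        drive = 0.0
                    dv = (-g_leak * (V_gc[j, i] - E_leak) + Ibias + drive
                          + rho * xi_gc[j * n_gc + i, step]) * (dt / C)
                    v = V_gc[j, i] + dv
                    if v >= V_th:
                        V_gc[j, i] = V_rest
                        refr_gc[j, i] = t_next + r_s
                        gsyn[j, i] += 1.0
                        if record_gc == 1:
                            idx = gc_count[0]
                            if idx < gc_times.shape[0]:
                                gc_times[idx] = t_next
                                gc_cell[idx] = j * n_gc + i
                                gc_count[0] = idx + 1
                    else:
                        V_gc[j, i] = v

        # SP cells -----------------------------------------------------------
        for j in range(2):
            # DAP alpha-function states (Euler)
            if pend_t[j] >= 0.0 and t_next >= pend_t[j]:
                z1[j] += pend_amp[j] * E_NAT
                pend_t[j] = -1.0
            dz1 = -z1[j] / tau * dt
            z2[j] += (z1[j] - z2[j]) / tau * dt
            z1[j] += dz1
            r_d[j] += (D - r_d[j]) / E * dt

            if t_next < refr_end[j]:
                V[j] = V_rest
                continue

            stim = kappa * np.sin(two_pi_f * t)
            if stim < 0.0:
                stim = 0.0
            current = (-g_leak * (V[j] - E_leak) + Ibias
                       + sigma * xi_sp[j, step] + stim + z2[j])
            if feedback_on:
                current += -g_GABA * (V[j] - E_GABA)
                s_sum = 0.0
                for i in range(n_gc):
                    s_sum += w[j, i] * gsyn[j, i]
                current += -g_max * s_sum * (V[j] - E_AMPA)
            v = V[j] + current * (dt / C)
            if not np.isfinite(v):
                return 1 + j
            if v < V_th:
                V[j] = v
                continue

            # spike ----------------------------------------------------------
            ts = t_next
            V[j] = V_rest
            refr_end[j] = ts + r_s
            # the DAP depends on the last two spikes only: replace it
            z1[j] = 0.0
            z2[j] = 0.0
            isi = ts - t_last[j]
            if isi > r_d[j]:
                pend_amp[j] = alpha * (A + gamma * k_dend[j])
                pend_t[j] = ts + r_s
                k_dend[j] += 1.0
                r_d[j] *= B
            else:
                pend_t[j] = -1.0
                k_dend[j] = 0.0
            t_prev[j] = t_last[j]
            t_last[j] = ts
            idx = sp_counts[j]
            if idx < sp_times.shape[1]:
                sp_times[j, idx] = ts
                sp_counts[j] = idx + 1

            # online burst classification + weight update -------------------
            if plastic:
                # shift history ring (most recent at position hn-1)
                hn = hist_n[j]
                if hn < 5:
                    hist_t[j, hn] = ts
                    hist_flag[j, hn] = 0
                    hist_n[j] = hn + 1
                    hn = hn + 1
                else:
                    for q in range(4):
                        hist_t[j, q] = hist_t[j, q + 1]
                        hist_flag[j, q] = hist_flag[j, q + 1]
                    hist_t[j, 4] = ts
                    hist_flag[j, 4] = 0
                burst_g = 0
                onset = 0.0
                if hn >= 4:
                    a0 = hn - 4
                    free = (hist_flag[j, a0] == 0 and hist_flag[j, a0 + 1] == 0
                            and hist_flag[j, a0 + 2] == 0 and hist_flag[j, a0 + 3] == 0)
                    if free and (ts - hist_t[j, a0]) <= BURST4_SPAN_MS:
                        for q in range(a0, a0 + 4):
                            hist_flag[j, q] = 1
                        burst_g = 4
                        onset = hist_t[j, a0]
                if burst_g == 0 and hn >= 5:
                    i4 = hn - 4  # 4th most recent
                    i5 = hn - 5  # 5th most recent
                    if (hist_flag[j, i4] == 0 and hist_flag[j, i5] == 0
                            and (hist_t[j, i4] - hist_t[j, i5]) <= BURST2_ISI_MS):
                        hist_flag[j, i4] = 1
                        hist_flag[j, i5] = 1
                        burst_g = 2
                        onset = hist_t[j, i5]
                if burst_g > 0:
                    eta = eta_4 if burst_g == 4 else eta_2
                    half_w = (L_W4 if burst_g == 4 else L_W2) / 2.0
                    phase = onset % period_ms
                    for i in range(n_gc):
                        dphi = t_pre_phase[i] - phase
                        if dphi > period_ms / 2.0:
                            dphi -= period_ms
                        elif dphi <= -period_ms / 2.0:
                            dphi += period_ms
                        if -half_w <= dphi <= half_w:
                            nw = w[j, i] - eta
                            w[j, i] = nw if nw > 0.0 else 0.0

        # non-associative potentiation toward w = 1 --------------------------
        if plastic and pot_rate > 0.0:
            for j in range(2):
                for i in range(n_gc):
                    w[j, i] += pot_rate * (1.0 - w[j, i])

    return 0


# ---------------------------------------------------------------------------
# state container and python driver
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Full mutable state of the 2-SP + granule network."""

    V_sp: np.ndarray
    refr_end: np.ndarray
    t_last: np.ndarray
    t_prev: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    r_d: np.ndarray
    k_dend: np.ndarray
    pend_t: np.ndarray
    pend_amp: np.ndarray
    hist_t: np.ndarray
    hist_flag: np.ndarray
    hist_n: np.ndarray
    V_gc: np.ndarray
    refr_gc: np.ndarray
    gsyn: np.ndarray
    weights: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, cfg: ModelConfig) -> "NetworkState":
        n_gc = cfg.gc.count_per_sp
        sp = cfg.sp
        return cls(
            V_sp=np.full(2, sp.V_rest),
            refr_end=np.full(2, -np.inf),
            t_last=np.full(2, -1e18),
            t_prev=np.full(2, -1e18),
            z1=np.zeros(2),
            z2=np.zeros(2),
            r_d=np.full(2, sp.D),
            k_dend=np.zeros(2),
            pend_t=np.full(2, -1.0),
            pend_amp=np.zeros(2),
            hist_t=np.zeros((2, 5)),
            hist_flag=np.zeros((2, 5), dtype=np.int64),
            hist_n=np.zeros(2, dtype=np.int64),
            V_gc=np.full((2, n_gc), sp.V_rest),
            refr_gc=np.full((2, n_gc), -np.inf),
            gsyn=np.zeros((2, n_gc)),
            weights=np.ones((2, n_gc)),
        )


def simulate_chunk(cfg: ModelConfig, state: NetworkState, xi_sp, xi_gc,
                   feedback_on: bool, plastic: bool,
                   record_gc: bool = False, gc_capacity: int = 0):
    """Advance the network by ``xi_sp.shape[1]`` steps; mutates ``state``.

    Returns ``(sp_spike_times_list, gc_times, gc_cell)`` for the chunk.
    """
    sp, gc, pl, st = cfg.sp, cfg.gc, cfg.plasticity, cfg.stimulus
    dt = cfg.dt_ms
    n_steps = xi_sp.shape[1]
    n_gc = gc.count_per_sp
    period_ms = st.period_ms
    delays = granule_delays(n_gc, st.f)
    t_pre_phase = granule_max_phase_times(n_gc, st.f)

    cap = n_steps // max(int(sp.r_s / dt), 1) + 16
    sp_times = np.zeros((2, cap))
    sp_counts = np.zeros(2, dtype=np.int64)
    if record_gc:
        gcap = gc_capacity or (2 * n_gc * n_steps // max(int(sp.r_s / dt), 1) + 16)
    else:
        gcap = 1
    gc_times = np.zeros(gcap)
    gc_cell = np.zeros(gcap, dtype=np.int64)
    gc_count = np.zeros(1, dtype=np.int64)

    if xi_gc is None:
        xi_gc_flat = np.zeros((1, n_steps))
    else:
        xi_gc_flat = xi_gc.reshape(2 * n_gc, n_steps)

    g_gaba = sp.g_GABA if feedback_on else 0.0
    g_max = sp.g_max if feedback_on else 0.0

    rc = _kernel(
        n_steps, dt, state.t,
        sp.C, sp.g_leak, sp.E_leak, sp.I, sp.sigma, st.kappa,
        sp.V_threshold, sp.V_rest, sp.r_s,
        g_gaba, sp.E_GABA, sp.E_AMPA, g_max, sp.tau_AMPA,
        sp.A, sp.B, sp.D, sp.E, sp.gamma, sp.alpha, sp.tau,
        st.f,
        feedback_on, n_gc, gc.rho, gc.g_relay, delays,
        xi_sp, xi_gc_flat,
        plastic, pl.eta_2, pl.eta_4, pl.L_W2, pl.L_W4,
        pl.tau_w * 1000.0, t_pre_phase, period_ms,
        state.V_sp, state.refr_end, state.t_last, state.t_prev,
        state.z1, state.z2, state.r_d, state.k_dend,
        state.pend_t, state.pend_amp,
        state.hist_t, state.hist_flag, state.hist_n,
        state.V_gc, state.refr_gc, state.gsyn, state.weights,
        sp_times, sp_counts, gc_times, gc_cell, gc_count, 1 if record_gc else 0,
    )
    if rc != 0:
        raise FloatingPointError(
            f"non-finite voltage in SP cell {rc - 1} near t = {state.t:.3f} ms")
    state.t += n_steps * dt
    spikes = [sp_times[j, : sp_counts[j]].copy() for j in range(2)]
    ngc = gc_count[0]
    return spikes, gc_times[:ngc].copy(), gc_cell[:ngc].copy()


def run_network(cfg: ModelConfig, duration_ms: float, noise_bundle,
                state: NetworkState | None = None,
                feedback_on: bool = True, plastic: bool = False,
                chunk_steps: int = 100_000, record_gc: bool = False):
    """Simulate for ``duration_ms``; returns (sp_spikes, gc_spikes, state).

    ``sp_spikes`` is a list of two arrays of spike times (ms, relative to the
    start of this run); ``gc_spikes`` is an (times, cell_index) tuple when
    ``record_gc`` is set, else empty arrays.
    """
    if state is None:
        state = NetworkState.initial(cfg)
    t_start = state.t
    n_total = int(round(duration_ms / cfg.dt_ms))
    collected = [[], []]
    gc_t_all, gc_c_all = [], []
    done = 0
    while done < n_total:
        n = min(chunk_steps, n_total - done)
        xi_sp, xi_gc = noise_bundle.next_chunk(n)
        spikes, gc_t, gc_c = simulate_chunk(
            cfg, state, xi_sp, xi_gc, feedback_on, plastic, record_gc=record_gc)
        for j in range(2):
            collected[j].append(spikes[j])
        if record_gc:
            gc_t_all.append(gc_t)
            gc_c_all.append(gc_c)
        done += n
    sp_spikes = [np.concatenate(collected[j]) - t_start if collected[j]
                 else np.zeros(0) for j in range(2)]
    if record_gc and gc_t_all:
        gc_spikes = (np.concatenate(gc_t_all) - t_start, np.concatenate(gc_c_all))
    else:
        gc_spikes = (np.zeros(0), np.zeros(0, dtype=np.int64))
    return sp_spikes, gc_spikes, state
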