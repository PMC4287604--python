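"""Structured low-pass-filtered Gaussian noise with tunable correlations.

The model's stochastic drive is Gaussian white noise passed through a causal
fourth-order low-pass Butterworth filter (500 Hz cutoff) and scaled to unit
variance.  Correlations are built by amplitude decomposition:

* SP cells:      xi_SP_i = sqrt(c)  * xi_shared + sqrt(1-c) * xi_unshared_i
* granule cells: xi_PF   = sqrt(e)  * xi_SP_j   + sqrt(1-e) * xi_private_i

where ``j`` indexes the SP cell the granule projects to (the deep-pyramidal
stream is identical to the SP stream of the same column).  Hence the pairwise
correlation between the two SP noises is exactly ``c``, between a granule
noise and its column's SP noise sqrt(e), between granules of the same column
``e``, and between granules of different columns ``e*c``.

Variance convention: the unit-variance white streams are composed first, the
composed stream is filtered, and the result is rescaled by the deterministic
white-noise gain of the filter, so every emitted process has unit variance
and the composition weights (hence the printed correlation coefficients)
are preserved exactly.  Filtering is forward-only (causal): the output at
step k depends only on white-noise samples at steps <= k.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .params import NoiseParams

__all__ = [
    "butter_lowpass",
    "filter_white_noise_gain",
    "NoiseBundle",
    "make_sp_noise",
    "make_granule_noise",
]


def butter_lowpass(order: int, cutoff_hz: float, dt_ms: float):
    """Butterworth low-pass coefficients for a sampling step of ``dt_ms``."""
    fs = 1000.0 / dt_ms  # Hz
    return signal.butter(order, cutoff_hz, fs=fs, btype="low")


def filter_white_noise_gain(b, a, n_impulse: int = 8192) -> float:
    """Std-dev gain of the filter on unit-variance white noise.

    Equal to the l2 norm of the impulse response; used to renormalise
    filtered streams back to unit variance deterministically.
    """
    impulse = np.zeros(n_impulse)
    impulse[0] = 1.0
    h = signal.lfilter(b, a, impulse)
    return float(np.sqrt(np.sum(h * h)))


class NoiseBundle:
    """Streaming generator of the composed, filtered, unit-variance noises.

    One master seed spawns named substreams (shared, unshared-0, unshared-1,
    granule-private i), so any single process is reproducible in isolation
    and chunked generation is exactly equivalent to one long draw.

    Parameters
    ----------
    params
        Correlation and filter settings.
    count_per_sp
        Granule cells per SP cell (granule streams are only drawn when
        ``with_granules`` is set).
    dt_ms
        Integration step; fixes the digital filter's sampling rate.
    seed
        Master seed (int or :class:`numpy.random.SeedSequence`).
    with_granules
        Whether granule noise is generated (off for feedback-off runs).
    """

    def __init__(
        self,
        params: NoiseParams,
        count_per_sp: int,
        dt_ms: float,
        seed,
        with_granules: bool = True,
    ):
        self.params = params
        self.count_per_sp = int(count_per_sp)
        self.dt_ms = float(dt_ms)
        self.with_granules = bool(with_granules)

        self.b, self.a = butter_lowpass(params.order, params.cutoff_hz, dt_ms)
        self._scale = 1.0 / filter_white_noise_gain(self.b, self.a)

        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        n_streams = 3 + (2 * self.count_per_sp if self.with_granules else 0)
        children = ss.spawn(n_streams)
        self._rng_shared = np.random.default_rng(children[0])
        self._rng_unshared = [np.random.default_rng(children[1]),
                              np.random.default_rng(children[2])]
        if self.with_granules:
            self._rng_private = [np.random.default_rng(ch) for ch in children[3:]]
        # one filter state per emitted process, carried across chunks
        n_proc = 2 + (2 * self.count_per_sp if self.with_granules else 0)
        self._zi = np.zeros((n_proc, max(len(self.a), len(self.b)) - 1))

    def next_chunk(self, n_steps: int):
        """Draw the next ``n_steps`` samples of every process.

        Returns
        -------
        xi_sp : (2, n_steps) array
            Composed SP noise processes.
        xi_gc : (2, count_per_sp, n_steps) array or None
            Composed granule noise processes, ``xi_gc[j, i]`` for granule i
            of SP j.  None when granule noise is disabled.
        """
        c = self.params.c
        e = self.params.e
        shared = self._rng_shared.standard_normal(n_steps)
        white_sp = np.empty((2, n_steps))
        for j in range(2):
            unshared = self._rng_unshared[j].standard_normal(n_steps)
            white_sp[j] = np.sqrt(c) * shared + np.sqrt(1.0 - c) * unshared

        if self.with_granules:
            white = np.empty((2 + 2 * self.count_per_sp, n_steps))
            white[:2] = white_sp
            k = 2
            for j in range(2):
                for i in range(self.count_per_sp):
                    private = self._rng_private[j * self.count_per_sp + i].standard_normal(n_steps)
                    white[k] = np.sqrt(e) * white_sp[j] + np.sqrt(1.0 - e) * private
                    k += 1
        else:
            white = white_sp

        filtered, self._zi = signal.lfilter(self.b, self.a, white, axis=-1, zi=self._zi)
        filtered *= self._scale
        xi_sp = filtered[:2]
        xi_gc = None
        if self.with_granules:
            xi_gc = filtered[2:].reshape(2, self.count_per_sp, n_steps)
        return xi_sp, xi_gc


def make_sp_noise(
    c: float,
    n_steps: int,
    dt_ms: float = 0.05,
    seed=0,
    cutoff_hz: float = 500.0,
    order: int = 4,
) -> np.ndarray:
    """Two unit-variance low-pass noise processes with correlation ``c``.

    Returns a (2, n_steps) array.
    """
    params = NoiseParams(c=c, e=0.0, cutoff_hz=cutoff_hz, order=order)
    bundle = NoiseBundle(params, count_per_sp=1, dt_ms=dt_ms, seed=seed,
                         with_granules=False)
    xi_sp, _ = bundle.next_chunk(n_steps)
    return xi_sp


def make_granule_noise(
    e: float,
    c: float,
    count_per_sp: int,
    n_steps: int,
    dt_ms: float = 0.05,
    seed=0,
    cutoff_hz: float = 500.0,
    order: int = 4,
):
    """SP and granule noise processes with the full shared/column/private
    structure.  Returns ``(xi_sp, xi_gc)`` with shapes (2, n) and
    (2, count_per_sp, n)."""
    params = NoiseParams(c=c, e=e, cutoff_hz=cutoff_hz, order=order)
    bundle = NoiseBundle(params, count_per_sp=count_per_sp, dt_ms=dt_ms,
                         seed=seed, with_granules=True)
    return bundle.next_chunk(n_steps)
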