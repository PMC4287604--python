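"""Correlogram statistics: ACG, CCG, shuffle predictor, signal/noise split.

All correlograms are expressed as coincidence rates relative to chance, in
units of 1/ms.  For spike trains binned at width ``dt`` (default 0.5 ms) into
count sequences X(t):

* auto-correlogram      A(tau)  = (1/(N dt))  sum_t X(t) X(t+tau)   - m
* cross-correlogram     C(tau)  = (1/(N1 dt)) sum_t X1(t) X2(t+tau) - m2

with N the spike count of the averaging train and m the mean rate (spikes per
ms) of the other; the sum runs over the spikes of cell 1 and lags where the
shifted windows overlap (no wraparound), with the counts at lag tau rescaled
by n_bins/(n_bins - |tau|) so the chance-level subtraction stays unbiased at
every lag despite the shrinking overlap.  The cross-correlation coefficient
averages the correlogram over a lag window W:

    R = <C(tau)>_W / sqrt(<A1(tau)>_W <A2(tau)>_W)

To split signal from noise correlations, responses are segmented into the M
stimulus cycles.  The shuffle predictor is the cross-cycle (j != k) averaged
CCG; the cycle-matched (j = k) averaged CCG is the corresponding raw
estimate, and the noise CCG is their pointwise difference, so that

    raw(tau) = shuffle(tau) + noise(tau)      (exactly, at every lag).

Coefficient conventions (the source equations define R on the raw CCG only):
``R_signal`` applies R to the shuffle predictor with a denominator built
from the shuffle (stimulus-locked) ACGs plus the lag-0 spike self-term, so
it is insensitive to added trial-to-trial noise power while a feedback
pathway that cancels the stimulus-locked modulation still reduces it; ``R_noise`` applies R to the noise CCG with the
shuffle-corrected (noise) ACGs in the denominator — the standard r_CCG of
the noise-correlation literature — so that two cells receiving identical
input have R_noise = 1 exactly.

The default lag window is one quarter of the stimulus period on each side of
zero: a window of a full period would average the stimulus-periodic
correlogram over a whole oscillation and annihilate the signal component.
The window is configurable and recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .spiketrains import SpikeTrain

__all__ = [
    "BinnedTrain",
    "Correlogram",
    "CorrelationResult",
    "bin_spikes",
    "acg",
    "ccg",
    "correlation_coefficient",
    "segment_cycles",
    "shuffle_predictor",
    "noise_ccg",
    "cycle_correlograms",
    "signal_noise_coefficients",
    "DEFAULT_BINWIDTH_MS",
]

DEFAULT_BINWIDTH_MS = 0.5


@dataclass
class BinnedTrain:
    counts: np.ndarray
    dt: float
    duration_ms: float

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())


@dataclass
class Correlogram:
    """Lag-indexed coincidence rate relative to chance (1/ms)."""

    lags_ms: np.ndarray
    values: np.ndarray
    kind: str = "cross"  # auto | cross | shuffle | noise
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_ms.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")


def bin_spikes(train: SpikeTrain, dt: float = DEFAULT_BINWIDTH_MS) -> BinnedTrain:
    """Bin spikes into half-open bins [k*dt, (k+1)*dt); counts are conserved."""
    if dt <= 0:
        raise ValueError("binwidth must be > 0")
    n_bins = int(np.ceil(train.duration_ms / dt))
    idx = np.floor(train.spike_times / dt).astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n_bins):
        raise ValueError("spike outside [0, duration)")
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return BinnedTrain(counts=counts, dt=dt, duration_ms=train.duration_ms)


def _lag_counts(x1: np.ndarray, x2: np.ndarray, max_bins: int) -> np.ndarray:
    """S(j) = sum_k x1[k] * x2[k+j] for j in [-max_bins, max_bins].

    Out-of-range terms are dropped (full-overlap / zero-padding convention).
    """
    k = len(x1)
    if k <= 4096:
        full = np.correlate(x2, x1, mode="full")  # index j + k - 1 holds S(j)
    else:
        full = _sig.fftconvolve(x2, x1[::-1], mode="full")
    center = k - 1
    lo, hi = center - max_bins, center + max_bins + 1
    out = np.zeros(2 * max_bins + 1)
    src_lo, src_hi = max(lo, 0), min(hi, len(full))
    out[src_lo - lo: src_hi - lo] = full[src_lo:src_hi]
    return out


def _lag_axis(max_bins: int, dt: float) -> np.ndarray:
    return np.arange(-max_bins, max_bins + 1) * dt


def _overlap_correction(n_bins: int, max_bins: int) -> np.ndarray:
    """Edge correction: at lag j only n_bins - |j| bin pairs overlap, so raw
    coincidence counts are scaled by n_bins/(n_bins - |j|) to keep the
    chance-level subtraction unbiased at every lag."""
    j = np.abs(np.arange(-max_bins, max_bins + 1))
    return n_bins / np.maximum(n_bins - j, 1)


def acg(train: SpikeTrain, max_lag_ms: float, dt: float = DEFAULT_BINWIDTH_MS) -> Correlogram:
    """Auto-correlogram; symmetric in lag; lag-0 self-coincidences included."""
    if len(train) == 0:
        raise ValueError("ACG undefined for an empty train")
    binned = bin_spikes(train, dt)
    n = binned.n_spikes
    m = n / train.duration_ms
    lbins = int(round(max_lag_ms / dt))
    corr = _overlap_correction(len(binned.counts), lbins)
    values = corr * _lag_counts(binned.counts, binned.counts, lbins) / (n * dt) - m
    return Correlogram(_lag_axis(lbins, dt), values, kind="auto",
                       meta={"N": n, "m_per_ms": m, "dt": dt})


def ccg(train1: SpikeTrain, train2: SpikeTrain, max_lag_ms: float,
        dt: float = DEFAULT_BINWIDTH_MS) -> Correlogram:
    """Cross-correlogram, averaged over the spikes of cell 1."""
    if train1.duration_ms != train2.duration_ms:
        raise ValueError("trains must share a duration")
    b1, b2 = bin_spikes(train1, dt), bin_spikes(train2, dt)
    n1 = b1.n_spikes
    if n1 == 0:
        raise ValueError("CCG undefined when the averaging train is empty")
    m2 = b2.n_spikes / train2.duration_ms
    lbins = int(round(max_lag_ms / dt))
    corr = _overlap_correction(len(b1.counts), lbins)
    values = corr * _lag_counts(b1.counts, b2.counts, lbins) / (n1 * dt) - m2
    return Correlogram(_lag_axis(lbins, dt), values, kind="cross",
                       meta={"N1": n1, "m2_per_ms": m2, "dt": dt})


def correlation_coefficient(cross: Correlogram, auto1: Correlogram,
                            auto2: Correlogram,
                            lag_window_ms: float | None = None) -> float:
    """Lag-averaged coefficient R = <C> / sqrt(<A1><A2>) over |lag| <= W."""
    for other in (auto1, auto2):
        if not np.array_equal(cross.lags_ms, other.lags_ms):
            raise ValueError("correlograms must share the lag axis")
    if lag_window_ms is None:
        sel = slice(None)
    else:
        sel = np.abs(cross.lags_ms) <= lag_window_ms + 1e-9
    num = cross.values[sel].mean()
    d1 = auto1.values[sel].mean()
    d2 = auto2.values[sel].mean()
    if d1 <= 0 or d2 <= 0:
        raise ValueError("non-positive lag-averaged autocorrelogram; "
                         "correlation coefficient undefined")
    return float(num / np.sqrt(d1 * d2))


# ---------------------------------------------------------------------------
# cycle segmentation and the shuffle-predictor pipeline
# ---------------------------------------------------------------------------

def segment_cycles(trains, period_ms: float,
                   dt: float = DEFAULT_BINWIDTH_MS) -> np.ndarray:
    """Stack per-cycle binned responses of one neuron into an (M, P) matrix.

    ``trains`` is a single :class:`SpikeTrain` or an iterable of them (one per
    trial); trials must start at stimulus phase zero.  Trailing partial
    cycles are discarded.
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    p_bins = int(round(period_ms / dt))
    rows = []
    for tr in trains:
        counts = bin_spikes(tr, dt).counts
        m = len(counts) // p_bins
        rows.append(counts[: m * p_bins].reshape(m, p_bins))
    if not rows:
        return np.zeros((0, p_bins))
    return np.concatenate(rows, axis=0)


def _per_cycle_norm(x: np.ndarray, dt: float):
    """Per-cycle spike counts, per-cycle rates (1/ms) and count-normalised
    responses (rows with zero spikes give a zero row)."""
    n = x.sum(axis=1)
    p = x.shape[1]
    m = n / (p * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(n[:, None] > 0, x / np.where(n[:, None] > 0, n[:, None], 1.0), 0.0)
    return n, m, y


def _rowwise_corr_sum(y: np.ndarray, x: np.ndarray, max_bins: int) -> np.ndarray:
    """sum_k S(y_k, x_k)(j) for j in [-max_bins, max_bins] via FFT."""
    p = y.shape[1]
    full = _sig.fftconvolve(x, y[:, ::-1], mode="full", axes=1).sum(axis=0)
    center = p - 1
    lo, hi = center - max_bins, center + max_bins + 1
    out = np.zeros(2 * max_bins + 1)
    src_lo, src_hi = max(lo, 0), min(hi, len(full))
    out[src_lo - lo: src_hi - lo] = full[src_lo:src_hi]
    return out


def cycle_correlograms(x1: np.ndarray, x2: np.ndarray, max_lag_ms: float,
                       dt: float = DEFAULT_BINWIDTH_MS) -> dict:
    """Cycle-matched raw, shuffle-predictor and noise correlograms.

    ``x1``/``x2`` are (M, P) per-cycle count matrices of the two neurons
    (``x2 is x1`` yields the auto versions).  The shuffle predictor averages
    over the ordered cycle pairs j != k whose averaging cycle k contains at
    least one spike of neuron 1; the O(M^2) double sum is evaluated with the
    algebraic identity

        sum_{j != k} corr(y_k, x_j) = corr(sum_k y_k, sum_j x_j)
                                      - sum_k corr(y_k, x_k)

    which is exact.  Returns a dict with 'raw', 'shuffle', 'noise'
    :class:`Correlogram` objects; raw = shuffle + noise at every lag.
    """
    m_cycles = x1.shape[0]
    if m_cycles < 2:
        raise ValueError("at least 2 stimulus cycles are required")
    if x1.shape != x2.shape:
        raise ValueError("cycle matrices must share a shape")
    lbins = int(round(max_lag_ms / dt))
    n1, m2, y1 = _per_cycle_norm(x1, dt)
    _, m2_b, _ = _per_cycle_norm(x2, dt)
    m2 = m2_b
    # the per-cycle normalisation 1/N_{1,k} is undefined for cycles in which
    # the averaging neuron is silent; those cycles are excluded from the
    # average (they contribute no spikes to average over)
    valid = n1 > 0
    m_valid = int(valid.sum())
    if m_valid == 0:
        raise ValueError("averaging train has no spikes in any cycle")

    matched = _rowwise_corr_sum(y1, x2, lbins)  # invalid rows are zero
    y1_sum = y1.sum(axis=0)
    x2_sum = x2.sum(axis=0)
    pooled = _lag_counts(y1_sum, x2_sum, lbins)

    mean_m2_matched = m2[valid].mean()
    # sum over valid k of sum_{j != k} m2_j
    m2_cross = (m_cycles * m2.mean() * m_valid - m2[valid].sum())
    over = _overlap_correction(x1.shape[1], lbins)
    raw = over * matched / (m_valid * dt) - mean_m2_matched
    shuf = (over * (pooled - matched) / (m_valid * (m_cycles - 1) * dt)
            - m2_cross / (m_valid * (m_cycles - 1)))
    lags = _lag_axis(lbins, dt)
    meta = {"M": m_cycles, "M_valid": m_valid, "dt": dt}
    return {
        "raw": Correlogram(lags, raw, kind="cross", meta=meta),
        "shuffle": Correlogram(lags, shuf, kind="shuffle", meta=meta),
        "noise": Correlogram(lags, raw - shuf, kind="noise", meta=meta),
    }


def shuffle_predictor(x1: np.ndarray, x2: np.ndarray, max_lag_ms: float,
                      dt: float = DEFAULT_BINWIDTH_MS) -> Correlogram:
    """Cross-cycle (j != k) averaged CCG: the signal-correlation estimate."""
    return cycle_correlograms(x1, x2, max_lag_ms, dt)["shuffle"]


def noise_ccg(raw: Correlogram, shuffle: Correlogram) -> Correlogram:
    """Pointwise raw minus shuffle predictor."""
    if not np.array_equal(raw.lags_ms, shuffle.lags_ms):
        raise ValueError("lag axes do not match")
    return Correlogram(raw.lags_ms, raw.values - shuffle.values, kind="noise",
                       meta=dict(raw.meta))


@dataclass
class CorrelationResult:
    """Signal/noise correlation coefficients for one neuron pair."""

    R_raw: float
    R_signal: float
    R_noise: float
    correlograms: dict
    meta: dict


def signal_noise_coefficients(trains1, trains2, period_ms: float,
                              dt: float = DEFAULT_BINWIDTH_MS,
                              lag_window_ms: float | None = None,
                              noise_lag_window_ms: float = 25.0,
                              max_lag_ms: float | None = None) -> CorrelationResult:
    """Full pipeline: segment into cycles, correlograms, R coefficients.

    ``trains1``/``trains2`` are the per-trial spike trains of the two
    neurons; trials must be phase-aligned to the stimulus.  The raw/signal
    lag window defaults to one quarter period (the stimulus-locked
    correlogram structure lives on the period timescale); the noise
    coefficient uses its own, narrower window matched to the width of the
    shared-noise correlogram peak (input bandwidth and membrane
    integration, a few ms), which would otherwise be diluted by lags that
    carry no noise-correlation signal.
    """
    if lag_window_ms is None:
        lag_window_ms = period_ms / 4.0
    if max_lag_ms is None:
        max_lag_ms = max(lag_window_ms, noise_lag_window_ms)
    x1 = segment_cycles(trains1, period_ms, dt)
    x2 = segment_cycles(trains2, period_ms, dt)
    cc = cycle_correlograms(x1, x2, max_lag_ms, dt)
    a1 = cycle_correlograms(x1, x1, max_lag_ms, dt)
    a2 = cycle_correlograms(x2, x2, max_lag_ms, dt)

    lags = cc["raw"].lags_ms
    sel_sig = np.abs(lags) <= lag_window_ms + 1e-9
    sel_noise = np.abs(lags) <= noise_lag_window_ms + 1e-9

    def _avg(corr, sel):
        return corr.values[sel].mean()

    d_raw = np.sqrt(_avg(a1["raw"], sel_sig) * _avg(a2["raw"], sel_sig))
    d_noise_1 = _avg(a1["noise"], sel_noise)
    d_noise_2 = _avg(a2["noise"], sel_noise)
    if d_raw <= 0:
        raise ValueError("non-positive raw autocorrelogram average")
    r_raw = _avg(cc["raw"], sel_sig) / d_raw
    # signal denominator: stimulus-locked autocovariance plus the lag-0
    # spike self-term.  The trial-to-trial (noise) autocovariance is
    # excluded so the signal coefficient does not shrink merely because the
    # cells got noisier; the self-term keeps it normalised by overall
    # firing, so cancelling the stimulus-locked modulation still lowers it.
    n_sel = int(np.count_nonzero(sel_sig))
    d_sig_terms = []
    for a, x in ((a1, x1), (a2, x2)):
        m_bar = x.sum() / (x.size * dt)
        self_term = max(1.0 / dt - m_bar, 0.0) / n_sel
        d_sig_terms.append(_avg(a["shuffle"], sel_sig) + self_term)
    d_sig = np.sqrt(max(d_sig_terms[0], 0.0) * max(d_sig_terms[1], 0.0))
    if d_sig <= 0:
        raise ValueError("non-positive signal autocorrelogram average")
    r_signal = _avg(cc["shuffle"], sel_sig) / d_sig
    if d_noise_1 <= 0 or d_noise_2 <= 0:
        r_noise = float("nan")
    else:
        r_noise = _avg(cc["noise"], sel_noise) / np.sqrt(d_noise_1 * d_noise_2)
    meta = {
        "dt": dt,
        "period_ms": period_ms,
        "lag_window_ms": lag_window_ms,
        "noise_lag_window_ms": noise_lag_window_ms,
        "max_lag_ms": max_lag_ms,
        "M_cycles": x1.shape[0],
    }
    return CorrelationResult(float(r_raw), float(r_signal), float(r_noise),
                             {"cross": cc, "auto1": a1, "auto2": a2}, meta)
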