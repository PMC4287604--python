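"""Parameter sweeps over the correlation mechanisms.

Each sweep trains the parallel-fiber weights once under the reference
configuration, freezes them, and evaluates the frozen network across the
grid (retraining per point is available via ``retrain_per_point``; the
stimulus-frequency sweep always retrains because the negative image is
frequency specific).  At rho = 0 the granule rasters are deterministic
regardless of the trained weights, so the ratio anchor at 1 is preserved
without retraining.

Uncertainties are trial-level bootstrap percentiles — an artifact-added
diagnostic, since the underlying model surfaces are reported without error
bars.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import signal_noise_coefficients
from .params import ModelConfig
from .plasticity import train_negative_image
from .protocols import evaluate_weights

__all__ = [
    "pair_coefficients",
    "bootstrap_coefficients",
    "sweep_rho",
    "sweep_c_e",
    "sweep_c_f",
]


def pair_coefficients(trains: dict, period_ms: float, **kwargs):
    """(R_raw, R_signal, R_noise) from a {0: [...], 1: [...]} train dict."""
    res = signal_noise_coefficients(trains[0], trains[1], period_ms, **kwargs)
    return res.R_raw, res.R_signal, res.R_noise


def bootstrap_coefficients(trains: dict, period_ms: float, n_boot: int = 200,
                           seed=0, **kwargs) -> dict:
    """Trial-level bootstrap of the three coefficients.

    Returns arrays of shape (n_boot,) under keys 'R_raw', 'R_signal',
    'R_noise'.
    """
    rng = np.random.default_rng(seed)
    n_trials = len(trains[0])
    out = {"R_raw": [], "R_signal": [], "R_noise": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n_trials, size=n_trials)
        res = signal_noise_coefficients([trains[0][i] for i in idx],
                                        [trains[1][i] for i in idx],
                                        period_ms, **kwargs)
        out["R_raw"].append(res.R_raw)
        out["R_signal"].append(res.R_signal)
        out["R_noise"].append(res.R_noise)
    return {k: np.asarray(v) for k, v in out.items()}


def _eval_point(cfg: ModelConfig, weights, geometry: str, n_trials: int,
                trial_duration_s: float, seed, n_boot: int) -> dict:
    trains = evaluate_weights(cfg, weights, n_trials, trial_duration_s, seed,
                              geometry=geometry)
    period = cfg.stimulus.period_ms
    r_raw, r_sig, r_noise = pair_coefficients(trains, period)
    row = {"R_raw": r_raw, "R_signal": r_sig, "R_noise": r_noise}
    if n_boot:
        boot = bootstrap_coefficients(trains, period, n_boot=n_boot, seed=seed)
        for key in ("R_signal", "R_noise"):
            row[f"{key}_lo"] = float(np.percentile(boot[key], 2.5))
            row[f"{key}_hi"] = float(np.percentile(boot[key], 97.5))
    return row


def sweep_rho(cfg: ModelConfig, rho_grid, n_trials: int = 20,
              trial_duration_s: float = 10.0, training_duration_s: float = 200.0,
              seed: int = 0, n_boot: int = 100) -> pd.DataFrame:
    """Global/local coefficient ratios vs granule noise intensity rho.

    The local baseline is computed once (it has no granule pathway and is
    rho-invariant).  The weights are retrained at every rho: granule cells
    sit close to threshold, so rho sets their mean firing rate as well as
    their variability, and frozen weights from another rho would put the
    feedback loop at a different operating point.
    """
    ss = np.random.SeedSequence(seed)
    s_local, *s_pts = ss.spawn(1 + 2 * len(rho_grid))
    local = _eval_point(cfg, None, "local", n_trials, trial_duration_s,
                        s_local, n_boot)
    rows = []
    for i, rho in enumerate(rho_grid):
        cfg_pt = cfg.replace(gc=replace(cfg.gc, rho=float(rho)))
        training = train_negative_image(cfg_pt, duration_s=training_duration_s,
                                        seed=s_pts[2 * i], snapshot_times_s=())
        glob = _eval_point(cfg_pt, training["final_weights"], "global",
                           n_trials, trial_duration_s, s_pts[2 * i + 1], n_boot)
        rows.append({
            "rho": float(rho),
            "R_signal_local": local["R_signal"],
            "R_noise_local": local["R_noise"],
            "R_signal_global": glob["R_signal"],
            "R_noise_global": glob["R_noise"],
            "ratio_signal": glob["R_signal"] / local["R_signal"],
            "ratio_noise": glob["R_noise"] / local["R_noise"],
            **{f"global_{k}": v for k, v in glob.items()
               if k.endswith(("_lo", "_hi"))},
        })
    return pd.DataFrame(rows)


def sweep_c_e(cfg: ModelConfig, c_grid, e_grid, n_trials: int = 10,
              trial_duration_s: float = 10.0, training_duration_s: float = 200.0,
              seed: int = 0, n_boot: int = 0) -> pd.DataFrame:
    """R_noise surfaces vs (c, e) for both geometries, plus the difference."""
    ss = np.random.SeedSequence(seed)
    s_train, s_eval = ss.spawn(2)
    training = train_negative_image(cfg, duration_s=training_duration_s,
                                    seed=s_train, snapshot_times_s=())
    weights = training["final_weights"]
    rows = []
    children = iter(s_eval.spawn(len(c_grid) * (1 + len(e_grid))))
    for c in c_grid:
        cfg_c = cfg.replace(noise=replace(cfg.noise, c=float(c)))
        local = _eval_point(cfg_c, None, "local", n_trials, trial_duration_s,
                            next(children), n_boot)
        for e in e_grid:
            cfg_ce = cfg_c.replace(noise=replace(cfg_c.noise, e=float(e)))
            glob = _eval_point(cfg_ce, weights, "global", n_trials,
                               trial_duration_s, next(children), n_boot)
            rows.append({
                "c": float(c), "e": float(e),
                "R_noise_local": local["R_noise"],
                "R_noise_global": glob["R_noise"],
                "difference": local["R_noise"] - glob["R_noise"],
            })
    return pd.DataFrame(rows)


def sweep_c_f(cfg: ModelConfig, c_grid, f_grid, n_trials: int = 10,
              trial_duration_s: float = 10.0, training_duration_s: float = 200.0,
              seed: int = 0, n_boot: int = 0) -> pd.DataFrame:
    """R_noise surfaces vs (c, f); retrains per frequency (the negative image
    is frequency specific)."""
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(f_grid) * (1 + 2 * len(c_grid))))
    rows = []
    for f in f_grid:
        cfg_f = cfg.replace(stimulus=replace(cfg.stimulus, f=float(f)))
        training = train_negative_image(cfg_f, duration_s=training_duration_s,
                                        seed=next(children), snapshot_times_s=())
        weights = training["final_weights"]
        for c in c_grid:
            cfg_cf = cfg_f.replace(noise=replace(cfg_f.noise, c=float(c)))
            local = _eval_point(cfg_cf, None, "local", n_trials,
                                trial_duration_s, next(children), n_boot)
            glob = _eval_point(cfg_cf, weights, "global", n_trials,
                               trial_duration_s, next(children), n_boot)
            rows.append({
                "c": float(c), "f": float(f),
                "R_noise_local": local["R_noise"],
                "R_noise_global": glob["R_noise"],
                "difference": local["R_noise"] - glob["R_noise"],
            })
    return pd.DataFrame(rows)
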