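"""Simulation protocols: local vs global geometry, train/freeze/evaluate.

Local geometry mimics spatially restricted stimulation, which does not
recruit the granule-cell feedback: g_max and g_GABA are set to zero and the
granule bank is silent, so local runs are invariant to rho, e and all
plasticity parameters.  Global geometry first trains the parallel-fiber
weights to equilibrium under the plasticity rule, freezes them, and then
runs the evaluation trials with fixed weights (avoiding non-stationarities).

Each trial is an independent realisation: fresh dynamical state, stimulus
phase starting at zero (so cycles align across trials, as the shuffle
predictor requires) and an independent noise substream spawned from the
protocol's master seed.
"""

from __future__ import annotations

import numpy as np

from .model import NetworkState, run_network
from .noise import NoiseBundle
from .params import ModelConfig, ProtocolSpec
from .plasticity import train_negative_image
from .spiketrains import SpikeTrain

__all__ = ["run_protocol", "evaluate_weights", "run_training_timecourse"]


def _trials(cfg: ModelConfig, weights, geometry: str, n_trials: int,
            trial_duration_s: float, trial_seeds) -> dict:
    """Run independent frozen-weight trials; returns per-neuron train lists."""
    feedback = geometry == "global"
    dur_ms = trial_duration_s * 1000.0
    trains = {0: [], 1: []}
    for trial_id, child in enumerate(trial_seeds):
        state = NetworkState.initial(cfg)
        if weights is not None:
            state.weights[:] = weights
        bundle = NoiseBundle(cfg.noise, cfg.gc.count_per_sp, cfg.dt_ms,
                             child, with_granules=feedback)
        spikes, _, _ = run_network(cfg, dur_ms, bundle, state=state,
                                   feedback_on=feedback, plastic=False)
        for j in range(2):
            times = spikes[j][spikes[j] < dur_ms]
            trains[j].append(SpikeTrain(times, dur_ms, neuron_id=j,
                                        trial_id=trial_id))
    return trains


def run_protocol(cfg: ModelConfig, spec: ProtocolSpec) -> dict:
    """Full protocol: (train, freeze,) evaluate; returns trains + metadata.

    Returns a dict with ``trains`` ({neuron_id: [SpikeTrain, ...]}),
    ``weights`` (frozen weights used for evaluation; None for local) and
    ``meta`` (all parameters and seeds needed to re-run).
    """
    ss = np.random.SeedSequence(spec.seed)
    train_seed, *trial_seeds = ss.spawn(1 + spec.n_trials)
    weights = None
    training = None
    if spec.geometry == "global":
        training = train_negative_image(cfg, duration_s=spec.training_duration_s,
                                        seed=train_seed, snapshot_times_s=())
        weights = training["final_weights"]
    trains = _trials(cfg, weights, spec.geometry, spec.n_trials,
                     spec.trial_duration_s, trial_seeds)
    meta = {
        "geometry": spec.geometry,
        "seed": spec.seed,
        "n_trials": spec.n_trials,
        "trial_duration_s": spec.trial_duration_s,
        "training_duration_s": (spec.training_duration_s
                                if spec.geometry == "global" else 0.0),
        "config": cfg.to_dict(),
    }
    return {"trains": trains, "weights": weights, "meta": meta,
            "training": training}


def evaluate_weights(cfg: ModelConfig, weights, n_trials: int,
                     trial_duration_s: float, seed,
                     geometry: str = "global") -> dict:
    """Frozen-weight evaluation trials (the inner loop of the protocols)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n_trials)
    return _trials(cfg, weights, geometry, n_trials, trial_duration_s,
                   trial_seeds)


def run_training_timecourse(cfg: ModelConfig, training_duration_s: float,
                            snapshot_times_s, n_trials: int,
                            trial_duration_s: float, seed=0) -> dict:
    """Train once, then evaluate frozen weights at each snapshot time.

    Weights are frozen at their value at the corresponding training time so
    the evaluation is stationary.  Returns ``snapshot_times_s``, the weight
    ``snapshots`` and per-snapshot ``evaluations`` (train dicts as returned
    by :func:`evaluate_weights`).
    """
    for t in snapshot_times_s:
        if t > training_duration_s:
            raise ValueError("snapshot beyond training duration")
    ss = np.random.SeedSequence(seed)
    train_seed, eval_seed = ss.spawn(2)
    training = train_negative_image(cfg, duration_s=training_duration_s,
                                    seed=train_seed,
                                    snapshot_times_s=snapshot_times_s)
    evaluations = []
    eval_children = eval_seed.spawn(len(training["snapshots"]))
    for w, child in zip(training["snapshots"], eval_children):
        evaluations.append(evaluate_weights(cfg, w, n_trials,
                                            trial_duration_s, child))
    return {
        "snapshot_times_s": training["snapshot_times_s"],
        "snapshots": training["snapshots"],
        "evaluations": evaluations,
        "training": training,
    }
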