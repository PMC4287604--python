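# ellnet

Spiking-network model of paired pyramidal cells in the electrosensory
lateral line lobe (ELL) with plastic parallel-fiber feedback, plus the
shuffle-predictor correlogram analysis that separates **signal** from
**noise** correlations between their spike trains.

## The problem

Neighboring sensory neurons are correlated both because they see the same
stimulus (signal correlations) and because they share noise (noise
correlations, the correlations of their trial-to-trial variability).  In
weakly electric fish, spatially diffuse ("global") stimulation — unlike
spatially restricted ("local") stimulation — recruits a diffuse granule-cell
feedback pathway onto superficial pyramidal (SP) cells, and both kinds of
correlation drop sharply.  This package implements a two-cell network that
reproduces that effect and dissects it into two independent mechanisms:

1. **Signal correlations** fall because anti-Hebbian burst-timing-dependent
   depression at the parallel-fiber synapses builds a *negative image* of
   the stimulus, cancelling each cell's stimulus-locked modulation.
2. **Noise correlations** fall because granule-cell spiking is variable
   from trial to trial, injecting variability into each SP cell through
   largely disjoint granule banks.

It is intended for computational neuroscientists studying correlation
control in cerebellum-like circuits, and as a reference implementation of
the shuffle-predictor signal/noise decomposition for periodic stimuli.

## The model and statistics in brief

Each SP cell is a noisy leaky integrate-and-fire neuron with a
depolarizing-afterpotential burst mechanism, driven by a half-wave-rectified
sinusoid `F(kappa sin 2 pi f t)`, low-pass-filtered Gaussian noise with
pairwise input correlation `c`, and — under global geometry — constant GABA
inhibition plus AMPA input from 100 spiking granule cells whose delays tile
the stimulus period.  Granule noise is inherited from the deep-pyramidal
stream with fraction `e`.  Weights follow burst-triggered depression
(`eta_2`, `eta_4` inside windows `L_W2`, `L_W4`) against slow potentiation
(time constant `tau_w`).

Analysis: spike trains binned at 0.5 ms; auto/cross-correlograms `A(tau)`,
`C(tau)` as coincidence rates relative to chance; responses segmented into
the M stimulus cycles; the shuffle predictor (cross-cycle averaged CCG)
estimates the signal part and `C_noise = C_raw - C_shuffle` the noise part,
exactly at every lag.  Scalar coefficients are lag-window averages

    R = <C> / sqrt(<A1> <A2>)

with shuffle-corrected autocorrelograms in the denominator for the noise
coefficient (the r_CCG convention: identical inputs give R_noise = 1).
See `docs/methods.md` for every convention and reconstruction decision.

## Worked example

Simulate both stimulation geometries at desk scale and compare the
coefficients (about two minutes; the global run trains the weights first):

```python
from ellnet import ModelConfig, ProtocolSpec
from ellnet.protocols import run_protocol
from ellnet.analysis import signal_noise_coefficients

cfg = ModelConfig()                      # printed default parameters
period = cfg.stimulus.period_ms          # 250 ms at f = 4 Hz

for geometry in ("local", "global"):
    spec = ProtocolSpec(geometry=geometry, n_trials=10, trial_duration_s=10.0,
                        training_duration_s=150.0, seed=1)
    out = run_protocol(cfg, spec)
    r = signal_noise_coefficients(out["trains"][0], out["trains"][1], period)
    print(f"{geometry:6s}  R_signal={r.R_signal:6.3f}  R_noise={r.R_noise:6.3f}")
```

Output from this exact script:

```
local   R_signal= 0.676  R_noise= 0.177
global  R_signal= 0.051  R_noise= 0.096
```

Local stimulation leaves the feedback silent: the pair is strongly
stimulus-locked (R_signal ≈ 0.68) and shares noise through the common
feedforward input (R_noise ≈ 0.18 at c = 0.25).  Global stimulation recruits
the trained feedback: the negative image cancels most of the stimulus-locked
response (R_signal drops ~95%) and granule trial-to-trial variability
dilutes the shared noise (R_noise drops ~45% at this short desk scale, more
at the full protocol scale) — both beyond the >40% reduction seen in vivo.  The same pipeline runs from the command line
(`ellnet simulate`, `ellnet analyze`, `ellnet sweep`, `ellnet train`).

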