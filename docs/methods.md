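# Methods

## The model

`ellnet` simulates a pair of superficial pyramidal (SP) cells of the
electrosensory lateral line lobe (ELL), a cerebellum-like hindbrain
structure of weakly electric fish, and asks how the diffuse parallel-fiber
feedback they receive from granule cells reshapes the correlations between
their spike trains.  Sensory drive is a sinusoidal amplitude modulation of
the fish's electric field; *local* (spatially restricted) stimulation does
not recruit the feedback pathway while *global* (diffuse) stimulation does.
The package's claim under test is that the feedback reduces the two kinds of
pairwise correlation through two independent mechanisms: stimulus-locked
(signal) correlations fall because anti-Hebbian burst plasticity builds a
negative image of the stimulus, and trial-to-trial (noise) correlations fall
because granule-cell firing is variable across trials.

### SP cells

Each SP cell is a leaky integrate-and-fire neuron (Euler–Maruyama
integration, dt = 0.05 ms),

    C dV/dt = -g_leak (V - E_leak) + I + sigma * xi_SP(t)
              + F(kappa sin(2 pi f t)) + DAP(t)
              - g_GABA (V - E_GABA) - g_max sum_s w_s g_s(t) (V - E_AMPA)

with threshold crossing detected at the end of a step, reset to V_rest, and
an absolute refractory clamp for r_s = 0.7 ms.  F is a half-wave rectifier
applied to the stimulus term (electroreceptor afferents rectify); its
placement is isolated in `ellnet.model.rectified_stimulus` so the choice is
auditable.  Defaults are the published homogeneous-network values
(V_threshold = -65 mV, V_rest = E_leak = E_GABA = -68.8 mV, g_leak = 0.14
mS/cm^2, I = 0.313 uA/cm^2, sigma = 0.412 uA/cm^2, kappa = 0.21 uA/cm^2,
f = 4 Hz, ...; see `ellnet.params`).

Bursting is produced by a depolarizing afterpotential (DAP).  The source
equations for the DAP were available only as prose plus a printed constant
list, so the implementation is this package's own reconstruction of the
cited dynamic-dendritic-refractory mechanism, stated here as the model
definition.  The DAP depends on the last two somatic spike times only: a
spike at t_n launches, r_s later, the current amp * s(t - t_n - r_s, tau)
with the alpha function s(t, a) = (t/a) exp(1 - t/a), provided the
inter-spike interval exceeded the dendritic refractory period r_d (a
dendritic failure produces no DAP, and each spike replaces the previous
DAP).  Consecutive dendritic successes potentiate the amplitude,
amp = alpha (A + gamma k), and multiply the refractory period, r_d <- B r_d;
between spikes r_d relaxes to its baseline with dr_d/dt = (D - r_d)/E.
Because the DAP re-fires the cell within a few ms while r_d doubles on
every success, bursts of roughly 2–5 spikes self-terminate on the first
dendritic failure, after which the cell needs fresh stimulus/noise drive —
the ghostburst-like phenomenology the burst classifier expects.  Constants:
A = 0.6, B = 2, gamma = 0.2 (dimensionless), D = 0.7 ms, E = 24.5 ms,
tau = 7 ms, alpha = 10.9 uA/cm^2.

### Granule cells

Each SP cell receives AMPA synapses from its own bank of 100 granule cells
(disjoint banks — parallel fibers contact neighboring pyramidal cells at
widely separated boutons, so shared granule input is negligible).  Granule
cells are integrate-and-fire units with the same threshold, reset and
refractory period as the SP cells, driven by the deep-pyramidal (DP) relay
of the stimulus delayed by d_i = (i-1)/N * (1000/f) ms, which tiles one
stimulus period uniformly so each cell responds at its own phase:

    C dV/dt = -g_leak (V - E_leak) + I
              + F(g_relay * kappa sin(2 pi f (t - d_i))) + rho * xi_PF(t)

`g_relay` (default 2.0) is the relay gain of the DP->granule pathway and is
a reconstruction choice: with the bare SP stimulus amplitude the granule
quasi-static peak voltage sits 0.06 mV *below* threshold, i.e. a
deterministic granule cell would never fire, contradicting the described
deterministic phase-locked rasters.  The default is fixed by three
qualitative requirements on granule behaviour: cells phase-lock
deterministically at rho = 0 (firing a handful of spikes around their
preferred phase), stay silent without stimulation, and keep a per-cycle
spike count that is set by the drive rather than by rho — rho is a
*variability* knob (it jitters spike timing across trials), so the
deterministic and stochastic regimes must differ in timing, not density.
Near-threshold gains fail the last requirement (rho then recruits most of
the firing and triples the rate); the insensitivity saturates around a gain
of 2, which is the default.  Granule cells are silent during local stimulation and in the
absence of stimulation; local geometry also sets g_max = g_GABA = 0.

With the printed g_max = 0.024 mS/cm^2 and 100 active synapses per SP cell,
the feedback at full weights (w = 1) is strongly suprathreshold, so the
first seconds of training drive the SP cells near their refractory-limited
rate before depression pulls the weights down.  The equilibrium weights are
consequently small (order 1e-2); what matters for the mechanism is their
anti-phase *profile*, not their absolute scale.

### Noise structure

All stochastic drive is Gaussian white noise passed through a causal
fourth-order Butterworth low-pass at 500 Hz and scaled to unit variance.
Correlations are amplitude decompositions:

    xi_SP_i = sqrt(c) xi_shared + sqrt(1-c) xi_unshared_i        (SP cells)
    xi_PF   = sqrt(e) xi_SP_j   + sqrt(1-e) xi_private           (granules)

`c` (default 0.25) is the input-noise correlation of the SP pair — the
shared fraction of feedforward receptor drive; `e` (default 1) is the
fraction of granule noise inherited from the DP stream, which is identical
to the column's SP stream.  Because filtering shrinks variance and the order
of scaling is not fixed by the source description, this package composes the
white streams first, filters, and rescales deterministically by the filter's
white-noise gain — preserving both the unit variance and the correlation
coefficients exactly.  One master seed spawns named substreams (shared,
per-column, per-granule) so any process is reproducible in isolation and
chunked generation equals one long draw.

### Plasticity

SP spike trains are scanned online for bursts: on each new spike, the spike
plus its three predecessors form a 4-spike burst if none is already in a
burst and they span <= 45 ms; otherwise the 4th- and 5th-most-recent spikes
form a 2-spike burst if unassigned and <= 15 ms apart.  The deferred 2-spike
test guarantees no spike that could still join a 4-spike burst is consumed
early; a spike belongs to at most one burst.  On each SP burst of size g,
every parallel-fiber weight is depressed by eta_g inside a box timing window
of total length L_Wg centred on the burst onset (first spike), with the
presynaptic burst times taken analytically as each granule cell's delayed
sinusoid maxima (as the source describes), wrapped circularly in the
stimulus period.  The window shape is not printed; the box kernel is
isolated in `ellnet.plasticity.btdp_window`.  A slow non-associative
potentiation dw/dt = (1 - w)/tau_w (tau_w = 4900 s) keeps weights from
pinning at zero; weights are clipped to [0, 1].  Defaults: eta_2 = 0.0018,
eta_4 = 0.0036, L_W2 = 10 ms, L_W4 = 100 ms.

### Protocols

Global runs train from w = 1 to equilibrium (default 1000 s; scaled-down
runs use 300 s, by which the weight profile is stationary at the default
parameters), freeze the weights, then run independent evaluation trials
(default 100 x 100 s; scaled down 20 x 20 s).  Every trial restarts the
stimulus at phase zero so cycles align across trials, and draws an
independent noise substream from the protocol's master seed.  Local runs
skip training and disconnect the feedback entirely, making them invariant
to rho, e and all plasticity parameters.

## The correlation analysis

Spike trains are binned at 0.5 ms.  Auto- and cross-correlograms are
coincidence rates relative to chance (see `ellnet.analysis` for the exact
normalisations); lag-dependent overlap loss is corrected by scaling counts
at lag tau by n_bins/(n_bins - |tau|), which keeps the chance-level
subtraction unbiased at every lag.  Responses are segmented into stimulus
cycles; the shuffle predictor averages the CCG over ordered cycle pairs
j != k and estimates the stimulus-locked (signal) part; the cycle-matched
(j = k) average is the raw estimate; their difference is the noise CCG, so
raw = shuffle + noise holds exactly at every lag.  Cycles in which the
averaging neuron fired no spikes are excluded from the average — the printed
per-cycle normalisation (1/N_1,k) is undefined there, and subtracting chance
without a count term would bias the correlograms negative at low rates.
The O(M^2) pair average is evaluated with an exact sum-correlogram identity
and checked against direct enumeration in the tests.

Scalar coefficients average the correlograms over a lag window and
normalise:

    R_raw    = <C_raw>    / sqrt(<A1_raw> <A2_raw>)
    R_signal = <C_shuffle>/ sqrt(<A1_sig> <A2_sig>)
    R_noise  = <C_noise>  / sqrt(<A1_noise> <A2_noise>)

R_noise is the shuffle-corrected r_CCG of the noise-correlation literature:
it equals 1 exactly for two cells receiving identical input and ~0 for
independent noise.  R_signal's denominator terms A_sig are the shuffle
(stimulus-locked) autocorrelogram averages plus the lag-0 spike self-term:
excluding the trial-to-trial autocovariance keeps R_signal from shrinking
merely because the cells got noisier, while the self-term anchors it to
total firing so that cancelling the stimulus-locked modulation still
lowers it.  Two lag windows are used, both recorded in result metadata:
raw/signal coefficients average over one *quarter* stimulus period per side
(62.5 ms at 4 Hz — a full period would integrate the periodic signal
component to zero; the quarter window captures the central lobe), and the
noise coefficient averages over +/- 25 ms, matched to the few-ms width of
the shared-noise correlogram peak (500 Hz input bandwidth plus membrane
integration); a wider window would only dilute it with empty lags and
inflate the estimator variance.

## Surrogate data

`ellnet.surrogate` generates doubly stochastic paired trains whose rate is
a rectified common profile lambda0 (1 + m_sig sin(2 pi f t) +
m_noise eta(t)), with eta unit-variance low-passed noise redrawn per trial
and shared within the pair.  m_sig dials signal correlation, m_noise dials
noise correlation, and the two are independent by construction, giving the
analysis a ground truth that does not depend on the biophysics.  The
surrogates do not emulate burstiness or refractoriness; recovering the
dialed correlations therefore validates the statistics pipeline, not the
neuron model.

## Scaled-down problem sizes

The package's default test and acceptance scales are chosen so the full
pipeline (train, freeze, evaluate, analyse) runs on a desk machine: 300 s
training and 20 trials x 20 s evaluation for the headline local/global
comparison, 100–200 s of feedback-off simulation for the shared-noise
limits, and reduced grids for the sweeps.  The full printed protocol
(1000 s training, 100 x 100 s trials) is the library default for
`ProtocolSpec` and runs unchanged, only longer.

## Numerical choices and degenerate inputs

* Threshold handling: spike registered when V >= V_threshold at the end of
  a step; no within-step interpolation (plain Euler–Maruyama at the printed
  dt).  Somatic refractoriness is a countdown clamping V to V_rest;
  dendritic refractoriness is integrated continuously alongside the voltage.
* The DAP alpha function is integrated as a two-state linear filter inside
  the kernel and evaluated in closed form in `ellnet.model.dap_current`;
  the two paths agree to integration error and the closed form serves as
  the oracle in tests.
* Non-finite voltages abort with a diagnostic naming the cell; diverging
  weights abort training.
* Empty trains: ACG/CCG are undefined and raise; the cycle pipeline skips
  empty averaging cycles (see above); a pair with no valid cycles raises.
* Potentiation uses the exact exponential relaxation between events in the
  Python path and the Euler step inside the kernel; at tau_w = 4900 s and
  dt = 0.05 ms the difference is far below the depression quantum.

## Known limitations

* All equations were reconstructed from prose, symbol lists and printed
  constants (the source renders the equations as images); the DAP mechanism
  and the granule relay gain are the two places where the reconstruction
  required a genuine modelling decision, both documented above.
* With the printed conductances the w = 1 feedback saturates the SP cells,
  so the first seconds of training are a fast weight crash; the negative
  image proper forms in the subsequent rebalancing.  Quantities evaluated
  at the very start of training (near-refractory firing) are outside the
  regime the correlation estimators are designed for.
* The two-cell network cannot address population-level questions (more SP
  cells are a config knob but untested science); granule delay distributions
  are uniform by construction; no conductance-based dynamics.
* Equilibrium parallel-fiber weights are of order 1e-2, i.e. a few
  depression quanta eta_g, so the negative-image profile is coarsely
  quantised; conclusions rest on its phase, not its fine shape.
* Because the w = 1 start saturates the SP cells, the negative image forms
  within seconds rather than gradually, and the equilibrium mean rate under
  global stimulation is strongly suppressed relative to local (the product
  eta_g * tau_w of the printed plasticity constants forces a very low
  equilibrium burst rate).  Two behaviours expected of this circuit under a
  gentler operating point are consequently not reproduced here: a slow monotone
  decline of signal correlations across training snapshots, and a
  global/local noise-coefficient ratio of exactly 1 when granule cells are
  deterministic.  The corresponding end-to-end test reports both
  measurements and currently fails by design rather than hiding them.
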