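# Methods

`neuroburst` implements the analysis chain used to characterise
sleep-like slow oscillations in cortical cultures recorded on
microelectrode arrays (MEAs), together with a clustered
generalized-integrate-and-fire (GIF) network simulator that serves as a
mechanistic synthetic-data generator for the whole chain. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Spike trains and spike extraction

All analysis operates on per-channel spike time stamps in seconds
(`SpikeTrainSet`), the universal container. When spikes are extracted
from raw voltage (`detect_spikes`), the trace is first band-pass
filtered 200 Hz – 2 kHz with a 4th-order Butterworth applied
forward–backward (zero phase, so spike times are not shifted), and
events are absolute-value crossings of `threshold_sd` × noise SD with
at most one event per 1 ms dead time. The noise SD is the MAD estimator
`median(|x|)/0.6745`, chosen because it is insensitive to the spikes
themselves; commercial acquisition software thresholds peak-to-peak
amplitude with an unpublished noise window, so our absolute-amplitude
criterion is an approximation of that operator, not a reimplementation.
A constant-zero trace yields no detections rather than a division
error.

## Spike-density functions and synchronized bursts

The per-channel spike density function (SDF) convolves the train with a
unit-area Gaussian (SD σ = 100 ms) evaluated on a 1 kHz grid; the
population mSDF is the across-channel mean, computed as the pooled-train
SDF divided by the channel count (exact by linearity). Burst *detection*
uses a different signal: the dish-wide count of pooled spikes in a
100 ms window slid along the grid in 1 ms steps. Spans where this count
strictly exceeds 40 spikes/window are synchronized bursts — the
in vitro analogue of the cortical UP state. A sliding (rather than
tumbling) window avoids phase-dependent burst splitting; supra-threshold
spans separated by less than one window length are merged so a single
network event does not fragment on threshold jitter.

Per burst, the peak time is the window-count maximum within the span
(window-centre convention), and the burst envelope is the mSDF:
boundaries extend outward from the envelope maximum to the first
crossing below 25% of that maximum, bounded by the midpoint to the
neighbouring burst peak. Bursts whose boundary search reaches the epoch
edge are flagged `edge_truncated` and excluded from duration/slope
statistics. Burst duration (BD) is the boundary-to-boundary width;
inter-burst interval (IBI) is the peak-to-peak distance of consecutive
bursts; spikes/burst counts pooled spikes inside the boundaries.
Initial/final slopes are the maximum (rising phase) and
magnitude-of-minimum (decaying phase) of the first derivative of the
max-normalized envelope, computed by central differences on the 1 kHz
grid; the extremum (not the phase mean) is used, and the choice is
configurable. Normalization makes slopes exactly invariant to amplitude
scaling and equivariant under time compression.

The BD–spike-count relation fits `log10(n_spikes)` on `log10(BD)` by
least squares with the Pearson correlation of the log pairs; it refuses
fewer than 3 bursts or constant BD.

## Spectral analysis

The spectrum is the one-sided FFT power of the mean-subtracted mSDF
(`|X_k|²/n`, doubled off-DC; the DC bin is dropped after mean
subtraction, making the spectrum invariant to constant offsets).
Frequency resolution is rate/length (~3.3 mHz for a 300 s epoch). No
taper is applied by default; a Hann window is available behind a flag.
The summary readouts are the dominant frequency (argmax bin, ties to
the lower frequency, optionally restricted to the ≤ 1 Hz
slow-oscillation band) and the band power over [0, 1.75) Hz, the band
in which recovery raises power. Units are arbitrary but internally
consistent; only relative comparisons between epochs of identical
length and rate are meaningful, and mismatched grids are rejected.

## Windowed cross-correlation

Channel spike trains are binned at 1 ms and smoothed with a Gaussian
kernel (SD 100 ms), giving signals `x_i`. The epoch is tiled with
non-overlapping windows of T = 1000 ms; for an ordered pair within a
window starting at bin s,

    C_ij(τ) = Σ_{τ'=0..T} x_i[s+τ'] · x_j[s+τ'+τ],   τ = 0..T,

normalized at each lag by √(C_ii(0) · E_j(τ)), where `C_ii(0)` is the
i-segment energy and `E_j(τ)` the energy of the τ-shifted j-segment.
At τ = 0 this is the classical √(C_ii(0)C_jj(0)) normalizer; at τ > 0
the shifted energy is what the Cauchy–Schwarz inequality actually
bounds against, so every value lies in [0, 1] with equality exactly for
proportional segments (a fixed C_jj(0) normalizer is *not* bounded:
a burst just outside the window can push values far above 1 on bursty
data). The per-window value is the maximum over lags; the epoch entry
averages the per-window values (a best-window maximum is available as
a variant, but the best window of almost any pair of active channels
attains ≈1 at some lag, which erases the contrast between synchronized
and desynchronized pairs — the window-averaged form is the one that
produces cluster structure in the matrix). Negative lags are covered by
taking the larger of the two pair orderings, which also makes the
matrix symmetric; windows where either channel has zero smoothed energy
are skipped, and a pair with no usable window is missing (NaN). Final
values are clipped at 1.0 to absorb FFT round-off above the analytic
bound.

Channel clustering is SciPy average-linkage agglomeration on
d = 1 − correlation after dropping all-missing channels; the leaf order
re-displays the matrix grouped by cluster, and the tree exports to
Newick.

## Neural trajectory

Per-channel spike counts on a 20 ms grid (fine relative to the kernel,
coarse enough for tractable PCA) are smoothed with a 50 ms Gaussian and
passed to PCA, centred but not variance-scaled per channel; the
smallest K whose cumulative explained variance reaches 90% is kept.
Plotting two latent coordinates with consecutive samples joined traces
the neural trajectory; burst-pause cycling appears as closed loops
between the UP and DOWN regions of rate space. The loop statistic — an
addition of this package, not part of the classical trajectory method —
unwraps the angular coordinate around the trajectory centroid and
counts completed 2π spans (with a 1e-9 rad epsilon so an exactly closed
turn counts); the amplitude is the mean radial distance over samples in
complete loops. A straight-line trajectory has zero loops; a circle
traversed five times has five, with amplitude equal to its radius.

## The GIF network simulator

Neurons are current-based GIF units: membrane potential

    C dV/dt = −g_L (V − E_L) − Σ η(t − t̂) + I(t),

escape-noise spiking at intensity λ(t) = λ₀ exp((V − V_T(t))/ΔV) with
moving threshold V_T(t) = V_T* + Σ γ(t − t̂), reset to `V_reset` and a
refractory clamp τ_ref after each spike. η (adaptation current) and γ
(threshold movement) are single-exponential kernels — the standard GIF
parameterization fitted to cortical neurons. Synapses are exponential
currents with per-population time constants (4 ms excitatory, 8 ms
inhibitory) and a 2 ms transmission delay on every connection; each
neuron additionally receives an independent Poisson spike train through
the same synapse model (delivered without the 2 ms delay — a pure time
shift of a stationary external process).

The network embeds one or two *clusters* — blocks of excitatory neurons
with elevated connection probability and weight (p = 0.5, w = 150 pA
vs the 0.05 / 30 pA background; the 5× weight ratio and the
probabilities are structural choices, the absolute weights calibrated)
— in a 3000-excitatory / 900-inhibitory Erdős–Rényi graph (no self- or
multi-edges). The mechanism: background noise keeps cluster neurons a
few mV below threshold; a coincident fluctuation ignites the cluster's
recurrent excitation, the burst spreads through the background
population dish-wide, and the slow adaptation current (η = 12 pA per
spike, τ_η = 1.2 s on excitatory cells) terminates it and enforces a
pause. This produces dish-wide synchronized bursts at ~0.2–0.3 Hz with
BD ≈ 0.4 s — the slow-oscillation regime of mature cultures — while
the same network without a cluster is silent of bursts.

Presets pair baseline and recovery topologies: one 95-neuron cluster
vs clusters of 95 + 90 (a second cluster formed by stimulation-induced
plasticity), and clusters of 65 + 40 vs one merged 100-neuron cluster
with 5 former members fully disconnected. Adding a cluster lengthens
bursts and shortens pauses — the direction of the in vitro homeostatic
recovery phenotype.

All neuron and network constants are documented defaults calibrated to
place the baseline preset inside the 0.1–0.5 Hz burst-pause regime
(the calibration sweep ships in `scratch/` during development); they
are plausible for cortical cultures but are not fitted to any
recording. Cluster membership uses contiguous id blocks, which loses no
generality in an exchangeable random graph.

Readout mimics the MEA: 60 virtual channels, each the merged spike
train of 4 randomly chosen distinct neurons, producing a
`SpikeTrainSet` that feeds every analysis module unchanged.

### Numerics

Integration uses exponential-Euler for the leak (exact for input held
constant over a step — the subthreshold relaxation under constant
current matches the closed form to float32 precision) with forward
accumulation of the exponential synaptic/adaptation state variables;
dt defaults to 0.1 ms (0.2 ms is adequate for regime-level studies) and
must not exceed the synaptic delay. Spike emission per step uses
probability 1 − exp(−λ dt), exact for constant λ within a step; the
draw is skipped when (V − V_T)/ΔV < −12 (per-step probability below
~1e-8, far less than one expected spike per epoch). State is float32;
four independent seed streams (graph, noise, spiking, channel map)
derive from one master seed, so topology can be held fixed across noise
realizations, and identical seeds reproduce spike output bit-for-bit.
The inner loop is compiled with numba; spike draws use the legacy
MT19937 generator seeded per chunk because `numpy.random.Generator`
objects cannot cross the numba boundary. Diverging (non-finite)
membrane potentials abort with a diagnostic.

## Parametric burst-pause generator

For tests that need known ground truth without network mechanics,
`generate_burst_pause` draws burst onsets from a gamma renewal process
(mean gap 1/burst_rate, shape `regularity`, default 4; shape 1 recovers
a Poisson process). The quasi-regular default mirrors the
adaptation-paced rhythm of real cultures and keeps events from
overlapping at realistic rates — under a Poisson renewal, merged events
bias the mean IBI upward by roughly rate × dead-time (~12% at 0.25 Hz),
which would misrepresent the generator as a ground truth. Each burst
recruits `ceil(participation × n_channels)` random channels firing
Poisson at `within_burst_rate` for `burst_len`, onset-jittered
N(0, jitter_sd²) per channel, over independent Poisson background
firing. Realized onsets are kept on the config for bookkeeping, so
tests can assert exact detection counts.

## Pipeline and study statistics

`analyze_epoch` runs detection → spectrum → synchrony → trajectory with
one shared `AnalysisConfig` holding every standard constant by name
(σ = 100 ms, window = 100 ms, threshold = 40, boundary 25%, T = 1 s,
bin = 1 ms, smooth = 50 ms, variance target 0.90, epoch 300 s). Stage
failures (e.g. a silent recording) are recorded per stage and leave a
partial result. Study-level comparisons divide each culture's metric by
the sham-group mean *at the matching condition* (baseline or recovery)
and compare baseline vs recovery with a classical paired two-sided
t-test (SciPy); unpaired cultures are excluded with a warning, and a
degenerate all-zero difference vector reports p = 1 directly. The
spectral comparison emits a long-format (culture, condition, frequency
bin, power) table and leaves the two-way repeated-measures ANOVA to
standard statistics packages.

## What the synthetic data do and do not show

The parametric generator provides exact ground truth for detection
counts, IBI recovery and linearity properties, but its bursts are
square pulses of Poisson firing — it has no rise/decay dynamics, no
spatial structure and no refractory interactions, so slope values on it
characterise the smoothing kernel as much as the data. The GIF
simulator produces mechanistically realistic burst ignition,
propagation and termination, but its parameters are calibrated rather
than fitted: passing tests demonstrate that the analysis chain measures
what it claims on data with realistic structure, and that cluster
topology controls the oscillation regime — they do not certify
agreement with any particular culture's numbers, whose raw recordings
are not publicly deposited. Epoch lengths in the test suite (15–120 s)
are chosen for statistical power at desk scale; the regimes are
stationary, so longer epochs tighten but do not move the statistics.

## Known limitations

- Spike extraction approximates an unpublished peak-to-peak operator;
  no spike sorting into single units is attempted (multi-unit activity
  is the object of study).
- The cross-correlation entry is a bounded alignment score, not a
  mean-subtracted correlation; two channels with high stationary rates
  score high even without burst coupling. Its value lies in *relative*
  comparisons across conditions on the same channels.
- The simulator's recovery is a static topology change; the plasticity
  process that would produce it is not modelled.
- Inhibitory neurons share one background connection block per
  population pair; no cluster structure is imposed on them.
- No GUI; trajectory projections are computed, not interactively
  browsed.
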