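# Methods

## Signal model and preprocessing

Input is multichannel bipolar iEEG sampled at 2000 Hz in microvolts.
Each channel is filtered into the ripple band (80–250 Hz) and the
fast-ripple band (250–500 Hz) with a causal single-biquad (2nd-order)
Butterworth band-pass, the digital counterpart of a 2nd-order analog
band-pass stage. Causal filtering is the default because the detector is
meant to be implementable in real time; a zero-phase mode
(forward–backward) is available for offline analysis. The filter design
(family, order, corners, phase mode) is recorded in the output metadata.
A single biquad rolls off at only ~20 dB/decade outside the band, so
out-of-band components are attenuated, not removed; tests therefore
compare filter output against the filter's own analytic magnitude
response rather than against an idealised brick wall.

**Baseline.** Recording amplitude varies strongly across electrodes and
sessions, so the delta-modulator thresholds adapt to a per-channel
baseline: over the first second of each interval the maximum absolute
amplitude is taken in non-overlapping 50-ms windows (20 windows at the
defaults), the maxima are sorted, and the baseline is the mean of the
⌈n/4⌉ smallest (5 of 20). The per-window maximum keeps the statistic
above the noise floor; the lowest quartile rejects windows contaminated
by transients or oscillatory events. When n is not divisible by 4 the
⌈n/4⌉ smallest values are used. For band-limited Gaussian background the
statistic sits near 1.8× the band RMS.

The baseline is computed on the *pre-amplified* band-passed trace
(gain × signal, default gain 8), i.e. at the scale at which the
delta-modulator comparator thresholds are defined; thresholds are then
`factor × baseline`, symmetric for UP and DN, with an absolute floor of
0.5 µV so silent channels keep finite thresholds. The default factor is
1.5: that places the threshold near 2.7× the band RMS, which suppresses
encoder activity on background almost completely while oscillatory
events — several times the background RMS in-band — drive kilohertz spike
bursts. With the factor at or below ~1 the threshold lies inside the
excursion range of the band-limited noise itself; the encoder then fires
at hundreds of hertz on background, the downstream population sits at its
firing threshold everywhere, and detection saturates on event-free
channels (measured on synthetic data over a 0.75–2.0 factor sweep). The
factor remains a top-level configuration knob.

## Delta modulation

The encoder tracks a reference r over the pre-amplified signal v = g·x.
An UP event is emitted when v − r ≥ v_tu, a DN event when r − v ≥ v_td
(threshold crossings are inclusive: at sample resolution the event fires
on the first sample at or beyond the threshold). After each event the
encoder is silent for a refractory period (default 300 µs); events are
stamped at sample resolution, which is adequate because the integrator
step downstream (0.1 ms) is finer than the 2000 Hz sampling.

Two reference-update conventions are implemented:

- `threshold` (default): on emission r steps by exactly ±the threshold.
  This makes the event stream exactly decodable — the running sum of
  +v_tu per UP and −v_td per DN tracks g·(x − x₀) within
  max(v_tu, v_td) at every sample, provided the per-sample slew stays
  below the thresholds and the refractory period is zero. This bound is
  asserted as a property test and on 1000 randomised slow signals.
- `sample`: on emission r snaps to the current sample value. This variant
  has no such error bound (the per-event overshoot accumulates), but
  mirrors a hardware reset of the modulator's input amplifier.

After a nonzero refractory period the reference always re-latches to the
first post-refractory sample, so excursions during the dead time are seen
only through that sample.

Two intuitive monotonicity properties — "raising a threshold never adds
events" and "lengthening the refractory period never adds events" — hold
only for monotone signals. For general signals both are false: UP and DN
events share one reference, and perturbing the threshold (or re-anchoring
the reference after a dead time) changes the reference trajectory
non-monotonically. Randomised search finds counterexamples in both
reference-update modes; on monotone inputs, 3000 randomised trials found
none. The property tests assert the monotone-signal versions, plus the
unconditional guarantees: minimum inter-event interval ≥ the refractory
period, and event count ≤ duration/refractory + 1.

## Neuron and synapse model

Each of the 256 second-layer neurons obeys

    τ_mem dV/dt   = −V + I_syn − v_ahp + f(V)
    τ_ahp dv_ahp/dt = −v_ahp + w_ahp δ_spk(t)
    τ_exc dI_exc/dt = −I_exc + w_exc δ_UP(t)
    τ_inh dI_inh/dt = −I_inh + w_inh δ_DN(t)

with I_syn = I_exc − I_inh. Every neuron receives all four input streams
(full fan-out): UP events of both bands excite, DN events inhibit. Each
input spike increments its synaptic current by the weight instantaneously
(jump–decay convention), so a regular train at rate r yields a mean
current w·r·τ; all analytic checks use this convention. On threshold
crossing the membrane resets to v_reset = 0 and the adaptation variable
v_ahp jumps by w_ahp, producing spike-frequency adaptation (successive
inter-spike intervals lengthen under sustained drive). I_exc, I_inh,
v_ahp and V are clipped at zero, as in subthreshold current-mode circuits
where currents flow in one direction only.

f(V) = Δ_T·exp((V − v_T)/Δ_T) is the standard exponential
spike-initiation term; it is disabled by default (plain adaptive LIF) and
available as a configuration flag. When enabled, an exponential argument
beyond 25 forces a spike (the usual escape convention) rather than
overflowing.

**Units.** Currents are in nanoamperes; V and v_ahp share the same
numeric scale, following the circuit-equation convention in which I_syn
enters the membrane equation directly.

**Defaults** (nominal values before mismatch):

| parameter | default | meaning |
|---|---|---|
| τ_mem | 15.2 ms | membrane time constant |
| τ_ahp | 35.7 ms | adaptation time constant |
| τ_exc | uniform 3–6 ms per neuron | excitatory synapse |
| τ_inh | uniform 0.1–1 ms per neuron | inhibitory synapse (fast preset) |
| w_exc, w_inh | 2 nA | synaptic weights |
| w_ahp | 1 | adaptation increment (≈20% of threshold) |
| v_reset | 0 | post-spike membrane value |
| v_thresh | calibrated (≈4.8) | see calibration |
| mismatch CV | 0.20 | per-parameter variability |
| dt | 0.1 ms | integrator step |

Two inhibitory time-constant presets ship: the fast 0.1–1 ms range used
as the default (it is the one tied to the detection-tuning procedure) and
a wide 2–5.7 ms range matching the nominal hardware corner values. Which
of the two produced the originally published rates is not determinable
from the source material, so both are provided and the choice is a
configuration knob.

**Mismatch.** Synaptic time constants are drawn uniformly from their
ranges per neuron; every parameter is then multiplied by an independent
truncated-Gaussian factor (mean 1, CV 0.20, truncated at ±3σ and at 0).
This stands in for analog device mismatch and is the only source of
diversity across the otherwise identical neurons; it is applied once per
network (not per step) and is deterministic given the seed.

**Numerics.** The membrane is integrated by forward Euler at dt = 0.1 ms
(error ~dt/2τ_mem ≈ 0.3% per membrane time constant; halving dt changes
subthreshold trajectories by <2%, asserted in tests). The linear synapse
and adaptation states are advanced by their exact exponential decay
factor per step rather than an Euler increment: the update is then exact
at any dt/τ ratio, which matters because the fast inhibitory time
constants (down to 0.1 ms) equal the default step. Input spikes are
binned to integrator steps and seen by the membrane in the step in which
they arrive. A pure-NumPy single-step reference implementation (`step`)
defines the semantics; the production numba kernel is held to agree with
it exactly in tests.

**Threshold calibration.** The firing threshold is not a published
quantity; it is anchored to the published behavioral fact that the
silicon neuron needs a minimum of 14 excitatory input spikes at 3 kHz to
produce one output spike (at w_exc = 2 nA, τ_exc = 4.5 ms — the midpoint
of the excitatory range — and mismatch disabled). The free-membrane peak
in response to a 13-spike train and to a 14-spike train bracket every
admissible threshold; `calibrate_threshold` returns their midpoint and
verifies the anchor by simulation (14 spikes fire, 13 do not). Because
the membrane dynamics before the first spike do not depend on the
threshold, the peak-bracketing search is exact — it is the fixed point
that an iterative bisection between the two responses would converge to.
Mismatch is applied after calibration, when the network is sampled, so
individual neurons scatter around the anchored threshold; that scatter is
what makes the ensemble informative.

## Synapse frequency response

`dpi_frequency_response` characterises the first-order synapse against
spiking input: a sine is delta-modulated into UP events, the events drive
the jump–decay synapse, and the gain at the drive frequency is the ratio
of the Fourier amplitudes of the synaptic current and of its spike-train
input, normalised by the DC gain τ. A faithful first-order element gives
|H(f)| = 1/√(1 + (2πfτ)²); the measurement agrees within a few percent
(tests allow 30% for encoding noise). Measuring the current *against the
actual spike train* makes the estimate robust to encoder saturation at
high frequencies. `dpi_bandpass_response` returns the magnitude of the
difference between the normalised gain curves of a slow excitatory and a
fast inhibitory synapse; it vanishes at DC (both normalised gains are 1)
and at high frequency (both vanish) and peaks in between — the band the
synapse pair is tuned to.

## Detection and clinical statistics

Pooled output spikes of the (unmasked) population are binned into
non-overlapping 15-ms snippets anchored at the interval start. In the
default `consecutive_snippets` mode a detection requires at least two
consecutive non-empty snippets; `any_spike` mode flags every non-empty
snippet. The two modes reflect two readings of the published detection
rule; the discrepancy is preserved as a configuration option rather than
resolved, and `any_spike` never yields fewer events (asserted as a
property). Detections separated by less than one snippet are aggregated
into a single HFO whose boundaries are the first and last pooled spike
times. Neurons whose mean rate over the whole run exceeds 10 Hz (a
configurable stand-in for "spiking continuously") are masked once,
study-wide — in cohort runs the mask is derived from the pooled activity
of all intervals, then applied globally.

Rates are events/min per channel and interval (60 × count / duration).
Within-night summaries report per-channel mean and standard error
(sd/√n; 0 for a single interval).

**Test–retest reliability** is the mean pairwise scalar product of the
per-interval rate vectors after normalising each to unit Euclidean norm
(i.e. mean pairwise cosine; a median aggregation is available). The
normalisation makes the score scale-free, which the "~1 for highly
overlapping spatial distributions" semantics requires; pairs involving an
all-zero vector contribute 0, and fewer than two intervals yield an
undefined score (rendered "—").

**HFO area**: per-channel rates are averaged over all intervals; the area
is the set of channels strictly above the 95th percentile (linear
interpolation between order statistics) of the patient's own per-channel
averages. The percentile is per-patient, not pooled across patients. A
flat or silent rate map yields an empty area.

**Outcome labels**: with "inside" meaning area ⊆ resected channel set and
seizure freedom meaning ILAE class 1 — TN (inside, free), TP (not inside,
not free), FN (inside, not free), FP (not inside, free). An empty area is
vacuously inside; this edge case is a package convention (the source
material does not discuss it) and is flagged in the per-patient report
(`area_is_empty`). Group metrics follow the standard confusion-matrix
formulas in percent; zero denominators yield NaN, printed as "—".

## Synthetic data

The generator exists to exercise the pipeline with known ground truth,
not to model epileptic physiology:

- **Background**: Gaussian noise shaped to f^(−β) in power (β = 1 by
  default, flat below 1 Hz), RMS-normalised to 50 µV per channel. This
  reproduces the qualitative 1/f spectrum of sleep iEEG.
- **Events**: Hann-enveloped sinusoids, 8 cycles per component, 150 µV
  peak per component; clinically relevant events carry a ripple and a
  fast-ripple component simultaneously. The envelope vanishes at the
  window edges, so injection changes nothing outside the annotated
  window. At the default background, the in-band event RMS is ≈3.3× the
  ripple-band background RMS — the smallest round amplitude at which
  events clearly stand out of the band-limited noise floor. No published
  amplitude/SNR statistics exist for the original recordings, so this is
  a pipeline-exercising choice, made once.
- **Timing**: homogeneous Poisson per channel (the simplest process
  consistent with a stated rate), with events kept out of the first
  second (the baseline-calibration window) and the final 0.2 s.
- **Cohorts**: per patient, a configurable number of channels, intervals
  and nights; pathological channels receive co-occurring events at the
  base rate (default 10/min), the rest ripple-only events at the
  background rate (default 0); resected sets either cover the
  pathological channels (plus one extra channel) or miss one of them; an
  ILAE class is attached per patient. Everything is reproducible from a
  single seed via spawned substreams.

What passing tests on this data do **not** show: robustness to real iEEG
artifacts (muscle, electrode pops beyond simple transients), to
non-stationary background, to spike-and-wave discharges, or to the actual
amplitude distribution of clinical HFOs. The end-to-end claims verified
here are ordering claims (event-carrying channels outrank clean ones) and
internal-consistency claims (the clinical layer recovers the constructed
ground truth), at problem sizes of 8–60 s intervals and 2–5 channels —
chosen as the package's standard desk-scale configuration; the interval
length enters only through event counts.

## Reproducibility and problem sizes

All computations are deterministic given the configuration seed: one
global seed expands into the network-sampling stream, and synthetic
generation spawns per-patient/per-interval substreams, so results do not
depend on processing order. The acceptance script recomputes the
calibration anchor (minimum excitatory spike count at 3 kHz) from scratch
at every run; the remaining study-level checks live in the test suite.

## Known limitations

- Transistor-level behavior (power, noise, AER routing, arbiter effects)
  is out of scope; this is a behavioral model.
- The published per-patient HFO rates and the patient-level test–retest
  scores of the original study require the original recordings and/or the
  physical device and are not reproduced here; the published per-patient
  labels are shipped as fixture data for the group-metric computations.
- The baseline is recomputed per interval from its first second; a
  quieter or noisier opening second shifts the operating point of that
  interval.
- The empty-HFO-area convention (vacuously inside the resection) can
  label a patient TN/FN with no localising evidence; the report flags it.
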