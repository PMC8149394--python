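# hfosnn

Detection of high-frequency oscillations (HFOs) in intracranial EEG with a
behavioral model of a neuromorphic spiking neural network, plus the
patient-level statistics used to relate HFO rates to epilepsy-surgery
outcome.

## Who this is for

HFOs — brief oscillatory events divided into ripples (80–250 Hz) and fast
ripples (250–500 Hz), whose co-occurrence marks clinically relevant
events — are a candidate iEEG biomarker of the epileptogenic zone. This
package implements, in software, the full event-based detection chain of a
neuromorphic HFO detector and the downstream clinical analysis, so that
the method can be studied, characterised and extended without hardware:

1. **Band-pass filtering** of 2000 Hz bipolar iEEG into the ripple and
   fast-ripple bands (causal 2nd-order Butterworth biquads, mirroring the
   analog filter stage).
2. **Adaptive baseline**: per channel, the mean of the lowest quartile of
   50-ms window maxima over the first second of recording.
3. **Asynchronous delta modulation (ADM)**: each band-passed trace is
   encoded into UP/DN spike trains — an event whenever the pre-amplified
   signal moves a baseline-scaled threshold away from a tracked reference,
   with a 300 µs refractory dead time.
4. **Two-layer spiking network**: the four streams (R_UP, R_DN, FR_UP,
   FR_DN) feed 256 adaptive integrate-and-fire neurons

   τ_mem dV/dt = −V + I_syn − v_ahp + f(V),  I_syn = I_exc − I_inh,

   through first-order dynamic synapses τ_x dI_x/dt = −I_x + w_x δ(t)
   (jump–decay; steady state w·r·τ). Per-neuron parameter diversity
   (~20% CV, truncated Gaussian) emulates analog device mismatch and turns
   the population into an ensemble of weak classifiers.
5. **Ensemble detection**: pooled output spikes are evaluated on a grid of
   15-ms snippets; spikes in consecutive snippets signal an HFO, and
   detections closer than one snippet are aggregated. Continuously firing
   neurons are masked out study-wide.
6. **Clinical layer**: per-channel HFO rates (events/min) per 5-min
   interval; test–retest reliability (mean pairwise cosine of rate
   vectors); the "HFO area" (channels above the 95th percentile of the
   patient's average rates); patient-level TN/TP/FN/FP labels from
   area-inside-resection × ILAE seizure outcome; group specificity,
   sensitivity, NPV, PPV, accuracy.

A synthetic-data module generates 1/f-like background, injected
ripple/fast-ripple bursts with ground-truth annotations, and multi-patient
cohorts, so the entire chain is testable offline.

## Worked example

```python
import numpy as np
import hfosnn as h

# 30 s of two-channel background; six ripple+fast-ripple events on AR1-2
rec = h.generate_background(30.0, fs=2000.0, n_channels=2,
                            channel_labels=["AR1-2", "AR2-3"], seed=42)
rng = np.random.default_rng(42)
onsets = np.sort(rng.uniform(1.5, 28.5, 6))
specs = [h.HFOSpec(onset_s=float(o), ripple_freq=140.0, fr_freq=320.0, channel=0)
         for o in onsets]
rec, truth = h.inject_hfo(rec, specs)

result = h.run_detection(rec, h.PipelineConfig(seed=1))
print(result.rates.as_series())
```

prints

```
AR1-2    12.0
AR2-3     0.0
```

i.e. 12 events/min (6 events in 30 s) on the channel carrying the injected
HFOs and none on the event-free channel. The event table shows each
detection within ~15 ms of its injected onset, with ~40–55 of the 256
neurons participating:

```
 onset_s  duration_s channel  n_neurons_active
   4.059       0.034   AR1-2                42
  13.366       0.036   AR1-2                49
  20.342       0.031   AR1-2                51
  22.416       0.030   AR1-2                48
  24.697       0.029   AR1-2                55
  27.857       0.032   AR1-2                45
```

The same chain is available from the shell:

```sh
hfosnn simulate --seed 3 --out cohort/ --patients 3 --interval-s 60
hfosnn cohort cohort/ --seed 3 --out results/
hfosnn report results/
```

`simulate` writes a synthetic cohort with ground truth, `cohort` runs
detection on every interval and produces the per-patient report
(intervals, test–retest score, HFO area, prediction label) and the group
metrics table, and `report` pretty-prints them.

## Layout

- `hfosnn.synthetic` — background, event injection, cohort generation
- `hfosnn.preprocess` — band-pass filters, adaptive baseline
- `hfosnn.adm` — delta-modulation encoder/decoder, threshold adaptation
- `hfosnn.snn` — neuron/synapse model, mismatch sampling, calibration,
  synapse frequency-response characterisation
- `hfosnn.detect` — ensemble event detection, rates, outlier masking
- `hfosnn.clinical` — test–retest, HFO area, outcome labels, group metrics
- `hfosnn.pipeline` / `hfosnn.cli` — orchestration, configuration, CLI
- `hfosnn.io` — text/NPZ serialisation of signals, spikes, events, cohorts

See `docs/methods.md` for the model equations, parameter defaults, the
numerical scheme, and known limitations.
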