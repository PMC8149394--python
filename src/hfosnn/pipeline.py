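"""End-to-end orchestration: recording -> spikes -> network -> rates -> report.

``run_detection`` processes one multichannel recording: per channel it
band-passes into the ripple and fast-ripple bands, estimates the adaptive
baseline at the delta-modulator amplifier output, encodes both bands into
UP/DN spike trains, drives the sampled 256-neuron network, and turns the
raster into HFO events and a per-channel rate vector.  ``run_cohort``
repeats this per interval and patient, derives the global outlier-neuron
mask from the pooled activity of the whole run, and feeds the rate
vectors into the clinical layer (test-retest, HFO area, outcome labels,
group metrics).

One global seed expands deterministically into the network-sampling
stream, so results do not depend on channel or interval processing order.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, detect, io
from .adm import adm_encode, thresholds_from_baseline
from .preprocess import BandSpec, IEEGRecording, bandpass, compute_baseline
from .snn import (
    NeuronParams,
    Raster,
    SNNConfig,
    SynapseParams,
    calibrate_threshold,
    run_network,
    sample_network,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the detection pipeline, serialisable to YAML."""

    # band-pass
    ripple_band: tuple[float, float] = (80.0, 250.0)
    fast_ripple_band: tuple[float, float] = (250.0, 500.0)
    filter_order: int = 1
    zero_phase: bool = False
    # baseline / ADM
    baseline_window_ms: float = 50.0
    baseline_calibration_s: float = 1.0
    adm_threshold_factor: float = 1.5
    adm_threshold_floor: float = 0.5
    adm_refractory_s: float = 300e-6
    adm_gain: float = 8.0
    adm_relatch: str = "threshold"
    # SNN
    n_neurons: int = 256
    mismatch_cv: float = 0.20
    tau_exc_range: tuple[float, float] = (3e-3, 6e-3)
    tau_inh_range: tuple[float, float] = (0.1e-3, 1e-3)
    tau_mem: float = 15.2e-3
    tau_ahp: float = 35.7e-3
    w_ahp: float = 1.0
    w_exc: float = 2.0
    w_inh: float = 2.0
    exp_enabled: bool = False
    delta_T: float = 1.0
    v_T: float = 10.0
    dt: float = 1e-4
    neuron_refractory_s: float = 0.0
    calibration_n_spikes: int = 14
    calibration_rate_hz: float = 3000.0
    # detection
    snippet_ms: float = 15.0
    detect_mode: str = "consecutive_snippets"
    outlier_max_rate_hz: float = 10.0
    # clinical
    area_percentile: float = 95.0
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("ripple_band", "fast_ripple_band", "tau_exc_range", "tau_inh_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Network:
    """A calibrated, mismatch-sampled second-layer population."""

    params: pd.DataFrame
    v_thresh_nominal: float
    config: PipelineConfig


@dataclass
class DetectionResult:
    """Per-interval output of the detection pipeline."""

    events: pd.DataFrame
    rates: detect.HFOVector
    rasters: dict[str, Raster] = field(default_factory=dict)


def build_network(config: PipelineConfig) -> Network:
    """Calibrate the nominal threshold and sample the mismatched population.

    Calibration uses the nominal operating point (mismatch disabled); the
    sampled table then carries the per-neuron diversity.
    """
    neuron = NeuronParams(
        tau_mem=config.tau_mem,
        tau_ahp=config.tau_ahp,
        w_ahp=config.w_ahp,
        exp_enabled=config.exp_enabled,
        delta_T=config.delta_T,
        v_T=config.v_T,
    )
    synapse = SynapseParams(
        tau_exc=float(np.mean(config.tau_exc_range)),
        tau_inh=float(np.mean(config.tau_inh_range)),
        w_exc=config.w_exc,
        w_inh=config.w_inh,
    )
    v_thresh = calibrate_threshold(
        neuron,
        synapse,
        n_spikes=config.calibration_n_spikes,
        rate_hz=config.calibration_rate_hz,
        dt=config.dt,
    )
    neuron = dataclasses.replace(neuron, v_thresh=v_thresh)
    snn_config = SNNConfig(
        n_neurons=config.n_neurons,
        mismatch_cv=config.mismatch_cv,
        tau_exc_range=config.tau_exc_range,
        tau_inh_range=config.tau_inh_range,
        seed=config.seed,
        dt=config.dt,
        neuron_refractory_s=config.neuron_refractory_s,
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    table = sample_network(snn_config, synapse, neuron, rng=rng)
    return Network(params=table, v_thresh_nominal=v_thresh, config=config)


def encode_channel(
    recording: IEEGRecording, channel: str, config: PipelineConfig
) -> list:
    """Band-pass one channel into both bands and delta-modulate each.

    The baseline (and hence the thresholds) is measured at the amplifier
    output, i.e. on the pre-amplified band-passed trace — the scale at
    which the comparator thresholds are defined in the hardware being
    modeled.
    """
    trains = []
    for lo_hi, name in ((config.ripple_band, "ripple"), (config.fast_ripple_band, "fast_ripple")):
        band = BandSpec(*lo_hi, name=name)
        filtered = bandpass(
            recording, band, order=config.filter_order, zero_phase=config.zero_phase
        )
        x = filtered.channel(channel)
        baseline = compute_baseline(
            config.adm_gain * x,
            recording.fs,
            window_ms=config.baseline_window_ms,
            calibration_s=config.baseline_calibration_s,
            channel=channel,
        )
        params = thresholds_from_baseline(
            baseline,
            factor=config.adm_threshold_factor,
            floor=config.adm_threshold_floor,
            refractory_s=config.adm_refractory_s,
            gain=config.adm_gain,
            relatch=config.adm_relatch,
        )
        trains.append(adm_encode(x, recording.fs, params, source=f"{channel}:{name}"))
    return trains


def _run_channel_raster(
    recording: IEEGRecording, channel: str, network: Network
) -> Raster:
    config = network.config
    trains = encode_channel(recording, channel, config)
    return run_network(
        trains,
        network.params,
        dt=config.dt,
        duration_s=recording.duration_s,
        exp_enabled=config.exp_enabled,
        delta_T=config.delta_T,
        v_T=config.v_T,
        neuron_refractory_s=config.neuron_refractory_s,
    )


def _events_and_rates(
    rasters: dict[str, Raster],
    keep_mask: np.ndarray,
    recording: IEEGRecording,
    config: PipelineConfig,
) -> DetectionResult:
    frames = []
    rates = []
    for channel in recording.channel_labels:
        masked = detect.apply_neuron_mask(rasters[channel], keep_mask)
        events = detect.detect_events(
            masked, snippet_ms=config.snippet_ms, mode=config.detect_mode, channel=channel
        )
        frames.append(detect.events_to_frame(events, interval_id=recording.interval_id))
        rates.append(detect.hfo_rate(events, recording.duration_s))
    vector = detect.HFOVector(
        channels=list(recording.channel_labels),
        rates=np.array(rates),
        duration_s=recording.duration_s,
        interval_id=recording.interval_id,
        night_id=recording.night_id,
    )
    nonempty = [f for f in frames if len(f)]
    events = (
        pd.concat(nonempty, ignore_index=True) if nonempty else frames[0].iloc[:0]
    )
    return DetectionResult(events=events, rates=vector, rasters=rasters)


def run_detection(
    recording: IEEGRecording,
    config: PipelineConfig,
    network: Network | None = None,
    keep_mask: np.ndarray | None = None,
) -> DetectionResult:
    """Full single-interval pipeline for every channel of ``recording``.

    With no precomputed ``keep_mask`` the outlier-neuron mask is derived
    from this interval alone; cohort runs pass the study-wide mask.
    """
    if network is None:
        network = build_network(config)
    rasters = {
        channel: _run_channel_raster(recording, channel, network)
        for channel in recording.channel_labels
    }
    if keep_mask is None:
        keep_mask = detect.outlier_mask(
            list(rasters.values()), max_rate_hz=config.outlier_max_rate_hz
        )
    return _events_and_rates(rasters, keep_mask, recording, config)


def run_cohort(patients, config: PipelineConfig) -> dict:
    """Detect on every interval of every patient and aggregate clinically.

    The outlier-neuron mask is computed once from the pooled activity of
    all intervals in the study, then applied globally.  Returns a dict
    with the per-patient report table, the group metrics table, the
    per-patient prediction labels and the per-interval rate vectors.
    """
    if not patients:
        raise ValueError("empty cohort")
    network = build_network(config)
    # pass 1: rasters for every (patient, interval, channel)
    per_patient_rasters = []
    all_rasters = []
    for patient in patients:
        rasters_by_interval = []
        for recording in patient.recordings:
            rasters = {
                ch: _run_channel_raster(recording, ch, network)
                for ch in recording.channel_labels
            }
            rasters_by_interval.append(rasters)
            all_rasters.extend(rasters.values())
        per_patient_rasters.append(rasters_by_interval)
    keep_mask = detect.outlier_mask(all_rasters, max_rate_hz=config.outlier_max_rate_hz)
    # pass 2: events, rates, clinical aggregation
    rows = []
    labels = []
    vectors_by_patient = {}
    for patient, rasters_by_interval in zip(patients, per_patient_rasters):
        vectors = []
        for recording, rasters in zip(patient.recordings, rasters_by_interval):
            result = _events_and_rates(rasters, keep_mask, recording, config)
            vectors.append(result.rates)
        record = clinical.PatientRecord(
            patient_id=patient.patient_id,
            hfo_vectors=vectors,
            resected_channels=set(patient.resected_channels),
            ilae_outcome=patient.ilae_outcome,
        )
        row = clinical.evaluate_patient(record, percentile=config.area_percentile)
        rows.append(row)
        labels.append(row["prediction"])
        vectors_by_patient[patient.patient_id] = vectors
    report = pd.DataFrame(rows)
    metrics = clinical.cohort_metrics(labels)
    return {
        "patients": report,
        "metrics": pd.DataFrame([metrics]),
        "labels": labels,
        "vectors": vectors_by_patient,
        "keep_mask": keep_mask,
        "config_hash": config.config_hash(),
    }


def write_detection(out_dir, result: DetectionResult, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_annotations(out / "events.tsv", result.events)
    result.rates.as_series().rename("rate_per_min").to_csv(out / "rates.tsv", sep="\t")
    (out / "run.yaml").write_text(
        yaml.safe_dump({"config_hash": config.config_hash(), "seed": config.seed})
        + config.to_yaml()
    )


def write_cohort_report(out_dir, results: dict, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["patients"].to_csv(out / "patients.tsv", sep="\t", index=False)
    results["metrics"].to_csv(out / "metrics.tsv", sep="\t", index=False)
    (out / "run.yaml").write_text(
        yaml.safe_dump({"config_hash": results["config_hash"], "seed": config.seed})
        + config.to_yaml()
    )
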