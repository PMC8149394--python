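"""Synthetic iEEG with ground-truth HFO annotations and synthetic cohorts.

Real intracranial recordings cannot ship with a software package, so every
downstream stage is exercised on surrogates: spectrally shaped (1/f-like)
Gaussian background at 2000 Hz, Hann-enveloped oscillatory bursts in the
ripple (80–250 Hz) and fast-ripple (250–500 Hz) bands — co-occurring
bursts standing in for clinically relevant HFO — and multi-patient cohort
structures (channels, intervals, nights, resected-channel sets, ILAE
outcome labels) whose ground truth is known by construction.

Default event morphology: 8-cycle sinusoid, 150 uV peak per component,
Hann taper.  Against the default 50 uV RMS 1/f background this puts the
in-band event RMS at roughly 3x the band-limited background RMS — large
but within the range of clinically reported events, and chosen once so
that injected events visibly stand out of the baseline after band-pass
filtering.  Event timing is a homogeneous Poisson process per channel,
the simplest process consistent with a stated event *rate*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import IEEGRecording

RIPPLE_RANGE = (80.0, 250.0)
FAST_RIPPLE_RANGE = (250.0, 500.0)

#: events are not injected into the opening baseline-calibration second
_GUARD_S = 1.0


@dataclass(frozen=True)
class HFOSpec:
    """One injected oscillatory event on one channel."""

    onset_s: float
    ripple_freq: float
    fr_freq: float | None = None
    n_cycles: int = 8
    amplitude_uv: float = 150.0
    channel: int = 0

    def __post_init__(self) -> None:
        if not RIPPLE_RANGE[0] <= self.ripple_freq <= RIPPLE_RANGE[1]:
            raise ValueError(f"ripple_freq {self.ripple_freq} outside {RIPPLE_RANGE}")
        if self.fr_freq is not None and not (
            FAST_RIPPLE_RANGE[0] <= self.fr_freq <= FAST_RIPPLE_RANGE[1]
        ):
            raise ValueError(f"fr_freq {self.fr_freq} outside {FAST_RIPPLE_RANGE}")
        if self.n_cycles < 3:
            raise ValueError("need at least 3 cycles per component")
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        if self.onset_s < 0:
            raise ValueError("onset must be non-negative")

    @property
    def co_occurring(self) -> bool:
        return self.fr_freq is not None

    @property
    def duration_s(self) -> float:
        d = self.n_cycles / self.ripple_freq
        if self.fr_freq is not None:
            d = max(d, self.n_cycles / self.fr_freq)
        return d


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a synthetic multi-patient study."""

    n_patients: int = 3
    channels_per_patient: int = 6
    intervals_per_night: int = 2
    nights: int = 1
    n_pathological: int = 2
    base_hfo_rate: float = 10.0  # events/min on pathological channels
    background_rate: float = 0.0  # events/min elsewhere
    interval_s: float = 300.0
    fs: float = 2000.0
    background_uv: float = 50.0
    resection_covers_hfo_channels: bool | tuple[bool, ...] = True
    outcome_ilae: int | tuple[int, ...] = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathological > self.channels_per_patient:
            raise ValueError("pathological channels must be a subset of the channels")
        if min(self.base_hfo_rate, self.background_rate) < 0:
            raise ValueError("rates must be non-negative")
        for ilae in np.atleast_1d(self.outcome_ilae):
            if ilae < 1:
                raise ValueError("ILAE outcome classes start at 1")

    def covers(self, patient_index: int) -> bool:
        v = self.resection_covers_hfo_channels
        return bool(v[patient_index]) if isinstance(v, (tuple, list)) else bool(v)

    def ilae(self, patient_index: int) -> int:
        v = self.outcome_ilae
        return int(v[patient_index]) if isinstance(v, (tuple, list)) else int(v)


@dataclass
class SyntheticPatient:
    """Signals plus ground truth for one simulated patient."""

    patient_id: str
    channel_labels: list[str]
    recordings: list[IEEGRecording]
    annotations: pd.DataFrame
    pathological_channels: set[str]
    resected_channels: set[str]
    ilae_outcome: int


def generate_background(
    duration_s: float,
    fs: float = 2000.0,
    amplitude_uv: float = 50.0,
    spectral_exponent: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    n_channels: int = 1,
    channel_labels: list[str] | None = None,
) -> IEEGRecording:
    """Zero-mean 1/f-like Gaussian background, RMS-normalised per channel.

    White noise is shaped in the frequency domain by ``f**(-beta/2)``
    (flat below 1 Hz to keep the variance finite), giving a log-log
    periodogram slope of about ``-spectral_exponent`` — the qualitative
    shape of sleep iEEG, with no claim of physiological fidelity.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs < 1000:
        raise ValueError("sampling rate below 1000 Hz cannot carry fast ripples")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(freqs, 1.0) ** (-spectral_exponent / 2.0)
    shape[0] = 0.0  # zero mean
    data = np.empty((n_channels, n), dtype=np.float64)
    for c in range(n_channels):
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        data[c] = x * (amplitude_uv / rms) if rms > 0 and amplitude_uv > 0 else 0.0 * x
    if channel_labels is None:
        channel_labels = [f"ch{c:02d}" for c in range(n_channels)]
    return IEEGRecording(
        data=data,
        fs=fs,
        channel_labels=channel_labels,
        meta={"generator": "background", "spectral_exponent": spectral_exponent,
              "amplitude_uv": amplitude_uv},
    )


def _event_waveform(spec: HFOSpec, fs: float) -> np.ndarray:
    """Hann-enveloped sinusoid(s); zero at both ends so injection is local."""
    n = int(round(spec.duration_s * fs))
    wave = np.zeros(n)
    t = np.arange(n) / fs
    for freq in filter(None, (spec.ripple_freq, spec.fr_freq)):
        dur = spec.n_cycles / freq
        m = int(round(dur * fs))
        env = np.hanning(m)
        wave[:m] += spec.amplitude_uv * env * np.sin(2 * np.pi * freq * t[:m])
    return wave


def inject_hfo(
    recording: IEEGRecording, specs: list[HFOSpec]
) -> tuple[IEEGRecording, pd.DataFrame]:
    """Add tapered oscillatory bursts; returns the new recording + truth.

    The signal outside the annotated windows is untouched (the envelopes
    vanish at the window edges).  Annotation columns: ``onset_s``,
    ``duration_s``, ``channel``, ``type`` ('ripple' or 'ripple+fr').
    """
    data = recording.data.copy()
    rows = []
    for spec in specs:
        if spec.onset_s + spec.duration_s > recording.duration_s + 1e-9:
            raise ValueError(
                f"event at {spec.onset_s:.3f}s (dur {spec.duration_s:.3f}s) "
                f"exceeds recording duration {recording.duration_s:.3f}s"
            )
        if not 0 <= spec.channel < recording.n_channels:
            raise ValueError(f"channel index {spec.channel} out of range")
        wave = _event_waveform(spec, recording.fs)
        i0 = int(round(spec.onset_s * recording.fs))
        data[spec.channel, i0 : i0 + wave.size] += wave
        rows.append(
            {
                "onset_s": spec.onset_s,
                "duration_s": spec.duration_s,
                "channel": recording.channel_labels[spec.channel],
                "type": "ripple+fr" if spec.co_occurring else "ripple",
            }
        )
    annotations = pd.DataFrame(rows, columns=["onset_s", "duration_s", "channel", "type"])
    return replace(recording, data=data), annotations


def _poisson_events(
    rng: np.random.Generator,
    rate_per_min: float,
    duration_s: float,
    channel: int,
    co_occurring: bool = True,
) -> list[HFOSpec]:
    """Homogeneous Poisson event times with band-uniform frequencies."""
    usable = duration_s - _GUARD_S - 0.2
    if rate_per_min <= 0 or usable <= 0:
        return []
    n = rng.poisson(rate_per_min * usable / 60.0)
    onsets = np.sort(rng.uniform(_GUARD_S, _GUARD_S + usable, size=n))
    specs = []
    for onset in onsets:
        specs.append(
            HFOSpec(
                onset_s=float(onset),
                ripple_freq=float(rng.uniform(100.0, 200.0)),
                fr_freq=float(rng.uniform(260.0, 450.0)) if co_occurring else None,
                channel=channel,
            )
        )
    return specs


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Simulate a cohort with per-patient ground truth.

    Pathological channels receive co-occurring ripple+fast-ripple events
    at ``base_hfo_rate``; the remaining channels receive ripple-only
    events at ``background_rate``.  When ``resection_covers_hfo_channels``
    the resected set is the pathological set plus one extra channel;
    otherwise one pathological channel is left outside the resection.
    Fully reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    patients = []
    for p, pat_seed in enumerate(root.spawn(spec.n_patients), start=1):
        rng = np.random.default_rng(pat_seed)
        labels = [f"P{p}C{c:02d}" for c in range(spec.channels_per_patient)]
        path_idx = sorted(
            rng.choice(spec.channels_per_patient, size=spec.n_pathological, replace=False)
        )
        pathological = {labels[i] for i in path_idx}
        if spec.covers(p - 1):
            extra = [i for i in range(spec.channels_per_patient) if i not in path_idx]
            resected = set(pathological)
            if extra:
                resected.add(labels[extra[0]])
        else:
            resected = {labels[i] for i in path_idx[1:]}
        recordings = []
        all_annotations = []
        for night in range(1, spec.nights + 1):
            for k in range(1, spec.intervals_per_night + 1):
                interval_id = f"n{night}i{k}"
                rec = generate_background(
                    spec.interval_s,
                    fs=spec.fs,
                    amplitude_uv=spec.background_uv,
                    seed=np.random.SeedSequence(rng.integers(2**31)),
                    n_channels=spec.channels_per_patient,
                    channel_labels=labels,
                )
                events: list[HFOSpec] = []
                for c in range(spec.channels_per_patient):
                    pathological_ch = c in path_idx
                    events.extend(
                        _poisson_events(
                            rng,
                            spec.base_hfo_rate if pathological_ch else spec.background_rate,
                            spec.interval_s,
                            channel=c,
                            co_occurring=pathological_ch,
                        )
                    )
                rec, ann = inject_hfo(rec, events)
                rec = replace(rec, interval_id=interval_id, night_id=f"n{night}")
                ann["interval_id"] = interval_id
                ann["night_id"] = f"n{night}"
                recordings.append(rec)
                all_annotations.append(ann)
        nonempty = [a for a in all_annotations if len(a)]
        if nonempty:
            annotations = pd.concat(nonempty, ignore_index=True)
        else:
            annotations = pd.DataFrame(
                columns=["onset_s", "duration_s", "channel", "type", "interval_id", "night_id"]
            )
        patients.append(
            SyntheticPatient(
                patient_id=f"synthetic-{p:02d}",
                channel_labels=labels,
                recordings=recordings,
                annotations=annotations,
                pathological_channels=pathological,
                resected_channels=resected,
                ilae_outcome=spec.ilae(p - 1),
            )
        )
    return patients
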