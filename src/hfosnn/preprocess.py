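"""Band-pass filtering and adaptive-baseline estimation for intracranial EEG.

The wideband bipolar iEEG is split into the two bands in which
high-frequency oscillations are defined — ripples (80–250 Hz) and fast
ripples (250–500 Hz) — with a causal second-order (single biquad)
Butterworth band-pass, mirroring the second-order analog filter stage of
the hardware this model emulates.  A per-channel baseline, the average of
the lowest quartile of 50-ms window maxima over the first second of the
recording, scales the delta-modulator thresholds downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class IEEGRecording:
    """Multichannel sampled iEEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique bipolar channel names, e.g. ``"AR1-2"``.
    interval_id, night_id : str or None
        Recording-session metadata.
    meta : dict
        Free-form provenance (filter settings, generator parameters, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    interval_id: str | None = None
    night_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its clinical name."""

    low: float
    high: float
    name: str = "band"

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2.0):
            raise ValueError(
                f"band {self.name} [{self.low}, {self.high}] Hz invalid for fs={fs}"
            )


RIPPLE_BAND = BandSpec(80.0, 250.0, "ripple")
FAST_RIPPLE_BAND = BandSpec(250.0, 500.0, "fast_ripple")


@dataclass(frozen=True)
class Baseline:
    """Per-channel amplitude baseline in microvolts (non-negative)."""

    value: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("baseline must be non-negative")


def design_bandpass(band: BandSpec, fs: float, order: int = 1) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass for ``band``.

    ``order`` is the Butterworth prototype order; the band-pass has twice
    that many poles, so the default is one biquad (two poles), matching the
    second-order analog stage being modeled.
    """
    band.validate(fs)
    return signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass_magnitude(band: BandSpec, fs: float, freqs, order: int = 1) -> np.ndarray:
    """Analytic magnitude response |H(f)| of the designed digital filter."""
    sos = design_bandpass(band, fs, order)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, dtype=float) / fs)
    return np.abs(h)


def bandpass(
    recording: IEEGRecording,
    band: BandSpec,
    order: int = 1,
    zero_phase: bool = False,
) -> IEEGRecording:
    """Filter every channel of ``recording`` into ``band``.

    Causal (``sosfilt``) by default, which is what a real-time system can
    compute; ``zero_phase`` switches to forward-backward filtering for
    offline analysis.  Filter design is recorded in the output metadata.
    """
    sos = design_bandpass(band, fs=recording.fs, order=order)
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    data = filt(sos, recording.data, axis=1)
    meta = dict(recording.meta)
    meta["filter"] = {
        "band": band.name,
        "low_hz": band.low,
        "high_hz": band.high,
        "design": "butterworth-biquad",
        "order": order,
        "zero_phase": zero_phase,
    }
    return replace(recording, data=np.ascontiguousarray(data), meta=meta)


def compute_baseline(
    channel_signal: np.ndarray,
    fs: float,
    window_ms: float = 50.0,
    calibration_s: float = 1.0,
    channel: str = "",
) -> Baseline:
    """Adaptive amplitude baseline from the start of a recording.

    The first ``calibration_s`` seconds are cut into non-overlapping
    windows of ``window_ms``; the maximum absolute amplitude of each
    window is taken, the maxima are sorted, and the baseline is the mean
    of the lowest quartile (the ``ceil(n/4)`` smallest values).  Taking
    the *lowest* quartile rejects transients and oscillatory events that
    happen to fall in the calibration second, while the per-window *max*
    stays above the noise floor.
    """
    x = np.asarray(channel_signal, dtype=np.float64).ravel()
    n_cal = int(round(calibration_s * fs))
    if x.size < n_cal:
        raise ValueError(
            f"signal ({x.size} samples) shorter than calibration window ({n_cal})"
        )
    win = int(round(window_ms * 1e-3 * fs))
    if win < 1:
        raise ValueError("window_ms too short for sampling rate")
    n_win = int(math.floor(calibration_s * 1000.0 / window_ms))
    if n_win < 1:
        raise ValueError("calibration window shorter than one analysis window")
    maxima = np.abs(x[: n_win * win]).reshape(n_win, win).max(axis=1)
    maxima.sort()
    k = math.ceil(n_win / 4)
    return Baseline(value=float(maxima[:k].mean()), channel=channel)
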