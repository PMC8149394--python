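"""Asynchronous delta modulation: analog traces to UP/DN spike trains.

The encoder tracks a reference value and emits an UP (DN) event whenever
the pre-amplified signal rises (falls) at least ``v_tu`` (``v_td``) away
from it, then stays silent for a refractory dead time.  The precise event
timing carries the signal content; :func:`adm_decode` reconstructs a
piecewise-constant estimate from the events alone, which is how the
encoder is verified.

Two reference-update conventions are supported.  In ``"threshold"`` mode
(default) the reference steps by exactly the threshold on every emission,
which makes the reconstruction error provably bounded by
``max(v_tu, v_td)`` for slowly varying inputs.  In ``"sample"`` mode the
reference snaps to the current sample.  After a nonzero refractory period
the reference always re-latches to the first post-refractory sample, so
excursions during the dead time are seen only through that sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

_UP = 1
_DN = -1


@dataclass(frozen=True)
class ADMParams:
    """Delta-modulator settings.

    v_tu, v_td : float
        UP / DN thresholds in microvolts at the amplifier output.
    refractory_s : float
        Dead time after each event (hardware default 300 us).
    gain : float
        Pre-amplification applied to the input before thresholding.
    relatch : {"threshold", "sample"}
        Reference update on emission (see module docstring).
    """

    v_tu: float
    v_td: float
    refractory_s: float = 300e-6
    gain: float = 8.0
    relatch: str = "threshold"

    def __post_init__(self) -> None:
        if self.v_tu <= 0 or self.v_td <= 0:
            raise ValueError("thresholds must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory period must be non-negative")
        if self.relatch not in ("threshold", "sample"):
            raise ValueError(f"unknown relatch mode {self.relatch!r}")


@dataclass
class SpikeTrain:
    """Timestamped UP/DN events from one (channel, band) source."""

    times: np.ndarray
    polarities: np.ndarray  # +1 UP, -1 DN
    source: str = ""
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.polarities = np.asarray(self.polarities, dtype=np.int8)
        if self.times.shape != self.polarities.shape:
            raise ValueError("times and polarities must have the same length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def up_times(self) -> np.ndarray:
        return self.times[self.polarities == _UP]

    @property
    def dn_times(self) -> np.ndarray:
        return self.times[self.polarities == _DN]

    def __len__(self) -> int:
        return self.times.size


@njit(cache=True)
def _encode_kernel(v, v_tu, v_td, refr_samples, threshold_step):
    n = v.size
    out_idx = np.empty(n, dtype=np.int64)
    out_pol = np.empty(n, dtype=np.int8)
    count = 0
    r = v[0]
    next_active = 0
    relatch_pending = False
    for i in range(n):
        if i < next_active:
            continue
        if relatch_pending:
            r = v[i]
            relatch_pending = False
            continue
        d = v[i] - r
        fired = 0
        if d >= v_tu:
            fired = 1
            r = r + v_tu if threshold_step else v[i]
        elif -d >= v_td:
            fired = -1
            r = r - v_td if threshold_step else v[i]
        if fired != 0:
            out_idx[count] = i
            out_pol[count] = fired
            count += 1
            if refr_samples > 0:
                next_active = i + refr_samples
                relatch_pending = True
    return out_idx[:count], out_pol[:count]


def adm_encode(signal: np.ndarray, fs: float, params: ADMParams, source: str = "") -> SpikeTrain:
    """Encode a sampled signal into an UP/DN spike train.

    The reference is initialised to the first pre-amplified sample; events
    are stamped at sample resolution (the input is already discrete and
    the downstream integrator step is finer).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.ascontiguousarray(np.asarray(signal, dtype=np.float64).ravel())
    if x.size == 0:
        return SpikeTrain(np.empty(0), np.empty(0, dtype=np.int8), source, 0.0)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite samples")
    refr_samples = int(math.ceil(params.refractory_s * fs)) if params.refractory_s > 0 else 0
    idx, pol = _encode_kernel(
        params.gain * x,
        float(params.v_tu),
        float(params.v_td),
        refr_samples,
        params.relatch == "threshold",
    )
    return SpikeTrain(idx / fs, pol, source=source, duration_s=x.size / fs)


def adm_decode(
    spikes: SpikeTrain, params: ADMParams, duration_s: float, fs: float = 2000.0
) -> np.ndarray:
    """Piecewise-constant reconstruction from the event stream.

    Starts at zero; each UP steps by ``+v_tu`` and each DN by ``-v_td``.
    Returned sampled at ``fs`` over ``duration_s``; dividing by
    ``params.gain`` brings it back to the input scale (up to the unknown
    initial value of the signal).
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    steps = np.where(spikes.polarities == _UP, params.v_tu, -params.v_td)
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    return cum[np.searchsorted(spikes.times, t, side="right")]


def thresholds_from_baseline(
    baseline,
    factor: float = 1.5,
    floor: float = 0.5,
    refractory_s: float = 300e-6,
    gain: float = 8.0,
    relatch: str = "threshold",
) -> ADMParams:
    """Symmetric ADM thresholds adapted to a channel's baseline.

    ``v_tu = v_td = factor * baseline``, never below ``floor`` (the
    comparator-offset-inspired minimum), so an all-quiet channel still
    gets finite thresholds.  The default factor of 1.5 places the
    threshold at roughly 2.7x the RMS of band-limited background (the
    baseline statistic sits near 1.8x RMS), which silences the encoder on
    noise while oscillatory events, several times the background RMS,
    drive it at kilohertz burst rates.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if floor <= 0:
        raise ValueError("floor must be positive")
    v = max(factor * baseline.value, floor)
    return ADMParams(
        v_tu=v, v_td=v, refractory_s=refractory_s, gain=gain, relatch=relatch
    )
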