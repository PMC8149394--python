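"""Behavioral model of the two-layer spiking network.

Four event streams (ripple UP/DN, fast-ripple UP/DN) feed 256
integrate-and-fire neurons through first-order dynamic synapses.  Each
neuron obeys

    tau_mem dV/dt  = -V + I_syn - v_ahp + f(V),      I_syn = I_exc - I_inh
    tau_ahp dv_ahp/dt = -v_ahp + w_ahp * delta_spk

with optional exponential spike-initiation term
``f(V) = delta_T * exp((V - v_T)/delta_T)`` (adaptive-exponential mode;
plain adaptive LIF by default).  The synapses integrate their input
spikes with first-order dynamics

    tau_x dI_x/dt = -I_x + w_x * delta_spikes

realised as a jump-decay process: every input spike increments the
current by its weight instantaneously, so a regular train at rate ``r``
settles at a mean of ``w * r * tau``.  Currents, the adaptation variable
and the membrane are clipped at zero, as in the subthreshold analog
circuits this model describes.

Numerics: the membrane is advanced by forward Euler; the linear synapse
and adaptation states decay by their exact exponential factor each step,
which is accurate at any ratio of ``dt`` to the synaptic time constant
(the fast inhibitory constants reach 0.1 ms at the default
``dt = 0.1 ms``).  Per-neuron parameter diversity emulates analog device
mismatch: uniform draws for the synaptic time constants, then every
parameter is scaled by a truncated-Gaussian factor (mean 1, configurable
CV, cut at three sigma and at zero).

All currents are expressed in nanoamperes and the membrane potential in
the same numeric scale, following the circuit-equation convention in
which ``I_syn`` enters the membrane equation directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import lfilter

from .adm import ADMParams, SpikeTrain, adm_encode

#: inhibitory time-constant presets: the detection-tuned fast range is the
#: default; the wide range matches the nominal hardware corner values.
TAU_INH_RANGE_FAST = (0.1e-3, 1.0e-3)
TAU_INH_RANGE_WIDE = (2.0e-3, 5.7e-3)
TAU_EXC_RANGE = (3.0e-3, 6.0e-3)


class CalibrationError(RuntimeError):
    """Raised when no firing threshold satisfies the calibration anchor."""


@dataclass(frozen=True)
class SynapseParams:
    """Nominal first-order synapse parameters (weights in nA, taus in s)."""

    tau_exc: float = 4.5e-3
    tau_inh: float = 0.55e-3
    w_exc: float = 2.0
    w_inh: float = 2.0  # applied subtractively

    def __post_init__(self) -> None:
        if min(self.tau_exc, self.tau_inh, self.w_exc, self.w_inh) <= 0:
            raise ValueError("synapse parameters must be positive")


@dataclass(frozen=True)
class NeuronParams:
    """Nominal adaptive (exponential) integrate-and-fire parameters."""

    tau_mem: float = 15.2e-3
    tau_ahp: float = 35.7e-3
    w_ahp: float = 1.0
    v_thresh: float | None = None  # set by calibrate_threshold
    v_reset: float = 0.0
    exp_enabled: bool = False
    delta_T: float = 1.0
    v_T: float = 10.0

    def __post_init__(self) -> None:
        if self.tau_mem <= 0 or self.tau_ahp <= 0:
            raise ValueError("time constants must be positive")
        if self.v_thresh is not None and self.v_thresh <= self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")


@dataclass(frozen=True)
class SNNConfig:
    """Network-level settings: size, mismatch level, ranges, integrator."""

    n_neurons: int = 256
    mismatch_cv: float = 0.20
    tau_exc_range: tuple[float, float] = TAU_EXC_RANGE
    tau_inh_range: tuple[float, float] = TAU_INH_RANGE_FAST
    seed: int = 0
    dt: float = 1e-4
    neuron_refractory_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if not 0 <= self.mismatch_cv < 1:
            raise ValueError("mismatch_cv must be in [0, 1)")
        for lo, hi in (self.tau_exc_range, self.tau_inh_range):
            if not 0 < lo <= hi:
                raise ValueError("time-constant ranges must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class SNNState:
    """Integrator state for a population of neurons."""

    v_mem: np.ndarray
    v_ahp: np.ndarray
    i_exc: np.ndarray
    i_inh: np.ndarray
    refr: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_neurons: int) -> "SNNState":
        z = lambda: np.zeros(n_neurons, dtype=np.float64)
        return cls(z(), z(), z(), z(), np.zeros(n_neurons, dtype=np.int64))


@dataclass
class Raster:
    """Per-neuron sorted spike times over a fixed window."""

    spike_times: list[np.ndarray]
    duration_s: float

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spike_times], dtype=np.int64)

    def rates_hz(self) -> np.ndarray:
        return self.counts() / self.duration_s if self.duration_s > 0 else self.counts() * 0.0

    def pooled_times(self) -> np.ndarray:
        if not self.spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.spike_times))


PARAM_COLUMNS = [
    "tau_mem", "tau_ahp", "w_ahp", "v_thresh", "v_reset",
    "tau_exc", "tau_inh", "w_exc", "w_inh",
]


def _mismatch_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative mismatch: N(1, cv) truncated at +/-3 sigma and at 0."""
    if cv == 0:
        return np.ones(n)
    lo, hi = max(1.0 - 3.0 * cv, np.finfo(float).tiny), 1.0 + 3.0 * cv
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(1.0, cv, size=max(2 * (n - filled), 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def sample_network(
    config: SNNConfig,
    synapse: SynapseParams,
    neuron: NeuronParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the per-neuron parameter table that stands in for device mismatch.

    Synaptic time constants are uniform over their configured ranges;
    every parameter is then jittered by an independent truncated-Gaussian
    factor.  Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if neuron.v_thresh is None:
        raise ValueError("neuron.v_thresh unset — run calibrate_threshold first")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    nominal = {
        "tau_mem": neuron.tau_mem,
        "tau_ahp": neuron.tau_ahp,
        "w_ahp": neuron.w_ahp,
        "v_thresh": neuron.v_thresh,
        "v_reset": neuron.v_reset,
        "w_exc": synapse.w_exc,
        "w_inh": synapse.w_inh,
    }
    table = pd.DataFrame(index=pd.RangeIndex(n, name="neuron"))
    table["tau_exc"] = rng.uniform(*config.tau_exc_range, size=n)
    table["tau_inh"] = rng.uniform(*config.tau_inh_range, size=n)
    for name, value in nominal.items():
        table[name] = value
    for col in PARAM_COLUMNS:
        table[col] = table[col].to_numpy() * _mismatch_factors(rng, n, config.mismatch_cv)
    return table[PARAM_COLUMNS]


def step(
    state: SNNState,
    params: pd.DataFrame,
    n_up: np.ndarray | int,
    n_dn: np.ndarray | int,
    dt: float,
    exp_enabled: bool = False,
    delta_T: float = 1.0,
    v_T: float = 10.0,
    refractory_steps: int = 0,
) -> np.ndarray:
    """One forward-Euler step of the whole population (NumPy reference).

    Input spikes arriving in this step jump the synaptic currents before
    the membrane update, so the membrane sees them immediately; the
    linear states then decay by their exact exponential factor.  Returns
    the boolean spike vector and mutates ``state`` in place.  The numba
    production kernel is held to agree with this function exactly.
    """
    p = params
    state.i_exc += p["w_exc"].to_numpy() * n_up
    state.i_inh += p["w_inh"].to_numpy() * n_dn

    active = state.refr <= 0
    i_syn = state.i_exc - state.i_inh
    f = np.zeros_like(state.v_mem)
    forced = np.zeros_like(active)
    if exp_enabled:
        arg = (state.v_mem - v_T) / delta_T
        forced = active & (arg > 25.0)  # AdExp escape: overflow means a spike
        f[arg <= 25.0] = delta_T * np.exp(arg[arg <= 25.0])
    k = dt / p["tau_mem"].to_numpy()
    v_new = state.v_mem + k * (-state.v_mem + i_syn - state.v_ahp + f)
    state.v_mem = np.where(active, v_new, p["v_reset"].to_numpy())
    np.maximum(state.v_mem, 0.0, out=state.v_mem)

    fired = (active & (state.v_mem >= p["v_thresh"].to_numpy())) | forced
    state.v_mem = np.where(fired, p["v_reset"].to_numpy(), state.v_mem)
    state.v_ahp = state.v_ahp + fired * p["w_ahp"].to_numpy()
    state.refr = np.where(fired, refractory_steps, np.maximum(state.refr - 1, 0))

    state.i_exc *= np.exp(-dt / p["tau_exc"].to_numpy())
    state.i_inh *= np.exp(-dt / p["tau_inh"].to_numpy())
    state.v_ahp *= np.exp(-dt / p["tau_ahp"].to_numpy())
    for arr in (state.i_exc, state.i_inh, state.v_ahp):
        np.maximum(arr, 0.0, out=arr)
    state.t += dt
    return fired


@njit(cache=True)
def _simulate_kernel(
    exc_counts, inh_counts, dt,
    tau_mem, tau_ahp, w_ahp, v_thresh, v_reset,
    tau_exc, tau_inh, w_exc, w_inh,
    exp_enabled, delta_t, v_t, refr_steps,
):
    n_steps = exc_counts.size
    n_neurons = tau_mem.size
    cap = 4096
    sp_neuron = np.empty(cap, dtype=np.int32)
    sp_step = np.empty(cap, dtype=np.int64)
    count = 0
    for j in range(n_neurons):
        de = math.exp(-dt / tau_exc[j])
        di = math.exp(-dt / tau_inh[j])
        da = math.exp(-dt / tau_ahp[j])
        k = dt / tau_mem[j]
        v = 0.0
        va = 0.0
        ie = 0.0
        ii = 0.0
        refr = 0
        for i in range(n_steps):
            if exc_counts[i] > 0:
                ie += w_exc[j] * exc_counts[i]
            if inh_counts[i] > 0:
                ii += w_inh[j] * inh_counts[i]
            fired = False
            if refr > 0:
                refr -= 1
                v = v_reset[j]
            else:
                f = 0.0
                if exp_enabled:
                    arg = (v - v_t) / delta_t
                    if arg > 25.0:
                        fired = True
                    else:
                        f = delta_t * math.exp(arg)
                v = v + k * (-v + (ie - ii) - va + f)
                if v < 0.0:
                    v = 0.0
                if v >= v_thresh[j]:
                    fired = True
            if fired:
                if count == cap:
                    cap2 = cap * 2
                    new_n = np.empty(cap2, dtype=np.int32)
                    new_s = np.empty(cap2, dtype=np.int64)
                    new_n[:cap] = sp_neuron
                    new_s[:cap] = sp_step
                    sp_neuron = new_n
                    sp_step = new_s
                    cap = cap2
                sp_neuron[count] = j
                sp_step[count] = i
                count += 1
                v = v_reset[j]
                va += w_ahp[j]
                refr = refr_steps
            ie *= de
            ii *= di
            va *= da
            if va < 0.0:
                va = 0.0
    return sp_neuron[:count], sp_step[:count]


@njit(cache=True)
def _trace_kernel(
    exc_counts, inh_counts, dt,
    tau_mem, tau_ahp, w_ahp, v_thresh, v_reset,
    tau_exc, tau_inh, w_exc, w_inh,
    exp_enabled, delta_t, v_t,
):
    """Single-neuron run recording end-of-step state (for tests/calibration)."""
    n_steps = exc_counts.size
    v_trace = np.empty(n_steps)
    ie_trace = np.empty(n_steps)
    ii_trace = np.empty(n_steps)
    va_trace = np.empty(n_steps)
    spikes = np.empty(n_steps, dtype=np.int64)
    n_sp = 0
    de = math.exp(-dt / tau_exc)
    di = math.exp(-dt / tau_inh)
    da = math.exp(-dt / tau_ahp)
    k = dt / tau_mem
    v = 0.0
    va = 0.0
    ie = 0.0
    ii = 0.0
    for i in range(n_steps):
        ie += w_exc * exc_counts[i]
        ii += w_inh * inh_counts[i]
        fired = False
        f = 0.0
        if exp_enabled:
            arg = (v - v_t) / delta_t
            if arg > 25.0:
                fired = True
            else:
                f = delta_t * math.exp(arg)
        v = v + k * (-v + (ie - ii) - va + f)
        if v < 0.0:
            v = 0.0
        if v >= v_thresh:
            fired = True
        if fired:
            spikes[n_sp] = i
            n_sp += 1
            v = v_reset
            va += w_ahp
        ie *= de
        ii *= di
        va *= da
        v_trace[i] = v
        ie_trace[i] = ie
        ii_trace[i] = ii
        va_trace[i] = va
    return v_trace, ie_trace, ii_trace, va_trace, spikes[:n_sp]


def simulate_neuron(
    exc_counts: np.ndarray,
    inh_counts: np.ndarray,
    neuron: NeuronParams,
    synapse: SynapseParams,
    dt: float,
    v_thresh: float | None = None,
):
    """Run one neuron on binned input-spike counts, returning state traces.

    ``v_thresh=None`` simulates the free (non-spiking) membrane, which is
    what the threshold calibration measures.
    """
    vth = v_thresh if v_thresh is not None else (
        neuron.v_thresh if neuron.v_thresh is not None else np.inf
    )
    exc = np.ascontiguousarray(exc_counts, dtype=np.int64)
    inh = np.ascontiguousarray(inh_counts, dtype=np.int64)
    v, ie, ii, va, spikes = _trace_kernel(
        exc, inh, float(dt),
        neuron.tau_mem, neuron.tau_ahp, neuron.w_ahp, float(vth), neuron.v_reset,
        synapse.tau_exc, synapse.tau_inh, synapse.w_exc, synapse.w_inh,
        neuron.exp_enabled, neuron.delta_T, neuron.v_T,
    )
    return {"v_mem": v, "i_exc": ie, "i_inh": ii, "v_ahp": va, "spike_steps": spikes}


def regular_train_counts(n_spikes: int, rate_hz: float, dt: float, tail_s: float = 0.05) -> np.ndarray:
    """Binned spike counts for a regular train of ``n_spikes`` at ``rate_hz``."""
    duration = n_spikes / rate_hz + tail_s
    n_steps = int(math.ceil(duration / dt))
    counts = np.zeros(n_steps, dtype=np.int64)
    idx = np.minimum(np.floor(np.arange(n_spikes) / rate_hz / dt).astype(np.int64), n_steps - 1)
    np.add.at(counts, idx, 1)
    return counts


def calibrate_threshold(
    neuron: NeuronParams,
    synapse: SynapseParams,
    n_spikes: int = 14,
    rate_hz: float = 3000.0,
    dt: float = 1e-4,
) -> float:
    """Firing threshold anchored to the n-spike excitatory-burst criterion.

    Finds ``v_thresh`` such that a regular excitatory train of exactly
    ``n_spikes`` at ``rate_hz`` makes the neuron fire at least once while
    ``n_spikes - 1`` never does: the free-membrane peaks for the two
    train lengths bracket every admissible threshold, and their midpoint
    is returned (mismatch must be disabled for calibration; it is applied
    afterwards, when the network is sampled).
    """
    if n_spikes < 2:
        raise ValueError("need at least two spikes to bracket a threshold")
    zeros = None
    peaks = []
    for n in (n_spikes - 1, n_spikes):
        exc = regular_train_counts(n, rate_hz, dt)
        zeros = np.zeros_like(exc)
        out = simulate_neuron(exc, zeros, neuron, synapse, dt, v_thresh=np.inf)
        peaks.append(float(out["v_mem"].max()))
    lo, hi = peaks
    if not hi > lo:
        raise CalibrationError(
            f"{n_spikes} spikes at {rate_hz} Hz do not raise the membrane peak "
            f"above the {n_spikes - 1}-spike response ({hi} <= {lo})"
        )
    v_thresh = 0.5 * (lo + hi)
    if v_thresh <= neuron.v_reset:
        raise CalibrationError("calibrated threshold does not exceed the reset value")
    # verify the anchor end to end
    for n, expect_spike in ((n_spikes, True), (n_spikes - 1, False)):
        exc = regular_train_counts(n, rate_hz, dt)
        out = simulate_neuron(exc, np.zeros_like(exc), neuron, synapse, dt, v_thresh=v_thresh)
        if (out["spike_steps"].size >= 1) != expect_spike:
            raise CalibrationError("calibration verification failed")
    return v_thresh


def bin_spike_counts(trains, dt: float, n_steps: int, polarity: int) -> np.ndarray:
    counts = np.zeros(n_steps, dtype=np.int64)
    for train in trains:
        times = train.up_times if polarity > 0 else train.dn_times
        if times.size:
            # tiny offset keeps events that sit exactly on a bin edge in that bin
            idx = np.minimum(((times + 1e-12) / dt).astype(np.int64), n_steps - 1)
            np.add.at(counts, idx, 1)
    return counts


def run_network(
    spike_trains,
    params: pd.DataFrame,
    dt: float = 1e-4,
    duration_s: float | None = None,
    exp_enabled: bool = False,
    delta_T: float = 1.0,
    v_T: float = 10.0,
    neuron_refractory_s: float = 0.0,
) -> Raster:
    """Drive the full population with the band spike trains.

    Every neuron receives every stream (full fan-out): UP events excite,
    DN events inhibit.  ``spike_trains`` is an iterable of
    :class:`~hfosnn.adm.SpikeTrain` (typically the ripple and fast-ripple
    encodings of one channel).
    """
    trains = list(spike_trains)
    for tr in trains:
        if np.any(np.diff(tr.times) < 0):
            raise ValueError("input spike trains must be sorted")
    if duration_s is None:
        duration_s = max((tr.duration_s for tr in trains), default=0.0)
    n_steps = int(math.ceil(duration_s / dt))
    n_neurons = len(params)
    if n_steps == 0 or all(len(tr) == 0 for tr in trains):
        return Raster([np.empty(0) for _ in range(n_neurons)], duration_s)
    exc = bin_spike_counts(trains, dt, n_steps, +1)
    inh = bin_spike_counts(trains, dt, n_steps, -1)
    col = lambda c: np.ascontiguousarray(params[c].to_numpy(dtype=np.float64))
    sp_neuron, sp_step = _simulate_kernel(
        exc, inh, float(dt),
        col("tau_mem"), col("tau_ahp"), col("w_ahp"), col("v_thresh"), col("v_reset"),
        col("tau_exc"), col("tau_inh"), col("w_exc"), col("w_inh"),
        exp_enabled, float(delta_T), float(v_T),
        int(round(neuron_refractory_s / dt)),
    )
    spike_times = []
    times = sp_step * dt
    for j in range(n_neurons):
        spike_times.append(np.sort(times[sp_neuron == j]))
    return Raster(spike_times, duration_s)


def dpi_frequency_response(
    tau: float,
    freqs,
    fs: float = 20000.0,
    amplitude: float = 10.0,
    threshold: float = 0.5,
    w: float = 1.0,
    n_cycles: int = 40,
) -> np.ndarray:
    """Measured gain of a first-order synapse driven by sine-encoded spikes.

    For each frequency a sine is delta-modulated into UP events, the
    events drive the jump-decay synapse, and the gain is the ratio of the
    Fourier amplitude of the synaptic current at the drive frequency to
    that of its spike-train input, normalised by the DC gain ``tau``.  A
    faithful first-order element returns ``1/sqrt(1 + (2 pi f tau)^2)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    gains = np.full(freqs.shape, np.nan)
    decay = math.exp(-1.0 / (fs * tau))
    for m, f in enumerate(freqs):
        transient = max(10.0 * tau, 2.0 / f)
        duration = transient + n_cycles / f
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        x = amplitude * np.sin(2 * np.pi * f * t)
        train = adm_encode(
            x, fs, ADMParams(v_tu=threshold, v_td=threshold, refractory_s=0.0, gain=1.0)
        )
        up = train.up_times
        counts = np.bincount(
            np.minimum((up * fs).round().astype(np.int64), n - 1), minlength=n
        ).astype(np.float64)
        current = lfilter([w], [1.0, -decay], counts)
        # integer number of cycles after the transient
        start = int(math.ceil(transient * fs))
        n_win = min(int(math.floor((n - start) * f / fs) * fs / f), n - start)
        if n_win <= 0:
            continue
        sl = slice(start, start + n_win)
        phase = np.exp(-2j * np.pi * f * t[sl])
        z_current = np.sum(current[sl] * phase) / fs
        in_win = (up >= t[sl.start]) & (up < t[sl.start] + int(n_win) / fs)
        if not np.any(in_win):
            continue
        z_spikes = np.sum(np.exp(-2j * np.pi * f * up[in_win]))
        gains[m] = abs(z_current) / (w * abs(z_spikes)) / tau
    return gains


def dpi_bandpass_response(
    tau_exc: float, tau_inh: float, freqs, **kwargs
) -> np.ndarray:
    """Band-pass curve from a slow excitatory and a fast inhibitory synapse.

    The normalised single-pole gains of the two pathways coincide at DC
    and both vanish at high frequency; the magnitude of their difference
    is therefore zero at both ends and peaks in between — the band the
    synapse pair is tuned to.
    """
    g_exc = dpi_frequency_response(tau_exc, freqs, **kwargs)
    g_inh = dpi_frequency_response(tau_inh, freqs, **kwargs)
    return np.abs(g_exc - g_inh)
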