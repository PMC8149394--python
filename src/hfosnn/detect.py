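"""From the population raster to discrete HFO events and per-channel rates.

The 256 mismatched neurons act as an ensemble of weak classifiers: their
pooled output is evaluated on a fixed grid of non-overlapping 15-ms
snippets anchored at the interval start.  In the default
``consecutive_snippets`` mode a detection requires spikes in at least two
consecutive non-empty snippets; ``any_spike`` mode flags every non-empty
snippet.  Detections closer than one snippet are aggregated into a single
HFO.  Neurons that fire essentially continuously carry no information and
are masked out before detection.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .snn import Raster

DETECT_MODES = ("consecutive_snippets", "any_spike")


@dataclass(frozen=True)
class HFOEvent:
    """One detected event: pooled first/last spike time and channel."""

    t_start: float
    t_end: float
    channel: str = ""
    n_neurons_active: int = 0

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")


@dataclass
class HFOVector:
    """Per-channel HFO rates (events/min) for one recording interval."""

    channels: list[str]
    rates: np.ndarray
    duration_s: float
    interval_id: str | None = None
    night_id: str | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (len(self.channels),):
            raise ValueError("one rate per channel required")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.rates, index=self.channels, name=self.interval_id)


def mask_outlier_neurons(raster: Raster, max_rate_hz: float = 10.0) -> Raster:
    """Drop neurons whose mean rate exceeds ``max_rate_hz`` (uninformative).

    The mask is meant to be derived once per study and applied globally,
    not re-estimated per interval; see
    :func:`outlier_mask` for deriving the mask from pooled activity.
    """
    keep = raster.rates_hz() <= max_rate_hz
    return apply_neuron_mask(raster, keep)


def outlier_mask(rasters: list[Raster], max_rate_hz: float = 10.0) -> np.ndarray:
    """Boolean keep-mask from mean firing rates pooled over many intervals."""
    counts = np.sum([r.counts() for r in rasters], axis=0)
    total = sum(r.duration_s for r in rasters)
    keep = counts / total <= max_rate_hz
    if not np.any(keep):
        warnings.warn("all neurons masked as outliers; downstream detection is empty")
    return keep


def apply_neuron_mask(raster: Raster, keep: np.ndarray) -> Raster:
    times = [t if keep[j] else np.empty(0) for j, t in enumerate(raster.spike_times)]
    return Raster(times, raster.duration_s)


def _active_neurons(raster: Raster, t0: float, t1: float) -> int:
    return sum(
        1 for t in raster.spike_times if t.size and np.any((t >= t0) & (t <= t1))
    )


def detect_events(
    raster: Raster,
    snippet_ms: float = 15.0,
    mode: str = "consecutive_snippets",
    channel: str = "",
) -> list[HFOEvent]:
    """Ensemble detection on the pooled raster (see module docstring).

    Event boundaries are the first and last pooled spike time inside the
    merged detection.
    """
    if mode not in DETECT_MODES:
        raise ValueError(f"mode must be one of {DETECT_MODES}")
    pooled = raster.pooled_times()
    if pooled.size == 0:
        return []
    w = snippet_ms * 1e-3
    bins = np.floor(pooled / w).astype(np.int64)
    nonempty = np.unique(bins)

    # group non-empty snippets into runs of consecutive bins
    run_starts = np.flatnonzero(np.concatenate(([True], np.diff(nonempty) > 1)))
    run_bounds = list(zip(run_starts, np.append(run_starts[1:], nonempty.size)))
    detections = []
    for a, b in run_bounds:
        run = nonempty[a:b]
        if mode == "consecutive_snippets" and run.size < 2:
            continue
        in_run = (bins >= run[0]) & (bins <= run[-1])
        detections.append((pooled[in_run][0], pooled[in_run][-1]))

    # aggregate detections separated by less than one snippet
    merged: list[list[float]] = []
    for t0, t1 in detections:
        if merged and t0 - merged[-1][1] < w:
            merged[-1][1] = t1
        else:
            merged.append([t0, t1])
    return [
        HFOEvent(t0, t1, channel=channel, n_neurons_active=_active_neurons(raster, t0, t1))
        for t0, t1 in merged
    ]


def hfo_rate(events: list[HFOEvent], duration_s: float) -> float:
    """Events per minute over the interval."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * len(events) / duration_s


def events_to_frame(events: list[HFOEvent], interval_id: str | None = None) -> pd.DataFrame:
    """Events as an annotation table matching the synthetic truth schema."""
    rows = [
        {
            "onset_s": e.t_start,
            "duration_s": e.t_end - e.t_start,
            "channel": e.channel,
            "type": "hfo",
            "n_neurons_active": e.n_neurons_active,
        }
        for e in events
    ]
    frame = pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "channel", "type", "n_neurons_active"]
    )
    if interval_id is not None:
        frame["interval_id"] = interval_id
    return frame


def rates_by_night(vectors: list[HFOVector]) -> pd.DataFrame:
    """Per-channel mean rate and standard error within each night.

    SE = sd / sqrt(n) over the intervals of the night (0 for a single
    interval), the error-bar convention for within-night variability.
    """
    if not vectors:
        raise ValueError("need at least one interval")
    rows = []
    for v in vectors:
        for ch, rate in zip(v.channels, v.rates):
            rows.append({"night_id": v.night_id, "channel": ch, "rate": rate})
    df = pd.DataFrame(rows)
    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    out = (
        df.groupby(["night_id", "channel"], dropna=False)["rate"]
        .agg(mean="mean", se=_se, n_intervals="size")
        .reset_index()
    )
    return out
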