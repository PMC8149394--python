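"""Patient-level statistics: test-retest reliability, HFO area, outcome.

The per-interval HFO-rate vectors are aggregated into (i) a test-retest
reliability score — the mean normalised scalar product (cosine) over all
interval pairs, ~1 when the spatial distribution of rates persists;
(ii) the "HFO area" — the channels whose average rate exceeds the 95th
percentile of the patient's own rate distribution; and (iii) a
patient-level prediction label comparing the HFO area with the resected
channel set against the ILAE seizure outcome (class 1 = seizure free):

    area inside resection, ILAE 1  -> TN     (resection covered the
    area outside resection, ILAE>1 -> TP      presumed epileptogenic
    area inside resection, ILAE>1  -> FN      tissue and the patient
    area outside resection, ILAE 1 -> FP      became seizure free, etc.)

Group metrics (specificity, sensitivity, NPV, PPV, accuracy) follow the
standard confusion-matrix formulas; a zero denominator yields NaN, which
formatting renders as "—".  An empty HFO area is vacuously "inside" any
resection; callers can flag this case via ``area_is_empty``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .detect import HFOVector

UNDEFINED = float("nan")
LABELS = ("TN", "TP", "FN", "FP")


@dataclass
class PatientRecord:
    """Everything the clinical layer needs about one patient."""

    patient_id: str
    hfo_vectors: list[HFOVector]
    resected_channels: set[str]
    ilae_outcome: int

    def __post_init__(self) -> None:
        if self.ilae_outcome < 1:
            raise ValueError("ILAE outcome classes start at 1")
        channel_sets = {tuple(v.channels) for v in self.hfo_vectors}
        if len(channel_sets) > 1:
            raise ValueError("all HFO vectors of a patient must share the channel set")

    @property
    def n_intervals(self) -> int:
        return len(self.hfo_vectors)

    @property
    def channels(self) -> list[str]:
        return list(self.hfo_vectors[0].channels) if self.hfo_vectors else []

    @property
    def seizure_free(self) -> bool:
        return self.ilae_outcome == 1


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.905 -> 0.91), unlike banker's rounding."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def test_retest(vectors: list[HFOVector], aggregate: str = "mean") -> float:
    """Mean pairwise cosine of the per-interval HFO-rate vectors.

    Each vector is scaled to unit Euclidean norm, so the score is
    invariant to overall rate changes and reflects only the *spatial*
    distribution over channels.  Pairs involving an all-zero vector
    contribute 0.  Returns NaN for fewer than two intervals (undefined).
    """
    if len(vectors) < 2:
        return UNDEFINED
    mat = np.stack([v.rates for v in vectors])
    norms = np.linalg.norm(mat, axis=1)
    unit = np.divide(mat, norms[:, None], out=np.zeros_like(mat), where=norms[:, None] > 0)
    gram = unit @ unit.T
    scores = gram[np.triu_indices(len(vectors), k=1)]
    if aggregate == "mean":
        return float(scores.mean())
    if aggregate == "median":
        return float(np.median(scores))
    raise ValueError("aggregate must be 'mean' or 'median'")


def hfo_area(vectors: list[HFOVector], percentile: float = 95.0) -> set[str]:
    """Channels whose average rate strictly exceeds the rate percentile.

    The percentile (linear interpolation between order statistics) is
    taken over the patient's own per-channel average rates, so at most a
    few channels qualify and a flat (or silent) rate map yields an empty
    area.
    """
    if not vectors:
        raise ValueError("need at least one interval")
    mean_rates = np.mean([v.rates for v in vectors], axis=0)
    threshold = np.percentile(mean_rates, percentile)
    channels = vectors[0].channels
    return {ch for ch, r in zip(channels, mean_rates) if r > threshold}


def classify_patient(
    area: set[str],
    resected_channels: set[str],
    ilae_outcome: int,
    all_channels: set[str] | None = None,
) -> str:
    """TN/TP/FN/FP label from area-in-resection vs seizure freedom.

    An empty area is treated as fully inside the resection (the subset
    relation holds vacuously).
    """
    if all_channels is not None:
        unknown = (set(area) | set(resected_channels)) - set(all_channels)
        if unknown:
            raise ValueError(f"unknown channel labels: {sorted(unknown)}")
    if ilae_outcome < 1:
        raise ValueError("ILAE outcome classes start at 1")
    inside = set(area) <= set(resected_channels)
    seizure_free = ilae_outcome == 1
    if inside and seizure_free:
        return "TN"
    if not inside and not seizure_free:
        return "TP"
    if inside and not seizure_free:
        return "FN"
    return "FP"


def cohort_metrics(labels: list[str]) -> dict[str, float]:
    """Confusion-matrix metrics in percent over patient-level labels.

    specificity = TN/(TN+FP), sensitivity = TP/(TP+FN), NPV = TN/(TN+FN),
    PPV = TP/(TP+FP), accuracy = (TP+TN)/N.  Zero denominators give NaN.
    """
    if not labels:
        raise ValueError("need at least one patient label")
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    n = {lab: labels.count(lab) for lab in LABELS}
    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else UNDEFINED
    return {
        "specificity": ratio(n["TN"], n["TN"] + n["FP"]),
        "sensitivity": ratio(n["TP"], n["TP"] + n["FN"]),
        "npv": ratio(n["TN"], n["TN"] + n["FN"]),
        "ppv": ratio(n["TP"], n["TP"] + n["FP"]),
        "accuracy": ratio(n["TP"] + n["TN"], len(labels)),
    }


def evaluate_patient(record: PatientRecord, percentile: float = 95.0) -> dict:
    """All patient-level outputs in one pass (row of a cohort report)."""
    area = hfo_area(record.hfo_vectors, percentile=percentile)
    label = classify_patient(
        area, record.resected_channels, record.ilae_outcome,
        all_channels=set(record.channels),
    )
    return {
        "patient": record.patient_id,
        "n_intervals": record.n_intervals,
        "test_retest": test_retest(record.hfo_vectors),
        "hfo_area": ",".join(sorted(area)),
        "area_is_empty": len(area) == 0,
        "ilae_outcome": record.ilae_outcome,
        "prediction": label,
    }


def load_published_cohort() -> pd.DataFrame:
    """Published per-patient study table shipped as fixture data.

    Columns: patient, histology, n_intervals, test_retest (NaN where the
    single-interval patient has no defined score), ilae_outcome,
    followup_months, morphology_label, snn_label.
    """
    ref = importlib.resources.files("hfosnn.data") / "published_cohort.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
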