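"""MEP preselection: peak gate, artifact-window removal, normalization.

A raw 2000-sample window is assumed to contain an MEP when its rectified
post-cutoff segment shows between 1 and 10 peaks whose prominence exceeds
twice the segment's standard deviation.  Accepted windows lose their first
350 samples (the 17.5 ms stimulation-artifact train) and are then divided,
per patient, by the largest absolute sample over all of that patient's
accepted traces, so each patient's strongest MEP peaks at exactly 1.

Everything in this module is deterministic.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks

from .synthetic import CUTOFF_MS, DEFAULT_SAMPLING_RATE, MuscleClass, RawTrace

logger = logging.getLogger(__name__)

#: gate bounds: a window is an MEP iff 1 <= number of qualifying peaks <= 10
MIN_PEAKS = 1
MAX_PEAKS = 10
#: prominence threshold in units of the post-cutoff rectified SD
PROMINENCE_SDS = 2.0


@dataclass(frozen=True)
class Peak:
    """A qualifying local maximum of the rectified trace.

    ``index`` is 0-based on the full 2000-sample window; ``time_ms`` is the
    stimulus-relative latency (index / 20 at 20 kHz).  For plateaus the
    leftmost plateau sample is reported.
    """

    index: int
    time_ms: float
    prominence: float


@dataclass
class PreselectedTrace:
    """An accepted, cutoff-trimmed trace (1650 samples at defaults)."""

    samples: np.ndarray
    muscle: MuscleClass
    patient_id: int
    trace_id: str
    peaks: Tuple[Peak, ...]
    accepted: bool = True
    normalized: bool = False
    truth_has_mep: Optional[bool] = None


@dataclass(frozen=True)
class Rejection:
    """Why a raw window failed the MEP gate."""

    trace_id: str
    patient_id: int
    muscle: MuscleClass
    reason: str  # "no_peaks" | "too_many_peaks"
    n_peaks: int


def detect_peaks(
    trace: Union[RawTrace, np.ndarray, Sequence[float]],
    cutoff_ms: float = CUTOFF_MS,
    prominence_sds: float = PROMINENCE_SDS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> List[Peak]:
    """Detect qualifying peaks on the rectified signal at/after the cutoff.

    The prominence threshold is ``prominence_sds`` times the standard
    deviation of the rectified post-cutoff samples of this same trace; a
    constant post-cutoff segment therefore yields no peaks.  Peaks of either
    polarity count because detection runs on ``|x|``.
    """
    x = np.asarray(trace.samples if isinstance(trace, RawTrace) else trace, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("detect_peaks expects a non-empty 1-D trace")
    if not (0.0 <= cutoff_ms < x.size / sampling_rate * 1000.0):
        raise ValueError("cutoff_ms must lie inside the trace window")
    cutoff_idx = int(np.ceil(cutoff_ms * sampling_rate / 1000.0))

    rect = np.abs(x)
    sd = float(np.std(rect[cutoff_idx:]))
    if sd == 0.0:
        return []
    threshold = prominence_sds * sd

    # plateau_size reports left edges -> leftmost-sample plateau convention;
    # prominence=0 makes scipy return prominences for every local maximum so
    # the strict ">" comparison stays ours.
    idx, props = find_peaks(rect, prominence=0.0, plateau_size=(1, None))
    left = props["left_edges"]
    prom = props["prominences"]
    keep = (left >= cutoff_idx) & (prom > threshold)
    return [
        Peak(index=int(i), time_ms=float(i) / sampling_rate * 1000.0,
             prominence=float(p))
        for i, p in zip(left[keep], prom[keep])
    ]


def preselect_trace(
    trace: RawTrace,
    cutoff_ms: float = CUTOFF_MS,
    prominence_sds: float = PROMINENCE_SDS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    expected_length: int = 2000,
    min_peaks: int = MIN_PEAKS,
    max_peaks: int = MAX_PEAKS,
) -> Union[PreselectedTrace, Rejection]:
    """Apply the MEP gate to one raw window.

    Accepted traces are returned with the first ``cutoff`` samples removed
    (1650 retained at defaults) and with their peak list (full-window
    indices).  Rejected traces come back as a :class:`Rejection` carrying
    the reason.
    """
    if len(trace.samples) != expected_length:
        raise ValueError(
            f"trace {trace.trace_id}: expected {expected_length} samples, "
            f"got {len(trace.samples)}"
        )
    peaks = detect_peaks(trace, cutoff_ms, prominence_sds, sampling_rate)
    if len(peaks) < min_peaks:
        return Rejection(trace.trace_id, trace.patient_id, trace.muscle,
                         "no_peaks", len(peaks))
    if len(peaks) > max_peaks:
        return Rejection(trace.trace_id, trace.patient_id, trace.muscle,
                         "too_many_peaks", len(peaks))
    cutoff_idx = int(np.ceil(cutoff_ms * sampling_rate / 1000.0))
    return PreselectedTrace(
        samples=np.array(trace.samples[cutoff_idx:], dtype=float),
        muscle=trace.muscle,
        patient_id=trace.patient_id,
        trace_id=trace.trace_id,
        peaks=tuple(peaks),
        accepted=True,
        truth_has_mep=trace.truth_has_mep,
    )


def normalize_patient(traces: Sequence[PreselectedTrace]) -> List[PreselectedTrace]:
    """Divide one patient's accepted traces by the patient's peak value.

    The denominator is the maximum absolute sample over all of the patient's
    accepted traces (across muscles); after normalization that maximum is
    exactly 1.  Labels and peak indices are unchanged; peak prominences are
    rescaled consistently.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("normalize_patient: no traces given")
    pids = {t.patient_id for t in traces}
    if len(pids) != 1:
        raise ValueError(f"normalize_patient: mixed patient ids {sorted(pids)}")
    denom = max(float(np.max(np.abs(t.samples))) for t in traces)
    if denom == 0.0:
        raise ValueError(
            f"patient {traces[0].patient_id}: all-zero traces, cannot normalize"
        )
    out = []
    for t in traces:
        out.append(replace(
            t,
            samples=t.samples / denom,
            peaks=tuple(replace(p, prominence=p.prominence / denom) for p in t.peaks),
            normalized=True,
        ))
    return out


def preselect_cohort(
    traces: Iterable[RawTrace],
    cutoff_ms: float = CUTOFF_MS,
    prominence_sds: float = PROMINENCE_SDS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    expected_length: int = 2000,
    normalize: bool = True,
) -> Tuple[List[PreselectedTrace], List[Rejection]]:
    """Gate every window, then normalize per patient over accepted traces."""
    by_patient: Dict[int, List[PreselectedTrace]] = defaultdict(list)
    rejections: List[Rejection] = []
    order: List[str] = []
    for tr in traces:
        res = preselect_trace(tr, cutoff_ms, prominence_sds, sampling_rate,
                              expected_length)
        if isinstance(res, Rejection):
            rejections.append(res)
        else:
            by_patient[res.patient_id].append(res)
            order.append(res.trace_id)
    accepted: Dict[str, PreselectedTrace] = {}
    for pid, plist in by_patient.items():
        normed = normalize_patient(plist) if normalize else plist
        for t in normed:
            accepted[t.trace_id] = t
    logger.info("preselection: %d accepted, %d rejected",
                len(accepted), len(rejections))
    return [accepted[tid] for tid in order], rejections
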