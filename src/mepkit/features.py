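"""Engineered MEP features and PCA compression.

The seven-dimensional feature representation of a preselected trace:

====================  =====================================================
onset_latency_ms      first departure from the baseline noise band
peak_latency_ms       latency of the first detected peak (stimulus-relative)
end_of_signal_ms      onset latency of the time-reversed trace, mapped back
maximum               largest sample (normalized units)
minimum               smallest sample (normalized units)
auc                   trapezoidal integral of |x| (normalized units x ms)
n_peaks               number of qualifying peaks (gate definition)
====================  =====================================================

Onset detection follows the threshold-crossing rule: the baseline mean is
taken over the last 20 ms of the window (assumed quiet) and the crossing
threshold is two standard deviations of the whole trace; the onset is the
first post-cutoff sample deviating from the baseline mean by more than that.
Undefined crossings are imputed (onset -> cutoff, end -> window end) so the
feature matrix stays rectangular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.decomposition import PCA

from . import preprocess
from .synthetic import CUTOFF_MS, DEFAULT_SAMPLING_RATE, DEFAULT_WINDOW_MS, MuscleClass

logger = logging.getLogger(__name__)

#: canonical column order of the engineered representation
FEATURE_NAMES = (
    "onset_latency_ms",
    "peak_latency_ms",
    "end_of_signal_ms",
    "maximum",
    "minimum",
    "auc",
    "n_peaks",
)

BASELINE_MS = 20.0
ONSET_SDS = 2.0


@dataclass(frozen=True)
class FeatureVector:
    """The 7 engineered features of one trace, plus its labels."""

    onset_latency_ms: float
    peak_latency_ms: float
    end_of_signal_ms: float
    maximum: float
    minimum: float
    auc: float
    n_peaks: int
    muscle: Optional[MuscleClass] = None
    patient_id: Optional[int] = None
    trace_id: Optional[str] = None

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def onset_latency(
    samples: Sequence[float],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = 0.0,
    cutoff_ms: float = CUTOFF_MS,
    baseline_ms: float = BASELINE_MS,
    n_sds: float = ONSET_SDS,
) -> Optional[float]:
    """Stimulus-relative onset latency in ms, or ``None`` if no crossing.

    ``t_start_ms`` is the absolute time of the first sample (0 for a raw
    window, 17.5 for a cutoff-trimmed trace).  Baseline mean over the final
    ``baseline_ms``; threshold ``n_sds`` times the whole-trace SD, so adding
    a constant offset leaves the result unchanged.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("onset_latency expects a non-empty 1-D trace")
    window_ms = x.size / sampling_rate * 1000.0
    if window_ms < baseline_ms:
        raise ValueError(
            f"trace spans {window_ms:.1f} ms; need >= {baseline_ms} ms for a baseline"
        )
    n_base = int(round(baseline_ms * sampling_rate / 1000.0))
    mu = float(np.mean(x[-n_base:]))
    sigma = float(np.std(x))
    start = max(0, int(np.ceil((cutoff_ms - t_start_ms) * sampling_rate / 1000.0)))
    if start >= x.size:
        return None
    crossing = np.abs(x[start:] - mu) > n_sds * sigma
    hits = np.flatnonzero(crossing)
    if hits.size == 0:
        return None
    return t_start_ms + (start + int(hits[0])) / sampling_rate * 1000.0


def end_of_signal(
    samples: Sequence[float],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = 0.0,
    baseline_ms: float = BASELINE_MS,
    n_sds: float = ONSET_SDS,
) -> Optional[float]:
    """Latency (ms) of the last departure from baseline: the onset of the
    time-reversed trace mapped back to forward time."""
    x = np.asarray(samples, dtype=float)
    rev = x[::-1]
    # scanning the reversed trace from its own start; no cutoff applies there
    res = onset_latency(rev, sampling_rate, t_start_ms=0.0, cutoff_ms=0.0,
                        baseline_ms=baseline_ms, n_sds=n_sds)
    if res is None:
        return None
    j = int(round(res * sampling_rate / 1000.0))
    return t_start_ms + (x.size - 1 - j) / sampling_rate * 1000.0


def peak_amplitude(samples: Sequence[float]) -> float:
    """Peak-to-peak amplitude: max minus min (always >= 0)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("peak_amplitude: empty trace")
    return float(np.max(x) - np.min(x))


def rectified_auc(samples: Sequence[float],
                  sampling_rate: float = DEFAULT_SAMPLING_RATE) -> float:
    """Trapezoidal integral of |x| in normalized units x ms."""
    x = np.abs(np.asarray(samples, dtype=float))
    return float(np.trapezoid(x, dx=1000.0 / sampling_rate))


def segment_peaks(
    samples: Sequence[float],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = CUTOFF_MS,
    prominence_sds: float = preprocess.PROMINENCE_SDS,
) -> List[preprocess.Peak]:
    """Peak detection on an already-trimmed (post-cutoff) segment.

    Mirrors :func:`mepkit.preprocess.detect_peaks` but allows a maximum on
    the very first sample by padding one zero on the left (relevant for
    bursts whose first extremum sits exactly at the cutoff, and for SMOTE
    interpolations of such traces).  Reported indices/latencies are absolute
    (full-window) like those stored during preselection.
    """
    x = np.asarray(samples, dtype=float)
    padded = np.concatenate([[0.0], x])
    cutoff_idx = int(round(t_start_ms * sampling_rate / 1000.0))
    raw_peaks = preprocess.detect_peaks(
        padded, cutoff_ms=1000.0 / sampling_rate,  # exclude only the pad sample
        prominence_sds=prominence_sds, sampling_rate=sampling_rate,
    )
    # threshold SD must come from the unpadded segment; recompute and filter
    sd = float(np.std(np.abs(x)))
    if sd == 0.0:
        return []
    thresh = prominence_sds * sd
    out = []
    for p in raw_peaks:
        if p.prominence > thresh:
            idx = p.index - 1 + cutoff_idx
            out.append(preprocess.Peak(
                index=idx, time_ms=idx / sampling_rate * 1000.0,
                prominence=p.prominence,
            ))
    return out


def extract_features(
    trace: Union[preprocess.PreselectedTrace, Sequence[float]],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = CUTOFF_MS,
    window_end_ms: Optional[float] = None,
) -> FeatureVector:
    """Compute the 7-feature representation of one preselected trace.

    Accepts either a :class:`PreselectedTrace` (whose stored peak list is
    reused) or a bare post-cutoff sample array (peaks recomputed, as needed
    for SMOTE-interpolated signals).  Undefined onset/end latencies are
    imputed to the cutoff and the window end respectively.
    """
    if isinstance(trace, preprocess.PreselectedTrace):
        x = np.asarray(trace.samples, dtype=float)
        peaks = list(trace.peaks)
        muscle, pid, tid = trace.muscle, trace.patient_id, trace.trace_id
    else:
        x = np.asarray(trace, dtype=float)
        peaks = None
        muscle = pid = tid = None
    if peaks is None or not peaks:
        peaks = segment_peaks(x, sampling_rate, t_start_ms)
    if window_end_ms is None:
        window_end_ms = t_start_ms + x.size / sampling_rate * 1000.0

    onset = onset_latency(x, sampling_rate, t_start_ms=t_start_ms,
                          cutoff_ms=t_start_ms)
    end = end_of_signal(x, sampling_rate, t_start_ms=t_start_ms)
    if onset is None:
        logger.debug("trace %s: no onset crossing, imputing cutoff", tid)
        onset = t_start_ms
    if end is None:
        logger.debug("trace %s: no end crossing, imputing window end", tid)
        end = window_end_ms
    peak_lat = peaks[0].time_ms if peaks else t_start_ms

    return FeatureVector(
        onset_latency_ms=float(onset),
        peak_latency_ms=float(peak_lat),
        end_of_signal_ms=float(end),
        maximum=float(np.max(x)),
        minimum=float(np.min(x)),
        auc=rectified_auc(x, sampling_rate),
        n_peaks=len(peaks),
        muscle=muscle,
        patient_id=pid,
        trace_id=tid,
    )


def feature_matrix(
    traces: Sequence[preprocess.PreselectedTrace],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = CUTOFF_MS,
) -> np.ndarray:
    """Stack feature vectors into an (n_traces, 7) matrix in FEATURE_NAMES order."""
    return np.vstack([
        extract_features(t, sampling_rate, t_start_ms).to_array() for t in traces
    ])


# ---------------------------------------------------------------------------
# PCA at 95% explained variance
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """A fitted PCA compressor retaining >= 95% of training variance."""

    components: np.ndarray  # (k, d)
    explained_variance_ratio: np.ndarray  # (k,)
    mean: np.ndarray  # (d,)
    n_components: int

    @property
    def cumulative_explained_variance(self) -> float:
        return float(np.sum(self.explained_variance_ratio))


def fit_pca(train: np.ndarray, variance: float = 0.95) -> PcaModel:
    """Fit PCA on training rows only, keeping the smallest number of
    components whose cumulative explained variance reaches ``variance``."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with >= 2 rows")
    if float(np.var(X, axis=0).sum()) == 0.0:
        logger.warning("fit_pca: zero-variance matrix, model has 0 components")
        return PcaModel(
            components=np.zeros((0, X.shape[1])),
            explained_variance_ratio=np.zeros(0),
            mean=X.mean(axis=0),
            n_components=0,
        )
    pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(X)
    return PcaModel(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        n_components=int(pca.n_components_),
    )


def apply_pca(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Mean-centered projection of ``X`` onto the retained components."""
    if model.n_components == 0:
        raise ValueError("cannot transform with a 0-component PCA model")
    X = np.asarray(X, dtype=float)
    return (X - model.mean) @ model.components.T
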