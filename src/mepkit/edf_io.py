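"""Cohort archives: EDF signal store + delimited-text manifest and tables.

A cohort archive is a directory holding

* ``signals.edf`` — one EDF channel per (patient, muscle) pair, with each
  100 ms sweep stored as one data record (2000 samples per record at
  20 kHz).  Channels with fewer sweeps than the longest one are zero-padded;
  the manifest says which records are real.
* ``manifest.tsv`` — one row per trace: trace_id, patient_id, muscle,
  truth_has_mep, channel index and record index into the EDF.

EDF is written and parsed here directly (16-bit integer EDF with ASCII
headers) because no EDF library is available in the runtime environment;
only the subset needed for this layout is implemented.  Samples survive a
round trip up to the 16-bit amplitude quantization of the per-channel
physical range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .synthetic import ConfigurationError, MuscleClass, RawTrace

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.tsv"
SIGNALS_NAME = "signals.edf"
_DIG_MAX = 32767


@dataclass(frozen=True)
class CohortArchive:
    """Paths and geometry of an exported cohort."""

    path: Path
    n_channels: int
    n_records: int
    samples_per_record: int
    sampling_rate: float

    @property
    def edf_path(self) -> Path:
        return self.path / SIGNALS_NAME

    @property
    def manifest_path(self) -> Path:
        return self.path / MANIFEST_NAME


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _phys_bound(maxabs: float) -> float:
    # smallest 3-decimal bound >= maxabs that still fits an 8-char field
    if maxabs <= 0 or not math.isfinite(maxabs):
        return 1.0
    return math.ceil(maxabs * 1000.0 + 1) / 1000.0


def write_edf(
    path: Path,
    channels: Sequence[Tuple[str, np.ndarray]],
    samples_per_record: int,
    record_duration_s: float,
) -> None:
    """Write a minimal 16-bit EDF file.

    ``channels`` maps label -> 2-D array (n_records, samples_per_record);
    all channels must share the record grid.
    """
    n_records = channels[0][1].shape[0]
    ns = len(channels)
    header = b""
    header += _ascii_field(0, 8)  # version
    header += _ascii_field("X", 80)  # local patient id (anonymous)
    header += _ascii_field("mepkit cohort", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (ns + 1), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(f"{record_duration_s:g}", 8)
    header += _ascii_field(ns, 4)

    phys_bounds = []
    for label, data in channels:
        maxabs = float(np.max(np.abs(data))) if data.size else 0.0
        phys_bounds.append(_phys_bound(maxabs))

    for (label, _), pb in zip(channels, phys_bounds):
        header += _ascii_field(label, 16)
    for _ in channels:
        header += _ascii_field("intramuscular EMG", 80)
    for _ in channels:
        header += _ascii_field("mV", 8)
    for pb in phys_bounds:
        header += _ascii_field(f"{-pb:.3f}", 8)
    for pb in phys_bounds:
        header += _ascii_field(f"{pb:.3f}", 8)
    for _ in channels:
        header += _ascii_field(-_DIG_MAX, 8)
    for _ in channels:
        header += _ascii_field(_DIG_MAX, 8)
    for _ in channels:
        header += _ascii_field("", 80)
    for _ in channels:
        header += _ascii_field(samples_per_record, 8)
    for _ in channels:
        header += _ascii_field("", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for (label, data), pb in zip(channels, phys_bounds):
                digital = np.clip(
                    np.round(data[r] / pb * _DIG_MAX), -_DIG_MAX, _DIG_MAX
                ).astype("<i2")
                fh.write(digital.tobytes())


def read_edf(path: Path) -> Tuple[List[str], np.ndarray, float, int]:
    """Read a 16-bit EDF file written in the one-sweep-per-record layout.

    Returns (labels, data[n_channels, n_records, samples_per_record],
    sampling_rate, n_records).  All channels must share one sample rate.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode("ascii"))
        duration = float(head[244:252].decode("ascii"))
        ns = int(head[252:256].decode("ascii"))
        sig = fh.read(256 * ns)
        labels = [sig[16 * i: 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        phys_min = [float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        if len(set(spr)) != 1:
            raise ValueError("mixed samples-per-record EDF layouts are not supported")
        n_per = spr[0]
        raw = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * ns * n_per
    if raw.size < expected:
        raise ValueError("EDF data section truncated")
    raw = raw[:expected].reshape(n_records, ns, n_per)
    data = np.empty((ns, n_records, n_per))
    for i in range(ns):
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (raw[:, i, :].astype(float) - dig_min[i]) * scale + phys_min[i]
    return labels, data, n_per / duration, n_records


# ---------------------------------------------------------------------------
# cohort-level export / import
# ---------------------------------------------------------------------------

def export_cohort(traces: Sequence[RawTrace], path,
                  sampling_rate: float = 20_000.0) -> CohortArchive:
    """Write raw traces to an EDF + manifest archive (round-trippable)."""
    traces = list(traces)
    if not traces:
        raise ValueError("export_cohort: no traces to export")
    lengths = {len(t.samples) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces of mixed lengths {sorted(lengths)} cannot share an archive")
    n_per = lengths.pop()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    keys: List[Tuple[int, str]] = []
    grouped: Dict[Tuple[int, str], List[RawTrace]] = {}
    for t in traces:
        k = (t.patient_id, t.muscle.value)
        if k not in grouped:
            grouped[k] = []
            keys.append(k)
        grouped[k].append(t)

    n_records = max(len(v) for v in grouped.values())
    channels = []
    rows = []
    for ch_idx, k in enumerate(keys):
        pid, muscle = k
        block = np.zeros((n_records, n_per))
        for rec_idx, t in enumerate(grouped[k]):
            block[rec_idx] = t.samples
            rows.append({
                "trace_id": t.trace_id,
                "patient_id": pid,
                "muscle": muscle,
                "truth_has_mep": "" if t.truth_has_mep is None else int(t.truth_has_mep),
                "channel": ch_idx,
                "record": rec_idx,
            })
        channels.append((f"P{pid:03d} {muscle}", block))

    write_edf(path / SIGNALS_NAME, channels, n_per, n_per / sampling_rate)
    pd.DataFrame(rows).to_csv(path / MANIFEST_NAME, sep="\t", index=False)
    logger.info("exported %d traces to %s (%d channels, %d records)",
                len(traces), path, len(channels), n_records)
    return CohortArchive(path=path, n_channels=len(channels),
                         n_records=n_records, samples_per_record=n_per,
                         sampling_rate=sampling_rate)


def import_cohort(path, window_ms: float = 100.0) -> List[RawTrace]:
    """Load an archive back into raw traces.

    Rows whose record index falls outside the EDF, or whose muscle label is
    unknown, are skipped with a warning rather than crashing the import.
    For non-20 kHz archives the expected window length is recomputed as
    ``window_ms`` x rate.
    """
    path = Path(path)
    manifest = path / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"archive {path} has no {MANIFEST_NAME}")
    labels, data, rate, n_records = read_edf(path / SIGNALS_NAME)
    expected_len = int(round(window_ms * rate / 1000.0))
    if expected_len != data.shape[2]:
        logger.warning(
            "archive %s: records hold %d samples but %g ms at %g Hz is %d",
            path, data.shape[2], window_ms, rate, expected_len)
    df = pd.read_csv(manifest, sep="\t")
    out: List[RawTrace] = []
    for row in df.itertuples(index=False):
        try:
            muscle = MuscleClass.from_label(row.muscle)
        except ConfigurationError:
            logger.warning("manifest row %s: unknown muscle %r, skipped",
                           row.trace_id, row.muscle)
            continue
        ch, rec = int(row.channel), int(row.record)
        if not (0 <= ch < data.shape[0]) or not (0 <= rec < n_records):
            logger.warning("manifest row %s: channel/record (%d, %d) outside "
                           "signal store, skipped", row.trace_id, ch, rec)
            continue
        truth = None
        if not pd.isna(row.truth_has_mep) and f"{row.truth_has_mep}" != "":
            truth = bool(int(row.truth_has_mep))
        out.append(RawTrace(samples=data[ch, rec], muscle=muscle,
                            patient_id=int(row.patient_id),
                            trace_id=str(row.trace_id), truth_has_mep=truth))
    logger.info("imported %d traces from %s", len(out), path)
    return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(vectors: Sequence[FeatureVector], path) -> None:
    """Delimited feature table: the 7 features plus labels, lossless at
    float repr precision."""
    if not vectors:
        raise ValueError("write_feature_table: no vectors")
    rows = []
    for v in vectors:
        row = {name: getattr(v, name) for name in FEATURE_NAMES}
        row["muscle"] = v.muscle.value if v.muscle is not None else ""
        row["patient_id"] = v.patient_id if v.patient_id is not None else ""
        row["trace_id"] = v.trace_id if v.trace_id is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> List[FeatureVector]:
    """Read a feature table, insisting on all 7 feature columns."""
    df = pd.read_csv(path, sep="\t")
    for name in FEATURE_NAMES:
        if name not in df.columns:
            raise ValueError(f"feature table {path} is missing column {name!r}")
    out = []
    for row in df.itertuples(index=False):
        muscle = None
        if isinstance(row.muscle, str) and row.muscle:
            muscle = MuscleClass.from_label(row.muscle)
        out.append(FeatureVector(
            onset_latency_ms=float(row.onset_latency_ms),
            peak_latency_ms=float(row.peak_latency_ms),
            end_of_signal_ms=float(row.end_of_signal_ms),
            maximum=float(row.maximum),
            minimum=float(row.minimum),
            auc=float(row.auc),
            n_peaks=int(row.n_peaks),
            muscle=muscle,
            patient_id=None if pd.isna(row.patient_id) else int(row.patient_id),
            trace_id=str(row.trace_id),
        ))
    return out
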