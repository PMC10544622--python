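"""Synthetic motor evoked potential (MEP) cohort generation.

Real intraoperative MEP recordings are patient data and generally not
shareable, so this module produces surrogate cohorts whose *post-preselection*
summary statistics (normalized peak-to-peak amplitude, first-peak latency,
number of detected peaks) are calibrated to the distributions reported for a
36-patient supratentorial-surgery cohort covering four routinely monitored
muscles: extensor digitorum (EXT), abductor pollicis brevis (APB), tibialis
anterior (TA) and abductor hallucis (AH).

Each trace is a 100 ms window sampled at 20 kHz (2000 samples) containing

* a train of five alternating-sign stimulation-artifact pulses, entirely
  before the 17.5 ms analysis cutoff (sample 350);
* with probability ``1 - blank_rate``, an MEP complex: one to three damped
  cosine bursts whose onset is drawn from a normal distribution truncated
  below at the 17.5 ms cutoff and whose peak-to-peak size is drawn from a
  lognormal distribution saturated (clipped) at ``amp_cap``, emulating the
  amplifier's finite recording range;
* additive white Gaussian baseline noise everywhere.

The burst uses cosine phase so that its first extremum falls exactly on the
onset sample: the empirical EXT first-peak latency mean (17.53 ms) sits
essentially at the cutoff, which no waveform with a slower rise can reach.
The whole trace is multiplied by a per-patient gain; because downstream
per-patient normalization divides by the patient's largest absolute sample,
the gain cancels exactly in all normalized statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: samples/s of the recording chain emulated by default
DEFAULT_SAMPLING_RATE = 20_000.0
#: analysis window length (ms); 2000 samples at 20 kHz
DEFAULT_WINDOW_MS = 100.0
#: stimulation-artifact cutoff (ms); the first 350 samples are discarded
CUTOFF_MS = 17.5


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


class Extremity(str, Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"


class MuscleClass(str, Enum):
    """The four monitored muscles and their limb assignment."""

    EXT = "EXT"  # extensor digitorum (forearm)
    APB = "APB"  # abductor pollicis brevis (thenar)
    TA = "TA"  # tibialis anterior (lower leg)
    AH = "AH"  # abductor hallucis (foot)

    @property
    def extremity(self) -> Extremity:
        if self in (MuscleClass.EXT, MuscleClass.APB):
            return Extremity.UPPER
        return Extremity.LOWER

    @classmethod
    def from_label(cls, label: str) -> "MuscleClass":
        try:
            return cls(str(label).strip().upper())
        except ValueError as exc:
            raise ConfigurationError(f"unknown muscle label: {label!r}") from exc


MUSCLES: tuple = (MuscleClass.EXT, MuscleClass.APB, MuscleClass.TA, MuscleClass.AH)


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle generative parameters.

    latency_mu_ms / latency_sigma_ms parameterize the *underlying* normal
    onset-latency distribution before truncation to
    ``[cutoff_ms, latency_max_ms]``; the defaults are solved numerically so
    that the mean of the sample-quantized truncated distribution equals the
    target first-peak latency.  Peak-to-peak amplitude is drawn as
    ``min(LogNormal(log(amp_median), amp_sigma_log), amp_cap)``; the cap
    emulates amplifier saturation and pins the per-patient normalization
    denominator (each patient's largest MEP sits at the cap with high
    probability), which is what makes the *normalized* amplitude means
    calibratable at all.
    """

    latency_mu_ms: float
    latency_sigma_ms: float
    amp_median: float
    amp_sigma_log: float
    amp_cap: float
    n_burst_pmf: Mapping[int, float]
    blank_rate: float
    traces_per_patient: int
    burst_freq_hz: float
    burst_tau_ms: float

    def validate(self, name: str) -> None:
        if self.latency_sigma_ms <= 0 or self.amp_sigma_log < 0:
            raise ConfigurationError(f"{name}: SDs must be positive")
        if not (0.0 <= self.blank_rate <= 1.0):
            raise ConfigurationError(f"{name}: blank_rate must lie in [0, 1]")
        if self.amp_cap <= 0 or self.amp_median <= 0:
            raise ConfigurationError(f"{name}: amplitude scale must be positive")
        if self.traces_per_patient < 0:
            raise ConfigurationError(f"{name}: traces_per_patient must be >= 0")
        if self.burst_freq_hz <= 0 or self.burst_tau_ms <= 0:
            raise ConfigurationError(f"{name}: burst shape parameters must be positive")
        pmf = dict(self.n_burst_pmf)
        if not pmf or any(k < 1 for k in pmf) or any(p < 0 for p in pmf.values()):
            raise ConfigurationError(f"{name}: invalid burst-count distribution")
        if abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"{name}: burst-count pmf must sum to 1")


# Defaults calibrated (see docs/methods.md) so that, after preselection and
# per-patient normalization of a default cohort, the per-muscle mean
# normalized amplitude, mean first-peak latency and median peak count
# reproduce the reference cohort statistics
# (amplitude 0.09/0.34/0.20/0.11; latency 17.53/20.01/24.69/31.03 ms;
# median peaks 1/2/2/2 for EXT/APB/TA/AH).
DEFAULT_MUSCLE_PARAMS: Dict[MuscleClass, MuscleParams] = {
    MuscleClass.EXT: MuscleParams(
        latency_mu_ms=-12.775507,
        latency_sigma_ms=1.0,
        amp_median=0.023458,
        amp_sigma_log=1.2,
        amp_cap=0.234582,
        n_burst_pmf={1: 0.80, 2: 0.15, 3: 0.05},
        blank_rate=0.25,
        traces_per_patient=112,
        burst_freq_hz=600.0,
        burst_tau_ms=0.28,
    ),
    MuscleClass.APB: MuscleParams(
        latency_mu_ms=17.810437,
        latency_sigma_ms=3.0,
        amp_median=0.100,
        amp_sigma_log=1.2,
        amp_cap=0.637719,
        n_burst_pmf={1: 0.55, 2: 0.30, 3: 0.15},
        blank_rate=0.29,
        traces_per_patient=136,
        burst_freq_hz=500.0,
        burst_tau_ms=0.72,
    ),
    MuscleClass.TA: MuscleParams(
        latency_mu_ms=23.634054,
        latency_sigma_ms=5.0,
        amp_median=0.055191,
        amp_sigma_log=1.2,
        amp_cap=0.551911,
        n_burst_pmf={1: 0.55, 2: 0.30, 3: 0.15},
        blank_rate=0.70,
        traces_per_patient=134,
        burst_freq_hz=400.0,
        burst_tau_ms=0.90,
    ),
    MuscleClass.AH: MuscleParams(
        latency_mu_ms=30.037111,
        latency_sigma_ms=8.0,
        amp_median=0.025382,
        amp_sigma_log=1.4,
        amp_cap=0.253818,
        n_burst_pmf={1: 0.55, 2: 0.30, 3: 0.15},
        blank_rate=0.79,
        traces_per_patient=112,
        burst_freq_hz=320.0,
        burst_tau_ms=1.13,
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort, including the seed.

    A config is a *stated world*: two cohorts generated from equal configs are
    byte-for-byte identical.
    """

    sampling_rate: float = DEFAULT_SAMPLING_RATE
    window_ms: float = DEFAULT_WINDOW_MS
    n_patients: int = 36
    muscles: Mapping[MuscleClass, MuscleParams] = field(
        default_factory=lambda: dict(DEFAULT_MUSCLE_PARAMS)
    )
    cutoff_ms: float = CUTOFF_MS
    latency_max_ms: float = 80.0
    artifact_n_pulses: int = 5
    artifact_start_ms: float = 2.0
    artifact_spacing_ms: float = 2.0
    artifact_amplitude: float = 3.0
    artifact_width_samples: int = 5
    noise_sd: float = 0.0001
    patient_scale_sigma: float = 0.4
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms * self.sampling_rate / 1000.0))

    @property
    def cutoff_index(self) -> int:
        return int(round(self.cutoff_ms * self.sampling_rate / 1000.0))

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.window_ms <= 0:
            raise ConfigurationError("window_ms must be positive")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not (0 <= self.cutoff_ms < self.window_ms):
            raise ConfigurationError("cutoff_ms must lie inside the window")
        if self.latency_max_ms <= self.cutoff_ms or self.latency_max_ms > self.window_ms:
            raise ConfigurationError("latency_max_ms must lie in (cutoff_ms, window_ms]")
        if self.noise_sd < 0 or self.patient_scale_sigma < 0:
            raise ConfigurationError("noise_sd and patient_scale_sigma must be >= 0")
        last_pulse_ms = (
            self.artifact_start_ms
            + (self.artifact_n_pulses - 1) * self.artifact_spacing_ms
            + self.artifact_width_samples / self.sampling_rate * 1000.0
        )
        if self.artifact_n_pulses > 0 and last_pulse_ms >= self.cutoff_ms:
            raise ConfigurationError(
                "stimulation-artifact train must end before the cutoff"
            )
        if not self.muscles:
            raise ConfigurationError("at least one muscle must be configured")
        for muscle, params in self.muscles.items():
            if not isinstance(muscle, MuscleClass):
                raise ConfigurationError(f"invalid muscle code: {muscle!r}")
            params.validate(muscle.value)

    def with_traces_per_patient(self, factor: float) -> "GeneratorConfig":
        """Scaled copy: per-muscle trace counts multiplied by ``factor``."""
        scaled = {
            m: replace(p, traces_per_patient=int(round(p.traces_per_patient * factor)))
            for m, p in self.muscles.items()
        }
        return replace(self, muscles=scaled)


@dataclass
class RawTrace:
    """One 100 ms recording window with its labels.

    ``truth_has_mep`` is the synthetic ground-truth flag; it is ``None`` for
    traces imported from real recordings.
    """

    samples: np.ndarray
    muscle: MuscleClass
    patient_id: int
    trace_id: str
    truth_has_mep: Optional[bool] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.trace_id}: non-finite samples")


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def burst_waveform(
    amplitude: float,
    freq_hz: float,
    tau_ms: float,
    sampling_rate: float,
    n_cycles_tail: float = 6.0,
) -> np.ndarray:
    """Sampled damped-cosine MEP burst with exact peak-to-peak ``amplitude``.

    The waveform is ``exp(-t/tau) * cos(2 pi f t)`` for ``t >= 0`` and is
    rescaled *after* sampling so that ``max - min`` over the sampled points
    equals ``amplitude`` exactly.  The first extremum is the first sample.
    """
    duration_ms = n_cycles_tail * tau_ms
    n = max(int(round(duration_ms * sampling_rate / 1000.0)), 2)
    t_ms = np.arange(n) / sampling_rate * 1000.0
    w = np.exp(-t_ms / tau_ms) * np.cos(2.0 * np.pi * freq_hz * t_ms / 1000.0)
    ptp = w.max() - w.min()
    return w * (amplitude / ptp)


def artifact_train(config: GeneratorConfig) -> np.ndarray:
    """The five-pulse stimulation-artifact template (full window length)."""
    out = np.zeros(config.n_samples)
    half = config.artifact_width_samples // 2
    shape = 1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1.0)
    for j in range(config.artifact_n_pulses):
        center = int(round(
            (config.artifact_start_ms + j * config.artifact_spacing_ms)
            * config.sampling_rate / 1000.0
        ))
        sign = 1.0 if j % 2 == 0 else -1.0
        lo = center - half
        hi = center + half + 1
        out[lo:hi] += sign * config.artifact_amplitude * shape[: hi - lo]
    return out


def _truncnorm_rvs(
    mu: float, sigma: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# trace / cohort generation
# ---------------------------------------------------------------------------

def generate_trace(
    muscle: MuscleClass,
    patient_gain: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    patient_id: int = 0,
    trace_id: str = "trace-0",
) -> RawTrace:
    """Draw one synthetic window for ``muscle`` from ``rng``.

    Blank windows (no MEP elicited) carry only the artifact train and
    baseline noise; non-blank windows add 1-3 damped-cosine bursts.
    """
    if not isinstance(muscle, MuscleClass):
        raise ConfigurationError(f"invalid muscle code: {muscle!r}")
    if config.sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    params = config.muscles.get(muscle)
    if params is None:
        raise ConfigurationError(f"muscle {muscle.value} not present in config")

    n = config.n_samples
    x = artifact_train(config)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=n)

    is_blank = bool(rng.random() < params.blank_rate)
    if not is_blank:
        ks = sorted(params.n_burst_pmf)
        probs = np.array([params.n_burst_pmf[k] for k in ks], dtype=float)
        n_bursts = int(rng.choice(ks, p=probs / probs.sum()))
        onset_ms = float(
            _truncnorm_rvs(
                params.latency_mu_ms, params.latency_sigma_ms,
                config.cutoff_ms, config.latency_max_ms, 1, rng,
            )[0]
        )
        amp = float(min(
            rng.lognormal(np.log(params.amp_median), params.amp_sigma_log),
            params.amp_cap,
        ))
        onsets = [onset_ms]
        amps = [amp]
        for _ in range(1, n_bursts):
            onsets.append(onsets[-1] + float(rng.uniform(2.0, 10.0)))
            amps.append(amp * float(rng.uniform(0.4, 0.9)))
        for o_ms, a in zip(onsets, amps):
            s0 = int(np.round(o_ms * config.sampling_rate / 1000.0))
            if s0 >= n:
                continue
            w = burst_waveform(a, params.burst_freq_hz, params.burst_tau_ms,
                              config.sampling_rate)
            hi = min(n, s0 + w.size)
            x[s0:hi] += w[: hi - s0]

    x *= patient_gain
    return RawTrace(
        samples=x,
        muscle=muscle,
        patient_id=patient_id,
        trace_id=trace_id,
        truth_has_mep=not is_blank,
    )


def generate_cohort(config: GeneratorConfig) -> List[RawTrace]:
    """Generate the full multi-patient cohort described by ``config``.

    Deterministic given ``config.seed``: each patient owns an independent
    child stream spawned from the root seed sequence, so per-patient data is
    reproducible in isolation.
    """
    config.validate()
    if config.n_patients < 2:
        raise ConfigurationError(
            "n_patients must be >= 2 (patient-wise splitting is impossible otherwise)"
        )
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)
    traces: List[RawTrace] = []
    for p_idx, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        gain = float(np.exp(rng.normal(0.0, config.patient_scale_sigma)))
        for muscle in MUSCLES:
            params = config.muscles.get(muscle)
            if params is None:
                continue
            for i in range(params.traces_per_patient):
                traces.append(
                    generate_trace(
                        muscle, gain, config, rng,
                        patient_id=p_idx,
                        trace_id=f"P{p_idx:03d}-{muscle.value}-{i:05d}",
                    )
                )
    logger.info("generated %d traces for %d patients", len(traces), config.n_patients)
    return traces


# ---------------------------------------------------------------------------
# cohort summary (Table-1-style statistics)
# ---------------------------------------------------------------------------

def summarize_cohort(traces: Sequence, sampling_rate: float = DEFAULT_SAMPLING_RATE,
                     t_start_ms: float = CUTOFF_MS) -> pd.DataFrame:
    """Per-muscle summary statistics of preselected, normalized traces.

    Returns a DataFrame indexed by muscle code with amplitude (max - min),
    first-peak latency (ms, stimulus-relative), peak count (median and SD)
    and rectified trapezoidal AUC (normalized units x ms).  Muscles with no
    traces are absent from the index rather than reported as zero.
    """
    from . import features as _features  # deferred: features depends on preprocess

    traces = list(traces)
    if not traces:
        raise ValueError("summarize_cohort: empty input")
    rows = []
    for tr in traces:
        peaks = getattr(tr, "peaks", None)
        fv = _features.extract_features(
            tr, sampling_rate=sampling_rate, t_start_ms=t_start_ms
        )
        rows.append({
            "muscle": tr.muscle.value,
            "amplitude": fv.maximum - fv.minimum,
            "peak_latency_ms": fv.peak_latency_ms,
            "n_peaks": fv.n_peaks,
            "auc": fv.auc,
        })
    df = pd.DataFrame(rows)
    out = df.groupby("muscle").agg(
        amplitude_mean=("amplitude", "mean"),
        amplitude_sd=("amplitude", "std"),
        peak_latency_mean_ms=("peak_latency_ms", "mean"),
        peak_latency_sd_ms=("peak_latency_ms", "std"),
        n_peaks_median=("n_peaks", "median"),
        n_peaks_sd=("n_peaks", "std"),
        auc_mean=("auc", "mean"),
        auc_sd=("auc", "std"),
        n_traces=("amplitude", "size"),
    )
    # single-trace groups: SD is 0 by convention, not NaN
    out = out.fillna({c: 0.0 for c in out.columns if c.endswith("_sd") or c.endswith("_sd_ms")})
    order = [m.value for m in MUSCLES if m.value in out.index]
    return out.loc[order]
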