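"""Shared fixtures: small synthetic cohorts and deterministic helpers."""

from dataclasses import replace

import numpy as np
import pytest

import mepkit
from mepkit.synthetic import DEFAULT_MUSCLE_PARAMS, GeneratorConfig, MuscleClass


def small_config(n_patients=6, traces_per_patient=12, seed=11, **kwargs):
    muscles = {m: replace(p, traces_per_patient=traces_per_patient)
               for m, p in DEFAULT_MUSCLE_PARAMS.items()}
    return GeneratorConfig(n_patients=n_patients, muscles=muscles, seed=seed,
                           **kwargs)


def noiseless_single_burst_config(onset_ms=30.0, amplitude=1.0, muscle=MuscleClass.APB,
                                  freq_hz=500.0, tau_ms=0.9):
    """One deterministic burst: no noise, no blanks, degenerate distributions."""
    p = DEFAULT_MUSCLE_PARAMS[muscle]
    params = replace(
        p,
        latency_mu_ms=onset_ms, latency_sigma_ms=1e-9,
        amp_median=amplitude, amp_sigma_log=0.0, amp_cap=10.0 * amplitude,
        n_burst_pmf={1: 1.0}, blank_rate=0.0,
        burst_freq_hz=freq_hz, burst_tau_ms=tau_ms,
    )
    return GeneratorConfig(muscles={muscle: params}, noise_sd=0.0,
                           patient_scale_sigma=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    return mepkit.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_preselected(small_cohort):
    accepted, rejections = mepkit.preselect_cohort(small_cohort)
    return accepted


def brute_force_peaks(x, cutoff_idx, threshold):
    """Independent oracle: enumerate local maxima (leftmost plateau sample)
    of the rectified trace and compute prominences from the definition."""
    rect = np.abs(np.asarray(x, dtype=float))
    n = rect.size
    peaks = []
    i = 1
    while i < n - 1:
        if rect[i] > rect[i - 1]:
            j = i
            while j + 1 < n and rect[j + 1] == rect[i]:
                j += 1
            if j + 1 < n and rect[j + 1] < rect[i]:
                peaks.append(i)  # leftmost sample of the plateau
                i = j + 1
                continue
        i += 1
    out = []
    for p in peaks:
        h = rect[p]
        lo = p
        while lo > 0 and rect[lo - 1] <= h:
            lo -= 1
        left_min = rect[lo:p + 1].min()
        hi = p
        while hi < n - 1 and rect[hi + 1] <= h:
            hi += 1
        right_min = rect[p:hi + 1].min()
        prom = h - max(left_min, right_min)
        if p >= cutoff_idx and prom > threshold:
            out.append((p, prom))
    return out
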