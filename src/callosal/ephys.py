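"""Extracellular spike/burst detection and EPSC train ratios.

Spike detection follows the MEA convention: the trace is zero-phase
high-pass filtered (default 100 Hz), the noise s.d. is estimated robustly
as MAD/0.6745 (insensitive to the spikes themselves), and a spike is scored
at the local minimum of every excursion below −k·sd (default k = 5.5);
crossings within the dead time are merged.  A burst is a maximal run of at
least ``min_spikes`` consecutive spikes whose inter-spike intervals are all
strictly below ``max_isi_s`` (defaults 5 and 50 ms).  Slice summaries report
the spike rate in Hz and burst rate per minute, averaged over active
electrodes; rate distributions are compared with the two-sample KS test.
For the patch-clamp train protocol (5 pulses at 20 Hz), per-pulse amplitudes
are normalised to the first EPSC and the EPSC5/EPSC1 ratio indexes
short-term depression (<1) or facilitation (>1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from . import stats
from .errors import ValidationError

__all__ = [
    "SpikeTrain",
    "BurstEvent",
    "EPSCTrain",
    "estimate_noise_sd",
    "highpass_filter",
    "detect_spikes",
    "detect_bursts",
    "activity_summary",
    "rate_distribution_compare",
    "epsc_train_metrics",
]


@dataclass
class SpikeTrain:
    electrode_id: str
    times_s: np.ndarray
    duration_s: float
    noise_sd: float = float("nan")

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        if self.times_s.size and (np.any(np.diff(self.times_s) <= 0)
                                  or self.times_s[0] < 0
                                  or self.times_s[-1] > self.duration_s):
            raise ValidationError("spike times must be strictly increasing within [0, duration]")

    @property
    def rate_hz(self) -> float:
        if self.duration_s <= 0:
            raise ValidationError("zero-duration train has no rate")
        return self.times_s.size / self.duration_s


@dataclass
class BurstEvent:
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class EPSCTrain:
    """Five EPSC amplitudes (positive magnitudes, pA) from a 20 Hz train."""

    cell_id: str
    amplitudes_pa: np.ndarray

    def __post_init__(self):
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float).ravel()
        if self.amplitudes_pa.size != 5:
            raise ValidationError("an EPSC train holds exactly 5 amplitudes")
        if self.amplitudes_pa[0] <= 0:
            raise ValidationError("first EPSC amplitude must be positive")


def estimate_noise_sd(trace: np.ndarray, sampling_hz: float | None = None) -> float:
    """Robust noise s.d.: median(|x − median(x)|)/0.6745.

    With ``sampling_hz`` given, at least 1 s of signal is required.
    A constant trace yields 0 with a warning.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if sampling_hz is not None and x.size < sampling_hz:
        raise ValidationError("need >=1 s of signal for a noise estimate")
    if x.size == 0:
        raise ValidationError("empty trace")
    mad = float(np.median(np.abs(x - np.median(x))))
    if mad == 0.0:
        warnings.warn("constant trace: noise sd estimated as 0", stacklevel=2)
        return 0.0
    return mad / 0.6745


def highpass_filter(trace: np.ndarray, sampling_hz: float, cutoff_hz: float = 100.0,
                    order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass conditioning before spike detection."""
    if cutoff_hz <= 0 or cutoff_hz >= sampling_hz / 2:
        raise ValidationError("cutoff must lie in (0, Nyquist)")
    sos = spsig.butter(order, cutoff_hz, btype="highpass", fs=sampling_hz, output="sos")
    return spsig.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def detect_spikes(trace: np.ndarray, sampling_hz: float, k: float = 5.5,
                  dead_time_s: float = 0.001, highpass_hz: float | None = 100.0,
                  electrode_id: str = "e0") -> SpikeTrain:
    """Negative-threshold spike detection at −k·(noise sd).

    The trace is high-pass conditioned (``highpass_hz=None`` disables),
    the noise sd estimated on the conditioned trace, and each excursion
    below the threshold yields one spike timed at its most negative sample;
    excursions starting within ``dead_time_s`` of the previous spike are
    merged.  Detection is invariant under global rescaling of the trace.
    """
    if k <= 0:
        raise ValidationError("threshold multiple k must be positive")
    if sampling_hz < 1000:
        raise ValidationError("sampling rate must be >=1 kHz")
    x = np.asarray(trace, dtype=float).ravel()
    duration = x.size / sampling_hz
    if x.size == 0:
        return SpikeTrain(electrode_id, np.array([]), 0.0, 0.0)
    if highpass_hz is not None:
        x = highpass_filter(x, sampling_hz, highpass_hz)
    sd = estimate_noise_sd(x)
    if sd == 0.0:
        return SpikeTrain(electrode_id, np.array([]), duration, 0.0)
    thr = -k * sd
    below = x < thr
    if not below.any():
        return SpikeTrain(electrode_id, np.array([]), duration, sd)
    edges = np.diff(below.astype(np.int8))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, below.size]
    dead = int(round(dead_time_s * sampling_hz))
    peaks = []
    for s0, e0 in zip(starts, ends):
        seg_peak = s0 + int(np.argmin(x[s0:e0]))
        if peaks and s0 - peaks[-1] <= dead:
            # merged into the previous event; keep the deeper minimum
            if x[seg_peak] < x[peaks[-1]]:
                peaks[-1] = seg_peak
            continue
        peaks.append(seg_peak)
    times = np.asarray(peaks, dtype=float) / sampling_hz
    return SpikeTrain(electrode_id, times, duration, sd)


def detect_bursts(train: SpikeTrain, min_spikes: int = 5,
                  max_isi_s: float = 0.050) -> list[BurstEvent]:
    """Maximal runs of >= ``min_spikes`` consecutive spikes with all ISIs
    strictly below ``max_isi_s``.  Runs are maximal (not extendable either
    direction), hence non-overlapping."""
    t = train.times_s
    if t.size < min_spikes:
        return []
    short = np.diff(t) < max_isi_s
    bursts: list[BurstEvent] = []
    i = 0
    while i < short.size:
        if short[i]:
            j = i
            while j < short.size and short[j]:
                j += 1
            count = j - i + 1
            if count >= min_spikes:
                bursts.append(BurstEvent(float(t[i]), float(t[j]), int(count)))
            i = j
        else:
            i += 1
    return bursts


def activity_summary(trains: list[SpikeTrain], min_rate_hz: float = 0.01,
                     burst_min_spikes: int = 5, burst_max_isi_s: float = 0.050
                     ) -> tuple[float, float, pd.DataFrame]:
    """Slice-level spike rate (Hz) and burst rate (min^-1) over active electrodes.

    An electrode is active when its spike rate reaches ``min_rate_hz``.
    Returns (mean spike rate, mean burst rate, per-electrode table).
    """
    if not trains:
        raise ValidationError("no electrodes")
    rows = []
    for tr in trains:
        if tr.duration_s <= 0:
            raise ValidationError("zero-duration recording")
        bursts = detect_bursts(tr, burst_min_spikes, burst_max_isi_s)
        rows.append({
            "electrode": tr.electrode_id,
            "n_spikes": tr.times_s.size,
            "spike_rate_hz": tr.rate_hz,
            "n_bursts": len(bursts),
            "burst_rate_per_min": 60.0 * len(bursts) / tr.duration_s,
            "active": tr.rate_hz >= min_rate_hz,
        })
    table = pd.DataFrame(rows)
    active = table[table.active]
    if len(active):
        return (float(active.spike_rate_hz.mean()),
                float(active.burst_rate_per_min.mean()), table)
    return 0.0, 0.0, table


def rate_distribution_compare(rates_a, rates_b, alpha: float = 0.05):
    """Empirical CDFs of per-electrode rates plus a two-sample KS test.

    Returns ((sorted_a, cdf_a), (sorted_b, cdf_b), TestResult).
    """
    a = np.sort(np.asarray(rates_a, dtype=float).ravel())
    b = np.sort(np.asarray(rates_b, dtype=float).ravel())
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >=2 rates per group")
    res = stats.ks_two_sample(a, b, alpha=alpha)
    cdf_a = np.arange(1, a.size + 1) / a.size
    cdf_b = np.arange(1, b.size + 1) / b.size
    return (a, cdf_a), (b, cdf_b), res


def epsc_train_metrics(trains: list[EPSCTrain]) -> pd.DataFrame:
    """Per-cell normalised EPSC amplitudes and the EPSC5/EPSC1 ratio."""
    rows = []
    for tr in trains:
        norm = tr.amplitudes_pa / tr.amplitudes_pa[0]
        row = {"cell": tr.cell_id}
        row.update({f"pulse_{i + 1}": float(v) for i, v in enumerate(norm)})
        row["ratio_5_1"] = float(norm[4])
        rows.append(row)
    return pd.DataFrame(rows)
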