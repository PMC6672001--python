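"""Resting-state ROI functional connectivity.

The pipeline mirrors the standard small-animal rsfMRI analysis: each
regional BOLD series is linearly detrended and ideal band-pass filtered
(default 0.01-0.1 Hz at TR = 2 s), pairwise Pearson correlations are
Fisher z-transformed (z = atanh r, with |r| clipped at 1 - 1e-7 so z stays
finite), and group summaries are formed on the z scale: the mean FC of a
region across all other regions, the bilateral (homotopic) FC of each
left/right pair, group-mean matrices, seed-based per-voxel z-maps with a
one-sample second-level T-map, and per-region two-sample comparisons with
Holm-Šidák correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from . import stats
from .errors import PairingError, ValidationError

R_CLIP = 1.0 - 1e-7

__all__ = [
    "ROITimeSeriesSet",
    "ConnectivityMatrix",
    "SeedMap",
    "bandpass",
    "fc_matrix",
    "mean_fc",
    "bilateral_fc",
    "homotopic_pairs_from_labels",
    "group_mean_matrix",
    "seed_map",
    "group_seed_tmap",
    "compare_groups_fc",
    "fisher_z",
]


@dataclass
class ROITimeSeriesSet:
    """Per-subject ROI x time signal matrix with group label and TR."""

    subject_id: str
    group: str
    labels: list[str]
    data: np.ndarray  # (n_roi, n_time)
    sampling_interval_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValidationError("data must be (n_roi, n_time) matching labels")
        if len(self.labels) < 2:
            raise ValidationError("need >=2 ROIs")
        if self.data.shape[1] < 8:
            raise ValidationError("need >=8 timepoints for filtering")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("non-finite samples in ROI time series")
        if self.sampling_interval_s <= 0:
            raise ValidationError("sampling interval must be positive")


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix over labelled ROIs; diagonal is undefined (NaN)."""

    labels: list[str]
    z: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.labels)
        if self.z.shape != (n, n):
            raise ValidationError("z must be square matching labels")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"region {label!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.labels, columns=self.labels)


@dataclass
class SeedMap:
    """Per-voxel Fisher-z (or group T) values for one seed region."""

    seed_label: str
    values: np.ndarray  # 3D
    subject_id: str | None = None
    kind: str = "z"     # "z" or "T"


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform with clipping at |r| = 1 - 1e-7 to keep z finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def bandpass(series: np.ndarray, sampling_interval_s: float,
             low_hz: float = 0.01, high_hz: float = 0.1) -> np.ndarray:
    """Linear detrend then ideal frequency-domain band-pass.

    Operates on the last axis.  Frequency bins with low <= f <= high are
    kept, all others (including DC) are zeroed, so an in-band sinusoid is
    preserved and out-of-band content is fully attenuated.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise ValidationError("series shorter than 8 samples")
    nyquist = 0.5 / sampling_interval_s
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValidationError(
            f"need 0 < low < high < Nyquist ({nyquist:.4g} Hz)")
    x = spsig.detrend(x, axis=-1, type="linear")
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=sampling_interval_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def fc_matrix(ts: ROITimeSeriesSet) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of (already band-passed) ROI series,
    Fisher z-transformed.  Zero-variance ROIs get NaN rows and a flag."""
    data = ts.data
    sd = data.std(axis=1)
    flags = []
    z = np.full((len(ts.labels), len(ts.labels)), np.nan)
    good = sd > 0
    if good.sum() >= 2:
        r = np.corrcoef(data[good])
        zi = fisher_z(r)
        idx = np.where(good)[0]
        z[np.ix_(idx, idx)] = zi
    for i in np.where(~good)[0]:
        flags.append(f"zero_variance:{ts.labels[i]}")
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(list(ts.labels), z, flags)


def mean_fc(cm: ConnectivityMatrix, region: str) -> tuple[float, int]:
    """Mean z of ``region`` across all other regions; returns (mean, n used)."""
    if len(cm.labels) < 2:
        raise ValidationError("mean FC needs >=2 regions")
    i = cm.index(region)
    row = np.delete(cm.z[i], i)
    defined = np.isfinite(row)
    if not defined.any():
        return float("nan"), 0
    return float(row[defined].mean()), int(defined.sum())


def homotopic_pairs_from_labels(labels: list[str]) -> list[tuple[str, str]]:
    """Pair ``X_L`` with ``X_R`` labels; unmatched hemisphere labels raise."""
    lefts = {lab[:-2]: lab for lab in labels if lab.endswith("_L")}
    rights = {lab[:-2]: lab for lab in labels if lab.endswith("_R")}
    unmatched = set(lefts) ^ set(rights)
    if unmatched:
        raise PairingError(f"unmatched hemisphere label(s): {sorted(unmatched)}")
    return [(lefts[k], rights[k]) for k in sorted(lefts)]


def bilateral_fc(cm: ConnectivityMatrix,
                 homotopic_pairs: list[tuple[str, str]] | None = None) -> dict[str, float]:
    """z of each homotopic (left, right) pair, keyed by the region stem."""
    if homotopic_pairs is None:
        homotopic_pairs = homotopic_pairs_from_labels(cm.labels)
    out = {}
    for left, right in homotopic_pairs:
        if left == right:
            raise PairingError(f"self-pair requested for {left!r}")
        out[left[:-2] if left.endswith("_L") else f"{left}|{right}"] = float(
            cm.z[cm.index(left), cm.index(right)])
    return out


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of z over subjects (identical label sets required)."""
    if not matrices:
        raise ValidationError("empty matrix list")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValidationError("label mismatch across subjects")
    stacked = np.stack([m.z for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean = np.nanmean(stacked, axis=0)
    return ConnectivityMatrix(list(labels), mean)


def seed_map(volume_4d: np.ndarray, seed_mask: np.ndarray,
             subject_id: str | None = None, seed_label: str = "seed") -> SeedMap:
    """Per-voxel Fisher z of the correlation with the seed-mean signal.

    ``volume_4d`` is (x, y, z, t), already band-passed; the seed signal is
    the mean over mask voxels.
    """
    vol = np.asarray(volume_4d, dtype=float)
    mask = np.asarray(seed_mask).astype(bool)
    if vol.ndim != 4:
        raise ValidationError("seed_map needs a 4D volume")
    if mask.shape != vol.shape[:3]:
        raise ValidationError("mask grid mismatch")
    if not mask.any():
        raise ValidationError("empty seed mask")
    seed = vol[mask].mean(axis=0)
    seed_sd = seed.std()
    flat = vol.reshape(-1, vol.shape[-1])
    sd = flat.std(axis=1)
    seed_c = seed - seed.mean()
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (flat_c @ seed_c) / (flat.shape[-1] * sd * seed_sd)
    z = np.where((sd > 0) & (seed_sd > 0), fisher_z(np.nan_to_num(r)), np.nan)
    return SeedMap(seed_label, z.reshape(vol.shape[:3]), subject_id, "z")


def group_seed_tmap(maps: list[SeedMap]) -> SeedMap:
    """Second-level one-sample t of subject z-maps against 0 (df = n - 1).

    Voxels with zero between-subject variance are T = 0 when the mean is
    also 0, NaN (undefined) otherwise.
    """
    if len(maps) < 3:
        raise ValidationError("need >=3 subject maps")
    label = maps[0].seed_label
    stack = np.stack([m.values for m in maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.nan), t)
    return SeedMap(label, t, None, "T")


def compare_groups_fc(values_a: pd.DataFrame, values_b: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-region two-sample t-tests with Holm-Šidák correction.

    ``values_a``/``values_b`` are subjects x regions tables of per-subject
    FC summaries (e.g. mean or bilateral FC).  Regions with fewer than two
    defined values in either group are excluded.  Returns a tidy frame with
    t, raw p, adjusted p and the significance flag.
    """
    regions = [c for c in values_a.columns if c in values_b.columns]
    rows, excluded = [], []
    for region in regions:
        a = values_a[region].dropna().to_numpy()
        b = values_b[region].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            excluded.append(region)
            continue
        res = stats.two_sample_t(a, b, alpha=alpha)
        rows.append({"region": region, "t": res.statistic, "df": res.df,
                     "p_raw": res.p, "mean_a": a.mean(), "mean_b": b.mean()})
    if not rows:
        raise ValidationError("no region has >=2 subjects per group")
    out = pd.DataFrame(rows)
    adj, reject = stats.holm_sidak(out["p_raw"].to_numpy(), alpha=alpha)
    out["p_adj"] = adj
    out["significant"] = reject
    out.attrs["excluded_regions"] = excluded
    return out
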