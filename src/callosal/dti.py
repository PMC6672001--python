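"""Diffusion tensor fitting and scalar maps.

Per voxel the single-shell signal model S = S0 exp(-b ĝᵀ D ĝ) is inverted by
log-linear least squares: with design row [1, -b gx², -b gy², -b gz²,
-2b gx gy, -2b gx gz, -2b gy gz] the fit is exact for noiseless data.
Eigenvalues are sorted λ1 >= λ2 >= λ3 and negatives clamped to zero
(flagged).  Scalars follow the universal conventions: MD = (λ1+λ2+λ3)/3,
AD = λ1, RD = (λ2+λ3)/2 and FA = sqrt(3/2)·||λ − MD|| / ||λ|| (Basser),
with FA of the all-zero tensor defined as 0.  Group tooling covers
differential (mean A − mean B) maps, voxel-wise pooled two-sample t-maps
with the critical-T helper used to calibrate display bounds, and ROI-mean
statistics with Holm-Šidák correction across the four scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .errors import ValidationError
from .io import Acquisition

__all__ = [
    "TensorFitVolume",
    "design_matrix",
    "fit_tensor",
    "scalar_maps",
    "fa_from_eigenvalues",
    "differential_map",
    "voxelwise_ttest",
    "critical_t",
    "roi_dti_stats",
    "cc_volume_mm3",
]

_SCALARS = ("FA", "MD", "AD", "RD")


@dataclass
class TensorFitVolume:
    """Per-voxel tensor fit: S0, tensor, ordered eigenvalues, derived scalars."""

    s0: np.ndarray                 # (...,)
    tensor: np.ndarray             # (..., 3, 3) symmetric, mm^2/s
    eigenvalues: np.ndarray        # (..., 3) descending
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def md(self) -> np.ndarray:
        return self.eigenvalues.mean(axis=-1)

    @property
    def ad(self) -> np.ndarray:
        return self.eigenvalues[..., 0]

    @property
    def rd(self) -> np.ndarray:
        return self.eigenvalues[..., 1:].mean(axis=-1)

    @property
    def fa(self) -> np.ndarray:
        return fa_from_eigenvalues(self.eigenvalues)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy sqrt(3/2)·||λ − MD|| / ||λ||; 0 for a zero tensor."""
    ev = np.asarray(evals, dtype=float)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - md) ** 2).sum(axis=-1))
    den = np.sqrt((ev ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    # tensors at numerical zero (<< any physical diffusivity) are isotropic
    return np.where(den <= 1e-14, 0.0, np.clip(fa, 0.0, 1.0))


def design_matrix(acq: Acquisition) -> np.ndarray:
    """Log-linear design: columns [1, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] coefficients."""
    b = acq.bvals
    g = acq.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _tensor_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric."""
    t = np.empty(comp.shape[:-1] + (3, 3))
    t[..., 0, 0] = comp[..., 0]
    t[..., 1, 1] = comp[..., 1]
    t[..., 2, 2] = comp[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = comp[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = comp[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = comp[..., 5]
    return t


def fit_tensor(signals: np.ndarray, acq: Acquisition) -> TensorFitVolume:
    """Log-linear least-squares tensor fit over any leading voxel shape.

    ``signals`` has the acquisition axis last.  Requires >=1 b0 and >=6
    non-collinear weighted directions (rank check on the design).
    Non-positive samples are clamped to the smallest positive observed value
    and flagged; negative eigenvalues are clamped to 0 and flagged.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != acq.bvals.size:
        raise ValidationError("signal count does not match acquisition")
    if acq.is_b0.sum() < 1:
        raise ValidationError("need >=1 b0 measurement")
    if acq.n_weighted < 6:
        raise ValidationError("need >=6 diffusion-weighted directions")
    X = design_matrix(acq)
    if np.linalg.matrix_rank(X) < 7:
        raise ValidationError("rank-deficient design (collinear directions)")

    flags: dict[str, np.ndarray] = {}
    nonpos = s <= 0
    if nonpos.any():
        smallest = s[s > 0].min() if (s > 0).any() else 1.0
        s = np.where(nonpos, smallest, s)
        flags["clamped_signal"] = nonpos.any(axis=-1)

    flat = np.log(s.reshape(-1, s.shape[-1]))
    coef, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    coef = coef.T  # (nvox, 7)
    s0 = np.exp(coef[:, 0]).reshape(s.shape[:-1])
    tensor = _tensor_from_components(coef[:, 1:]).reshape(s.shape[:-1] + (3, 3))
    evals = np.linalg.eigvalsh(tensor)[..., ::-1]  # descending
    negative = evals < 0
    if negative.any():
        flags["clamped_eigenvalue"] = negative.any(axis=-1)
        evals = np.clip(evals, 0.0, None)
    return TensorFitVolume(s0, tensor, evals, flags)


def scalar_maps(fit: TensorFitVolume) -> dict[str, np.ndarray]:
    """FA/MD/AD/RD volumes from a fitted tensor volume."""
    return {"FA": fit.fa, "MD": fit.md, "AD": fit.ad, "RD": fit.rd}


def differential_map(maps_a: list[np.ndarray], maps_b: list[np.ndarray]) -> np.ndarray:
    """Voxelwise mean(A) − mean(B) on a common grid."""
    a = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    b = np.stack([np.asarray(m, dtype=float) for m in maps_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValidationError("grid mismatch between groups")
    return a.mean(axis=0) - b.mean(axis=0)


def voxelwise_ttest(maps_a: list[np.ndarray], maps_b: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise pooled-variance two-sample two-tailed t-test.

    Returns (T volume, p volume) with df = nA + nB − 2.  Voxels with zero
    within-group variance in both groups are NaN (undefined) unless the
    means are also equal, in which case T = 0, p = 1.
    """
    a = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    b = np.stack([np.asarray(m, dtype=float) for m in maps_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValidationError("grid mismatch between groups")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("need >=2 subjects per group")
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
    zero = se == 0
    t = np.where(zero, np.where(ma == mb, 0.0, np.nan), t)
    p = np.where(zero, np.where(ma == mb, 1.0, np.nan), p)
    return t, p


def critical_t(p_uncorrected: float, n_a: int, n_b: int) -> float:
    """Critical two-tailed |T| at an uncorrected p for a pooled two-sample test.

    Used to calibrate statistical-map display bounds, e.g. the T window
    corresponding to p in [0.05, 0.005] at group sizes 7 and 6 (df = 11).
    """
    if not (0.0 < p_uncorrected < 1.0):
        raise ValidationError("p must lie in (0, 1)")
    df = n_a + n_b - 2
    return float(sps.t.ppf(1.0 - p_uncorrected / 2.0, df))


def roi_dti_stats(subject_maps_a: list[dict[str, np.ndarray]],
                  subject_maps_b: list[dict[str, np.ndarray]],
                  roi_mask: np.ndarray,
                  alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROI-mean FA/MD/AD/RD per subject + group t-tests with Holm-Šidák.

    Each element of the subject lists is a dict of scalar volumes (as from
    :func:`scalar_maps`).  Returns (per-subject means, per-parameter tests).
    """
    mask = np.asarray(roi_mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty ROI mask")
    rows = []
    for group, subject_maps in (("A", subject_maps_a), ("B", subject_maps_b)):
        for i, maps in enumerate(subject_maps):
            row = {"group": group, "subject": f"{group}{i}"}
            for name in _SCALARS:
                vol = np.asarray(maps[name], dtype=float)
                if vol.shape != mask.shape:
                    raise ValidationError("mask grid mismatch")
                row[name] = float(vol[mask].mean())
            rows.append(row)
    per_subject = pd.DataFrame(rows)
    tests = []
    for name in _SCALARS:
        a = per_subject.loc[per_subject.group == "A", name].to_numpy()
        b = per_subject.loc[per_subject.group == "B", name].to_numpy()
        res = stats.two_sample_t(a, b, alpha=alpha)
        tests.append({"parameter": name, "t": res.statistic, "df": res.df,
                      "p_raw": res.p, "mean_a": a.mean(), "mean_b": b.mean()})
    tests = pd.DataFrame(tests)
    adj, reject = stats.holm_sidak(tests["p_raw"].to_numpy(), alpha=alpha)
    tests["p_adj"] = adj
    tests["significant"] = reject
    return per_subject, tests


def cc_volume_mm3(mask: np.ndarray, voxel_volume_mm3: float) -> float:
    """Structure volume as voxel count x voxel volume over a supplied mask."""
    return float(np.asarray(mask).astype(bool).sum() * voxel_volume_mm3)
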