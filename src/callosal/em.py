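"""Axon/g-ratio morphometry from electron micrographs.

Myelin appears as a dark annulus around the axoplasm in backscatter-SEM
images.  Segmentation thresholds the dark phase (Otsu by default), labels
connected myelin components, and fills their holes: the filled region is
the outer (axon + myelin) area, the holes the inner (axon) lumen.  Each
component yields one axon record with inner/outer areas, circular-equivalent
diameters d and D (2·sqrt(A/π)), myelin thickness (D − d)/2 and g-ratio d/D.
Components touching the image border, lacking a lumen, or failing the size
and g-ratio gates are excluded with named flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats
from .errors import ValidationError

__all__ = [
    "AxonRecord",
    "equivalent_diameter",
    "g_ratio",
    "myelin_thickness",
    "segment_axons",
    "records_to_frame",
    "diameter_binned_profile",
]


@dataclass
class AxonRecord:
    """One myelinated axon's geometry.  Lengths in um unless suffixed _px."""

    axon_id: int
    centroid_px: tuple[float, float]
    inner_area_px: float
    outer_area_px: float
    inner_area_um2: float
    outer_area_um2: float
    d_um: float          # inner (axon) circular-equivalent diameter
    D_um: float          # outer (axon + myelin) circular-equivalent diameter
    myelin_thickness_um: float
    g_ratio: float
    flags: list[str] = field(default_factory=list)

    @property
    def included(self) -> bool:
        return not self.flags


def equivalent_diameter(area: float) -> float:
    """Circular-equivalent diameter 2·sqrt(area/π); unit-propagating."""
    if area <= 0:
        raise ValidationError("area must be positive")
    return 2.0 * float(np.sqrt(area / np.pi))


def g_ratio(d: float, D: float) -> float:
    """g = d/D for 0 < d < D."""
    if not 0 < d < D:
        raise ValidationError(f"need 0 < d < D, got d={d}, D={D}")
    return d / D


def myelin_thickness(d: float, D: float) -> float:
    """(D − d)/2 for 0 < d < D."""
    if not 0 < d < D:
        raise ValidationError(f"need 0 < d < D, got d={d}, D={D}")
    return (D - d) / 2.0


def segment_axons(
    image: np.ndarray,
    pixel_size_nm: float,
    threshold: float | None = None,
    min_inner_diameter_um: float = 0.2,
    g_bounds: tuple[float, float] = (0.2, 0.98),
) -> tuple[np.ndarray, list[AxonRecord]]:
    """Identify and parameterise myelinated axons.

    Returns the labelled outer-region image and one record per myelin
    component.  ``threshold`` overrides the default Otsu threshold on the
    dark (myelin) phase.  Gates: components touching the border
    ("border"), without a lumen ("no_lumen"), with d below
    ``min_inner_diameter_um`` ("too_small") and with g-ratio outside
    ``g_bounds`` ("g_out_of_range") are flagged and excluded from
    ``included`` records but still reported.
    """
    if pixel_size_nm is None or pixel_size_nm <= 0:
        raise ValidationError("pixel size (nm) must be known and positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("image must be 2D grayscale")
    um_per_px = pixel_size_nm / 1000.0
    if img.size == 0 or img.max() == img.min():
        return np.zeros(img.shape, dtype=int), []
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(img))
    myelin = img < threshold  # myelin-dark convention
    labels, n = ndimage.label(myelin)
    out_labels = np.zeros(img.shape, dtype=int)
    records: list[AxonRecord] = []
    if n == 0:
        return out_labels, records
    slices = ndimage.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        comp = labels[sl] == idx
        filled = ndimage.binary_fill_holes(comp)
        holes = filled & ~comp
        flags = []
        touches = (sl[0].start == 0 or sl[1].start == 0
                   or sl[0].stop == img.shape[0] or sl[1].stop == img.shape[1])
        if touches:
            flags.append("border")
        inner_px = float(holes.sum())
        outer_px = float(filled.sum())
        if inner_px == 0:
            flags.append("no_lumen")
            records.append(AxonRecord(idx, _centroid(filled, sl), 0.0, outer_px,
                                      0.0, outer_px * um_per_px ** 2, 0.0,
                                      equivalent_diameter(outer_px) * um_per_px,
                                      0.0, 0.0, flags))
            continue
        d = equivalent_diameter(inner_px) * um_per_px
        D = equivalent_diameter(outer_px) * um_per_px
        g = d / D
        if d < min_inner_diameter_um:
            flags.append("too_small")
        if not (g_bounds[0] < g < g_bounds[1]):
            flags.append("g_out_of_range")
        rec = AxonRecord(
            idx, _centroid(filled, sl), inner_px, outer_px,
            inner_px * um_per_px ** 2, outer_px * um_per_px ** 2,
            d, D, (D - d) / 2.0, g, flags)
        records.append(rec)
        if rec.included:
            out_labels[sl][filled] = idx
    return out_labels, records


def _centroid(mask: np.ndarray, sl) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return (float(rr.mean() + sl[0].start), float(cc.mean() + sl[1].start))


def records_to_frame(records: list[AxonRecord], group: str | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "axon_id": r.axon_id, "row_px": r.centroid_px[0], "col_px": r.centroid_px[1],
            "inner_area_um2": r.inner_area_um2, "outer_area_um2": r.outer_area_um2,
            "d_um": r.d_um, "D_um": r.D_um,
            "myelin_thickness_um": r.myelin_thickness_um, "g_ratio": r.g_ratio,
            "flags": ";".join(r.flags), "included": r.included,
        })
    df = pd.DataFrame(rows)
    if group is not None and len(df):
        df.insert(0, "group", group)
    return df


def diameter_binned_profile(
    records_by_group: dict[str, list[AxonRecord]],
    bin_edges_um,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, stats.TestResult], pd.DataFrame]:
    """Per-bin per-group mean g-ratio ± SEM with a genotype x bin ANOVA.

    Binning is on the inner (axon) diameter d.  Returns (per-bin summary,
    two-way ANOVA results, per-bin group comparisons with Holm-Šidák).
    A design with a single occupied bin degenerates to a one-way comparison
    (the ANOVA dict then carries only the genotype effect).
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    frames = []
    for group, recs in records_by_group.items():
        g = np.array([r.g_ratio for r in recs if r.included])
        d = np.array([r.d_um for r in recs if r.included])
        which = np.digitize(d, edges) - 1
        ok = (which >= 0) & (which < edges.size - 1)
        frames.append(pd.DataFrame({"group": group, "bin": which[ok], "g": g[ok]}))
    data = pd.concat(frames, ignore_index=True)
    summary = (data.groupby(["group", "bin"])["g"]
               .agg(mean_g="mean", sem_g="sem", n="count").reset_index())
    summary["bin_low_um"] = edges[summary["bin"]]
    summary["bin_high_um"] = edges[summary["bin"] + 1]

    occupied = sorted(data["bin"].unique())
    groups = sorted(records_by_group)
    if len(occupied) >= 2 and len(groups) >= 2:
        anova = stats.two_way_anova(data["g"], data["group"], data["bin"],
                                    alpha=alpha, names=("genotype", "bin"))
    else:
        a = data.loc[data.group == groups[0], "g"]
        b = data.loc[data.group == groups[-1], "g"]
        anova = {"genotype": stats.two_sample_t(a, b, alpha=alpha)}
        anova["genotype"].flags.append("degenerate_single_bin")

    rows = []
    for b in occupied:
        sub = data[data["bin"] == b]
        a = sub.loc[sub.group == groups[0], "g"].to_numpy()
        c = sub.loc[sub.group == groups[-1], "g"].to_numpy()
        if a.size < 2 or c.size < 2:
            continue
        res = stats.two_sample_t(a, c, alpha=alpha)
        rows.append({"bin": b, "t": res.statistic, "p_raw": res.p})
    perbin = pd.DataFrame(rows)
    if len(perbin):
        adj, rej = stats.holm_sidak(perbin["p_raw"].to_numpy(), alpha=alpha)
        perbin["p_adj"] = adj
        perbin["significant"] = rej
    return summary, anova, perbin
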