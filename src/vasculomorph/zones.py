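"""Tumor / transition / normal zonal analysis of vascular morphometry.

A manually drawn tumor ROI is morphologically dilated and eroded with a
spherical structuring element (default diameter ~100 µm); the eroded ROI is
subtracted from the dilated ROI to yield the *transition zone* at the
tumor-brain interface, the eroded ROI is the tumor core, and the remainder
of the brain is normal tissue.  Each skeleton branch is assigned the zone
holding the majority of its centerline voxels, and per-zone branch-length
and radius distributions are compared pairwise with two-sided Mann-Whitney
rank-sum tests (the distributions are skewed, so a rank test is the safe
default; Holm correction is available behind a flag).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .morphometry import Skeleton
from .volume import Volume3D, require_same_grid

ZONE_ORDER = ("tumor", "transition", "normal")  # tie-break priority


@dataclass
class ZoneMasks:
    """Pairwise-disjoint tumor, transition and normal masks."""

    tumor: Volume3D
    transition: Volume3D
    normal: Volume3D

    def __post_init__(self) -> None:
        t = np.asarray(self.tumor.data) > 0
        tr = np.asarray(self.transition.data) > 0
        n = np.asarray(self.normal.data) > 0
        if (t & tr).any() or (t & n).any() or (tr & n).any():
            raise ValueError("zone masks must be pairwise disjoint")

    def labels(self) -> Volume3D:
        """Label volume: 0 outside, 1 normal, 2 transition, 3 tumor."""
        lab = np.zeros(self.tumor.shape, dtype=np.uint8)
        lab[np.asarray(self.normal.data) > 0] = 1
        lab[np.asarray(self.transition.data) > 0] = 2
        lab[np.asarray(self.tumor.data) > 0] = 3
        return self.tumor.with_data(lab, kind="labels")


def spherical_element(diameter_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Binary ball structuring element defined by physical distance.

    Includes every voxel offset whose centre lies within ``diameter/2`` µm
    of the origin (anisotropy-aware); always contains the origin.
    """
    sp = np.asarray(spacing, dtype=float)
    if diameter_um < sp.max():
        raise ValueError(
            f"element diameter {diameter_um} µm below max voxel spacing {sp.max()} µm")
    r = diameter_um / 2.0
    half = np.maximum(np.floor(r / sp).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.linalg.norm(offsets * sp, axis=1)
    el = (dist <= r).reshape(grids[0].shape)
    if el.sum() == 1:
        warnings.warn("structuring element degenerates to a single voxel", stacklevel=2)
    return el


def make_zones(tumor_roi: Volume3D, brain_mask: Volume3D, element: np.ndarray) -> ZoneMasks:
    """Build the three zones from a tumor ROI by dilation/erosion.

    transition = dilate(ROI) ∧ ¬erode(ROI); tumor = erode(ROI);
    normal = brain ∧ ¬dilate(ROI).  All masks are clipped to the brain.
    """
    require_same_grid(tumor_roi, brain_mask, "tumor ROI and brain mask")
    roi = np.asarray(tumor_roi.data) > 0
    brain = np.asarray(brain_mask.data) > 0
    if (roi & ~brain).any():
        raise ValueError("tumor ROI must lie inside the brain mask")
    dil = ndimage.binary_dilation(roi, structure=element)
    ero = ndimage.binary_erosion(roi, structure=element)
    if roi.any() and not ero.any():
        raise ValueError(
            "erosion empties the tumor ROI — the ROI is thinner than the "
            "structuring element; use a smaller element diameter")
    tumor = ero & brain
    transition = dil & ~ero & brain
    normal = brain & ~dil
    mk = lambda a: tumor_roi.with_data(a.astype(np.uint8), kind="binary")
    return ZoneMasks(tumor=mk(tumor), transition=mk(transition), normal=mk(normal))


def zonal_morphometry(
    segments: pd.DataFrame, skel: Skeleton, zones: ZoneMasks
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each branch a zone by majority vote of its skeleton voxels.

    Ties break toward the more tumor-proximal zone (tumor > transition >
    normal).  Branches whose voxels fall entirely outside every zone are
    labelled ``unassigned`` and excluded from the summary, which reports
    per-zone n, median and IQR of branch length and radius.
    """
    lab = np.asarray(zones.labels().data)
    zone_of = {3: "tumor", 2: "transition", 1: "normal"}
    labels = []
    for b in skel.branches:
        counts = np.bincount(lab[tuple(b.voxels.T)], minlength=4)
        in_zone = counts[1:4]
        if in_zone.sum() == 0:
            labels.append("unassigned")
            continue
        # argmax over (tumor, transition, normal) so ties prefer tumor
        pri = np.array([counts[3], counts[2], counts[1]])
        labels.append(ZONE_ORDER[int(np.argmax(pri))])
    if len(labels) != len(segments):
        raise ValueError("segment table and skeleton branch count disagree")
    out = segments.copy()
    out["zone"] = labels
    rows = []
    for z in ZONE_ORDER:
        sub = out[out["zone"] == z]
        row = {"zone": z, "n_branches": len(sub)}
        for col, name in (("length_um", "length"), ("mean_radius_um", "radius")):
            if col in sub.columns and len(sub):
                q1, med, q3 = np.percentile(sub[col], [25, 50, 75])
                row.update({f"median_{name}_um": med, f"iqr_{name}_um": q3 - q1})
            else:
                row.update({f"median_{name}_um": np.nan, f"iqr_{name}_um": np.nan})
        rows.append(row)
    return out, pd.DataFrame(rows)


def compare_zones(
    per_zone: dict[str, np.ndarray],
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney rank-sum tests between zones.

    ``per_zone`` maps zone name → 1D sample of a morphometric quantity
    (branch lengths or radii).  Pairs where either zone has fewer than two
    observations are skipped with a notice row.  No multiplicity correction
    by default; ``holm=True`` applies the Holm step-down adjustment.
    """
    rows = []
    names = list(per_zone)
    for a, b in itertools.combinations(names, 2):
        xa, xb = np.asarray(per_zone[a]), np.asarray(per_zone[b])
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"zone_a": a, "zone_b": b, "n_a": len(xa), "n_b": len(xb),
                         "statistic": np.nan, "p_value": np.nan,
                         "note": "skipped: fewer than 2 observations"})
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"zone_a": a, "zone_b": b, "n_a": len(xa), "n_b": len(xb),
                     "statistic": float(res.statistic), "p_value": float(res.pvalue),
                     "note": ""})
    df = pd.DataFrame(rows)
    if holm and len(df):
        tested = df["p_value"].notna()
        p = df.loc[tested, "p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        df.loc[tested, "p_holm"] = adj
    return df
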