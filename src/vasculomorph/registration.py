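"""Landmark thin-plate-spline registration and cross-modality validation.

Volumes acquired on different scanners (µMRI vs µCT, in vivo vs ex vivo)
are aligned through landmarks placed on large vessel bifurcations visible
in both datasets.  The warp is a 3D thin-plate spline: radial basis kernel
U(r) = ‖r‖ (the biharmonic spline in three dimensions — not the 2D r²·log r
kernel) plus an affine tail, which interpolates the landmarks exactly at
zero regularization and reproduces any affine-consistent landmark
configuration exactly.

Validation compares fractional-blood-volume maps between modalities on a
coarse cell grid via Pearson correlation with an ordinary-least-squares fit
and its 95% mean-response confidence band, and compares in vivo ΔR2*
against ex vivo FV through per-ROI histograms and a joint 2D histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.interpolate import RBFInterpolator

from .volume import Volume3D


@dataclass
class LandmarkSet:
    """Paired source/target landmark coordinates in µm."""

    source: np.ndarray  # (n, 3)
    target: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 3:
            raise ValueError("landmarks must be matching (n, 3) arrays")
        if len(self.source) < 4:
            raise ValueError("a 3D thin-plate spline needs at least 4 landmark pairs")
        d = np.linalg.norm(self.source[:, None] - self.source[None], axis=2)
        np.fill_diagonal(d, np.inf)
        if (d < 1e-9).any():
            raise ValueError("duplicate source landmarks")
        centered = self.source - self.source.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
            raise ValueError("source landmarks are coplanar; the affine part is singular")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        """6-column CSV: xs, ys, zs, xt, yt, zt in µm."""
        df = pd.read_csv(path)
        arr = df.to_numpy(dtype=float)
        return cls(source=arr[:, :3], target=arr[:, 3:6])


class TPSWarp:
    """A fitted 3D thin-plate-spline transform source → target."""

    def __init__(self, landmarks: LandmarkSet, regularization: float = 0.0):
        if regularization < 0:
            raise ValueError("regularization must be ≥ 0")
        self.landmarks = landmarks
        self.regularization = regularization
        # polyharmonic spline of degree 1 (kernel ∝ r) with a linear tail
        self._rbf = RBFInterpolator(
            landmarks.source, landmarks.target,
            kernel="linear", degree=1, smoothing=regularization,
        )

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self._rbf(pts)


def tps_fit(landmarks: LandmarkSet, regularization: float = 0.0) -> TPSWarp:
    """Fit the 3D TPS mapping source landmarks onto target landmarks.

    With ``regularization = 0`` the warp interpolates the landmarks exactly;
    positive values trade landmark fidelity for lower bending energy.
    """
    return TPSWarp(landmarks, regularization)


def warp_volume(
    vol: Volume3D,
    warp: TPSWarp,
    target_grid: Volume3D,
    interp: str = "linear",
) -> Volume3D:
    """Resample ``vol`` onto ``target_grid`` through a backward-mapped warp.

    ``warp`` must map *target* physical coordinates to *source* coordinates
    (fit the TPS with target points as its source side); each target voxel
    centre is pushed through the warp and the source volume interpolated
    there.  Binary volumes must use nearest-neighbour interpolation.
    Out-of-field voxels are 0.
    """
    if interp not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.kind == "binary" and interp != "nearest":
        raise ValueError("binary volumes must be warped with nearest-neighbour "
                         "interpolation")
    shp = target_grid.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shp], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    tgt_um = target_grid.voxel_to_physical(idx)
    src_um = warp(tgt_um)
    src_idx = vol.physical_to_voxel(src_um)
    # snap round-off just outside the grid back onto the boundary: the
    # constant-mode interpolator treats -1e-15 as fully out of field
    tol = 1e-6
    for a in range(3):
        c = src_idx[:, a]
        hi = vol.shape[a] - 1
        c[(c > -tol) & (c < 0)] = 0.0
        c[(c > hi) & (c < hi + tol)] = hi
    order = 0 if interp == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), src_idx.T, order=order,
        mode="constant", cval=0.0,
    ).reshape(shp)
    kind = vol.kind if vol.kind != "binary" else "binary"
    if vol.kind == "binary":
        out = (out > 0).astype(np.uint8)
    return Volume3D(out, target_grid.spacing, target_grid.origin, kind)


def resample(vol: Volume3D, factor: tuple[int, int, int], mode: str = "mean-bin") -> Volume3D:
    """Integer-factor resampling between grids.

    ``factor > 1`` components downsample by that block size (``mean-bin``
    averages source voxels per target voxel — applied to a binary input this
    yields partial-volume fractions; ``nearest`` picks the block's first
    voxel).  For upsampling pass the factor as a negative integer: ``-k``
    repeats each voxel ``k`` times along that axis (nearest), which makes
    upsample-then-downsample an identity.  Mean-bin conserves total mass.
    """
    data = np.asarray(vol.data, dtype=float)
    sp = list(vol.spacing)
    for axis, f in enumerate(factor):
        if f in (0, 1, -1):
            continue
        if f > 1:
            n = data.shape[axis] // f
            if n == 0:
                raise ValueError(f"axis {axis}: factor {f} exceeds size {data.shape[axis]}")
            sl = [slice(None)] * data.ndim
            sl[axis] = slice(0, n * f)
            data = data[tuple(sl)]
            new_shape = list(data.shape)
            new_shape[axis : axis + 1] = [n, f]
            if mode == "mean-bin":
                data = data.reshape(new_shape).mean(axis=axis + 1)
            elif mode == "nearest":
                data = data.reshape(new_shape).take(0, axis=axis + 1)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            sp[axis] *= f
        else:  # f < -1: upsample by repetition
            k = -f
            data = np.repeat(data, k, axis=axis)
            sp[axis] /= k
    kind = "parametric" if mode == "mean-bin" else vol.kind
    if np.isin(np.unique(data), (0, 1)).all() and vol.kind == "binary":
        kind = "binary"
        data = data.astype(np.uint8)
    return Volume3D(data, tuple(sp), vol.origin, kind)


@dataclass
class CorrelationReport:
    """Cell-wise FV pairs with their Pearson correlation and OLS line."""

    pairs: pd.DataFrame          # columns fv_a, fv_b
    r: float
    p_value: float
    slope: float
    intercept: float
    band: pd.DataFrame = field(default_factory=pd.DataFrame)
    # band columns: x, fit, lo95, hi95 (mean-response confidence limits)

    @property
    def n(self) -> int:
        return len(self.pairs)


def fv_correlation(
    fv_a: np.ndarray,
    fv_b: np.ndarray,
    mask: np.ndarray | None = None,
    exclude_double_zero: bool = False,
) -> CorrelationReport:
    """Correlate two fractional-blood-volume grids cell by cell.

    Reports the Pearson r, the ordinary-least-squares line and the 95%
    confidence band of the mean response.  Cells where both FVs are zero
    can be excluded (``exclude_double_zero``) — by default they are kept.
    Zero variance in either input leaves r undefined (NaN).
    """
    a = np.asarray(fv_a, dtype=float).ravel()
    b = np.asarray(fv_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("FV grids must have identical dimensions")
    keep = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask).ravel() > 0
    if exclude_double_zero:
        keep &= ~((a == 0) & (b == 0))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    pairs = pd.DataFrame({"fv_a": a, "fv_b": b})
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationReport(pairs=pairs, r=float("nan"), p_value=float("nan"),
                                 slope=float("nan"), intercept=float("nan"))
    r, p = stats.pearsonr(a, b)
    # OLS of fv_b on fv_a with the mean-response confidence band
    n = len(a)
    xbar = a.mean()
    sxx = ((a - xbar) ** 2).sum()
    slope = ((a - xbar) * (b - b.mean())).sum() / sxx
    intercept = b.mean() - slope * xbar
    resid = b - (intercept + slope * a)
    dof = n - 2
    s2 = (resid**2).sum() / dof if dof > 0 else np.nan
    xs = np.linspace(a.min(), a.max(), 64)
    fit = intercept + slope * xs
    if dof > 0:
        se_mean = np.sqrt(s2 * (1.0 / n + (xs - xbar) ** 2 / sxx))
        tcrit = stats.t.ppf(0.975, dof)
        band = pd.DataFrame({"x": xs, "fit": fit,
                             "lo95": fit - tcrit * se_mean,
                             "hi95": fit + tcrit * se_mean})
    else:
        band = pd.DataFrame({"x": xs, "fit": fit, "lo95": fit, "hi95": fit})
    return CorrelationReport(pairs=pairs, r=float(r), p_value=float(p),
                             slope=float(slope), intercept=float(intercept),
                             band=band)


def compare_invivo_exvivo(
    dcbv: Volume3D,
    fv: Volume3D,
    roi_tumor: Volume3D,
    roi_contra: Volume3D,
    bins: int = 32,
) -> dict:
    """Compare in vivo ΔR2* with ex vivo FV on co-registered grids.

    Returns per-ROI 1D histograms of both measures (shared fixed bin
    edges), a joint 2D histogram over the union of the ROIs (bin ranges
    from the robust 1st–99th percentiles), and per-ROI medians.
    """
    for other in (fv, roi_tumor, roi_contra):
        if dcbv.shape != other.shape:
            raise ValueError("all volumes must be co-registered to one grid")
    d = np.asarray(dcbv.data, dtype=float)
    f = np.asarray(fv.data, dtype=float)
    rois = {"tumor": np.asarray(roi_tumor.data) > 0,
            "contralateral": np.asarray(roi_contra.data) > 0}
    for name, m in rois.items():
        if not m.any():
            raise ValueError(f"empty ROI: {name}")
    union = rois["tumor"] | rois["contralateral"]

    def robust_edges(x):
        lo, hi = np.percentile(x, [1, 99])
        if lo == hi:
            hi = lo + 1e-12
        return np.linspace(lo, hi, bins + 1)

    d_edges = robust_edges(d[union])
    f_edges = robust_edges(f[union])
    # clip into the robust range so every masked voxel lands in a bin and
    # the 2D histogram marginals recompose the 1D histograms exactly
    d = np.clip(d, d_edges[0], d_edges[-1])
    f = np.clip(f, f_edges[0], f_edges[-1])
    out: dict = {"rois": {}, "bins": {"dcbv": d_edges, "fv": f_edges}}
    for name, m in rois.items():
        out["rois"][name] = {
            "dcbv_hist": np.histogram(d[m], bins=d_edges)[0],
            "fv_hist": np.histogram(f[m], bins=f_edges)[0],
            "median_dcbv": float(np.median(d[m])),
            "median_fv": float(np.median(f[m])),
            "n_voxels": int(m.sum()),
        }
    h2, _, _ = np.histogram2d(d[union], f[union], bins=[d_edges, f_edges])
    out["hist2d"] = h2
    return out
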