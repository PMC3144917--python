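"""Voxel-wise monoexponential relaxometry and ΔR2* blood-volume maps.

Each voxel of a multi-echo series is fitted with the monoexponential decay

    S(TE_i) = S0 * exp(-R2* * TE_i)

by bounded nonlinear least squares, initialized from the closed-form
log-linear estimate.  Fitting is constrained to 0 < S0 < 2^16 (16-bit data)
and 0 < R2* < 1 /ms (T2 > 1 ms); parameters that finish at a bound are
clamped there and flagged.  Background voxels are masked out and assigned an
R2* of exactly zero.  The difference of post- and pre-contrast R2* maps is
the ΔR2* cerebral-blood-volume proxy; negative differences are reported, not
clipped.

Units: echo times in ms, relaxation rates in 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D, require_same_grid

S0_UPPER = 2.0**16   # 16-bit data ceiling
R2S_UPPER = 1.0      # 1/ms, i.e. T2* > 1 ms
EPS_BOUND = 1e-12
S0_MARGIN = 1e-6     # representable strict-inequality margin at the S0 bound


@dataclass
class EchoSeries:
    """A multi-echo acquisition: one volume per echo, all on one grid."""

    echo_times_ms: tuple[float, ...]
    volumes: list[Volume3D]

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if len(te) != len(self.volumes):
            raise ValueError("one volume per echo time required")
        if len(te) >= 2 and not (np.diff(te) > 0).all():
            raise ValueError("echo times must be strictly increasing")
        for v in self.volumes[1:]:
            require_same_grid(self.volumes[0], v, "echo volumes")

    @property
    def grid(self) -> Volume3D:
        return self.volumes[0]

    def stack(self) -> np.ndarray:
        """Signals as an array of shape (nechoes, nx, ny, nz)."""
        return np.stack([np.asarray(v.data, dtype=float) for v in self.volumes])


@dataclass
class RelaxMap:
    """Fitted S0 and R2* maps with the fit mask and per-voxel residual norm."""

    s0: Volume3D
    r2star: Volume3D
    mask: Volume3D
    fit_error: Volume3D
    at_bound: Volume3D  # 1 where a parameter was clamped at a constraint


def _loglinear_fit(te: np.ndarray, sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form log-linear estimate per voxel.

    ``sig`` has shape (nechoes, nvox).  Echoes with non-positive signal are
    excluded voxel-wise (log undefined); voxels with fewer than two usable
    echoes fall back to (mean signal, upper R2* bound).
    """
    nvox = sig.shape[1]
    ok = sig > 0
    logs = np.where(ok, np.log(np.where(ok, sig, 1.0)), 0.0)
    w = ok.astype(float)
    n = w.sum(axis=0)
    sx = (w * te[:, None]).sum(axis=0)
    sy = (w * logs).sum(axis=0)
    sxx = (w * te[:, None] ** 2).sum(axis=0)
    sxy = (w * te[:, None] * logs).sum(axis=0)
    denom = n * sxx - sx**2
    usable = (n >= 2) & (np.abs(denom) > 0)
    slope = np.zeros(nvox)
    intercept = np.zeros(nvox)
    slope[usable] = (n * sxy - sx * sy)[usable] / denom[usable]
    intercept[usable] = (sy - slope * sx)[usable] / n[usable]
    s0 = np.where(usable, np.exp(intercept), sig.mean(axis=0))
    r2s = np.where(usable, -slope, R2S_UPPER)
    return s0, r2s


def _gauss_newton_refine(
    te: np.ndarray, sig: np.ndarray, s0: np.ndarray, r2s: np.ndarray,
    n_iter: int = 60, tol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projected Gauss-Newton refinement of (S0, R2*) per voxel.

    The two-parameter normal equations are solved in closed form for every
    voxel simultaneously; steps that would worsen the residual are halved
    (up to 8 times) and iterates are projected onto the box constraints.
    """
    s0 = np.clip(s0.copy(), EPS_BOUND, S0_UPPER - S0_MARGIN)
    r2s = np.clip(r2s.copy(), EPS_BOUND, R2S_UPPER - EPS_BOUND)

    def residual2(a, r):
        return ((a[None] * np.exp(-r[None] * te[:, None]) - sig) ** 2).sum(axis=0)

    f2 = residual2(s0, r2s)
    for _ in range(n_iter):
        e = np.exp(-r2s[None] * te[:, None])        # (nte, nvox)
        model = s0[None] * e
        res = sig - model
        # Jacobian columns: d/dS0 = e, d/dR2* = -te*model
        j11 = (e * e).sum(axis=0)
        j12 = (-te[:, None] * model * e).sum(axis=0)
        j22 = ((te[:, None] * model) ** 2).sum(axis=0)
        g1 = (e * res).sum(axis=0)
        g2 = (-te[:, None] * model * res).sum(axis=0)
        det = j11 * j22 - j12**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_s0 = (j22 * g1 - j12 * g2) / det
        d_r2 = (j11 * g2 - j12 * g1) / det
        step = np.ones_like(s0)
        new_s0 = np.clip(s0 + d_s0, EPS_BOUND, S0_UPPER - S0_MARGIN)
        new_r2 = np.clip(r2s + d_r2, EPS_BOUND, R2S_UPPER - EPS_BOUND)
        new_f2 = residual2(new_s0, new_r2)
        for _ in range(8):
            worse = new_f2 > f2 + 1e-30
            if not worse.any():
                break
            step[worse] *= 0.5
            new_s0 = np.where(worse, np.clip(s0 + step * d_s0, EPS_BOUND, S0_UPPER - S0_MARGIN), new_s0)
            new_r2 = np.where(worse, np.clip(r2s + step * d_r2, EPS_BOUND, R2S_UPPER - EPS_BOUND), new_r2)
            new_f2 = np.where(worse, residual2(new_s0, new_r2), new_f2)
        improved = new_f2 <= f2
        s0 = np.where(improved, new_s0, s0)
        r2s = np.where(improved, new_r2, r2s)
        f2_prev, f2 = f2, np.where(improved, new_f2, f2)
        if np.all(np.abs(f2_prev - f2) <= tol * (1.0 + f2)):
            break
    return s0, r2s


def fit_monoexponential(series: EchoSeries, mask: Volume3D | None = None) -> RelaxMap:
    """Fit S(TE) = S0·exp(−R2*·TE) per voxel inside the mask.

    Voxels outside the mask get R2* = 0 exactly.  An all-zero voxel series
    cannot constrain the decay; such voxels are set to the upper R2* bound
    and flagged in ``at_bound``.
    """
    te = np.asarray(series.echo_times_ms, dtype=float)
    if len(te) < 2:
        raise ValueError("monoexponential fit needs at least 2 echoes")
    grid = series.grid
    if mask is None:
        m = np.ones(grid.shape, dtype=bool)
    else:
        require_same_grid(grid, mask, "mask and echo volumes")
        m = np.asarray(mask.data) > 0
    sig_all = series.stack()
    sig = sig_all[:, m]  # (nte, nvox)

    s0_init, r2s_init = _loglinear_fit(te, sig)
    s0_fit, r2s_fit = _gauss_newton_refine(te, sig, s0_init, r2s_init)

    # residual norm and bound flags
    model = s0_fit[None] * np.exp(-r2s_fit[None] * te[:, None])
    err = np.sqrt(((model - sig) ** 2).sum(axis=0))
    tol = 1e-9
    at_bound = (
        (s0_fit <= EPS_BOUND * 2) | (s0_fit >= S0_UPPER - S0_MARGIN - tol)
        | (r2s_fit <= EPS_BOUND * 2) | (r2s_fit >= R2S_UPPER - EPS_BOUND - tol)
    )
    dead = sig.max(axis=0) <= 0
    r2s_fit[dead] = R2S_UPPER - EPS_BOUND
    at_bound[dead] = True

    s0_map = np.zeros(grid.shape)
    r2s_map = np.zeros(grid.shape)
    err_map = np.zeros(grid.shape)
    bound_map = np.zeros(grid.shape, dtype=np.uint8)
    s0_map[m] = s0_fit
    r2s_map[m] = r2s_fit
    err_map[m] = err
    bound_map[m] = at_bound.astype(np.uint8)
    return RelaxMap(
        s0=grid.with_data(s0_map, kind="parametric"),
        r2star=grid.with_data(r2s_map, kind="parametric"),
        mask=grid.with_data(m.astype(np.uint8), kind="binary"),
        fit_error=grid.with_data(err_map, kind="parametric"),
        at_bound=grid.with_data(bound_map, kind="binary"),
    )


def delta_r2star(pre: RelaxMap, post: RelaxMap) -> Volume3D:
    """ΔR2* = R2*(post) − R2*(pre) on the intersection of the two fit masks.

    This post-minus-pre change in the effective transverse relaxation rate
    is the cerebral-blood-volume proxy; it is zero outside the joint mask
    and negative values are retained.
    """
    require_same_grid(pre.r2star, post.r2star, "pre/post R2* maps")
    joint = (np.asarray(pre.mask.data) > 0) & (np.asarray(post.mask.data) > 0)
    d = np.where(joint, np.asarray(post.r2star.data) - np.asarray(pre.r2star.data), 0.0)
    return pre.r2star.with_data(d, kind="parametric")


def mask_background(series: EchoSeries, method: str = "isodata") -> Volume3D:
    """Foreground mask from the first-echo intensity.

    The iterative intermeans threshold of the segmentation stage is applied
    to the first echo (highest SNR) and the largest 26-connected foreground
    component is retained.  A uniform nonzero volume is entirely foreground;
    an all-zero volume has no foreground and raises.
    """
    from .segmentation import isodata_threshold

    first = np.asarray(series.volumes[0].data, dtype=float)
    if first.max() <= 0:
        raise ValueError("empty foreground: first echo has no positive signal")
    if first.min() == first.max():
        fg = np.ones(first.shape, dtype=bool)
    else:
        t = isodata_threshold(series.volumes[0])
        fg = first >= t
        if not fg.any():
            raise ValueError("empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(counts)) + 1)
    return series.grid.with_data(fg.astype(np.uint8), kind="binary")
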