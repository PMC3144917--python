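"""Diffusion tensor fitting, scalar maps and FACT streamline tracking.

The tensor is estimated voxel-wise from one b0 and ≥6 diffusion-weighted
volumes by the log-linear model

    ln(S_i / S0) = -b · g_iᵀ D g_i,

an exact 6×6 linear solve when exactly six non-collinear directions are
acquired.  From the sorted eigenvalues λ1 ≥ λ2 ≥ λ3 (mm²/s):

    ADC = (λ1 + λ2 + λ3) / 3
    FA  = sqrt(3/2) · sqrt(Σ(λi − λ̄)²) / sqrt(Σ λi²),   FA(0) := 0

Noise can break positive-definiteness; negative eigenvalues are clamped to
zero for the scalar maps and flagged per voxel rather than propagated as
NaNs.

Tracking follows FACT (fiber assignment by continuous tracking): from each
seed, propagate bidirectionally along the voxel's principal eigenvector,
advancing to the next voxel boundary (not by fixed Euler steps), with the
eigenvector sign flipped to keep a non-negative dot product with the
incoming direction.  Propagation stops when FA drops below the threshold
(default 0.2), when the turning angle between consecutive voxels exceeds
the angular threshold (default 40°), or at the volume edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume import Volume3D, require_same_grid

DEFAULT_BVALUE = 1700.0  # s/mm^2
DEFAULT_DIRECTIONS: tuple[tuple[float, float, float], ...] = (
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (-1, 1, 0), (1, 0, -1), (0, -1, 1))


@dataclass
class GradientScheme:
    """Diffusion gradient table: one b-value and ≥6 unit directions."""

    b_value: float = DEFAULT_BVALUE
    directions: tuple[tuple[float, float, float], ...] = DEFAULT_DIRECTIONS

    def __post_init__(self) -> None:
        if self.b_value <= 0:
            raise ValueError("b-value must be > 0")
        g = np.asarray(self.directions, dtype=float)
        if g.shape[0] < 6 or g.shape[1] != 3:
            raise ValueError("need at least 6 gradient directions")
        self._g = g / np.linalg.norm(g, axis=1, keepdims=True)
        d = self.design_matrix()
        cond = np.linalg.cond(d)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(
                f"singular diffusion design (condition {cond:.3g}); "
                f"directions: {self.directions}")

    @property
    def unit_directions(self) -> np.ndarray:
        return self._g

    def design_matrix(self) -> np.ndarray:
        """Rows (gx², gy², gz², 2gxgy, 2gxgz, 2gygz) of the unit gradients."""
        g = self._g
        return np.stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ], axis=1)


def read_bvecs(path) -> np.ndarray:
    """Gradient table from whitespace-separated 3-column text."""
    g = np.loadtxt(path, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError(f"{path}: expected a 3-column gradient table, got {g.shape}")
    return g


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with eigendecomposition."""

    tensors: np.ndarray       # (nx, ny, nz, 3, 3) mm²/s
    eigenvalues: np.ndarray   # (nx, ny, nz, 3) sorted descending λ1 ≥ λ2 ≥ λ3
    principal: np.ndarray     # (nx, ny, nz, 3) eigenvector of λ1
    mask: np.ndarray          # bool
    negative_flag: np.ndarray  # bool, where clamping occurred
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def fit_tensor(
    b0: Volume3D,
    dwis: Sequence[Volume3D],
    scheme: GradientScheme,
    mask: Volume3D | None = None,
    signal_floor: float = 1e-12,
) -> TensorField:
    """Log-linear least-squares tensor fit (exact solve for 6 directions).

    Signals are floored at ``signal_floor`` before taking logs so that
    zero-signal voxels yield large but finite attenuations.  Eigenvalues are
    sorted descending; negative eigenvalues are clamped to zero with the
    voxel flagged in ``negative_flag``.
    """
    g = scheme.unit_directions
    if len(dwis) != len(g):
        raise ValueError(f"{len(dwis)} DWI volumes for {len(g)} directions")
    for d in dwis:
        require_same_grid(b0, d, "b0 and DWI volumes")
    m = np.ones(b0.shape, dtype=bool) if mask is None else np.asarray(mask.data) > 0
    s0 = np.asarray(b0.data, dtype=float)[m]
    s = np.stack([np.asarray(d.data, dtype=float)[m] for d in dwis])  # (ndir, nvox)
    atten = -np.log(np.maximum(s, signal_floor) / np.maximum(s0, signal_floor)[None]) / scheme.b_value
    design = scheme.design_matrix()
    coef, *_ = np.linalg.lstsq(design, atten, rcond=None)  # (6, nvox)
    nvox = coef.shape[1]
    tens = np.empty((nvox, 3, 3))
    tens[:, 0, 0] = coef[0]
    tens[:, 1, 1] = coef[1]
    tens[:, 2, 2] = coef[2]
    tens[:, 0, 1] = tens[:, 1, 0] = coef[3]
    tens[:, 0, 2] = tens[:, 2, 0] = coef[4]
    tens[:, 1, 2] = tens[:, 2, 1] = coef[5]
    w, v = np.linalg.eigh(tens)          # ascending
    w = w[:, ::-1]                       # λ1 ≥ λ2 ≥ λ3
    v = v[:, :, ::-1]
    neg = (w < 0).any(axis=1)
    w_cl = np.maximum(w, 0.0)

    shape = b0.shape
    tensors = np.zeros(shape + (3, 3))
    evals = np.zeros(shape + (3,))
    princ = np.zeros(shape + (3,))
    negf = np.zeros(shape, dtype=bool)
    tensors[m] = tens
    evals[m] = w_cl
    princ[m] = v[:, :, 0]
    negf[m] = neg
    return TensorField(tensors=tensors, eigenvalues=evals, principal=princ,
                       mask=m, negative_flag=negf,
                       spacing=b0.spacing, origin=b0.origin)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of eigenvalue triples; FA of the zero tensor is 0."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def scalar_maps(field: TensorField) -> tuple[Volume3D, Volume3D]:
    """ADC (mean diffusivity, mm²/s) and FA maps from the eigenvalues."""
    adc = field.eigenvalues.mean(axis=-1)
    fa = fa_from_eigenvalues(field.eigenvalues)
    adc[~field.mask] = 0.0
    fa[~field.mask] = 0.0
    adc_vol = Volume3D(adc, field.spacing, field.origin, "parametric")
    fa_vol = Volume3D(fa, field.spacing, field.origin, "parametric")
    return adc_vol, fa_vol


def _first_positive_exit(pos: np.ndarray, direction: np.ndarray,
                         lo: np.ndarray, hi: np.ndarray) -> float:
    """Parameter t > 0 at which the ray pos + t·dir leaves the box [lo, hi]."""
    t = np.full(3, np.inf)
    for a in range(3):
        if direction[a] > 1e-12:
            t[a] = (hi[a] - pos[a]) / direction[a]
        elif direction[a] < -1e-12:
            t[a] = (lo[a] - pos[a]) / direction[a]
    # ties at a corner resolve by axis priority x > y > z via argmin order
    return float(t[int(np.argmin(t))])


def fact_track(
    field: TensorField,
    seeds: Sequence[tuple[int, int, int]],
    fa_threshold: float = 0.2,
    angle_threshold_deg: float = 40.0,
    max_steps: int = 10_000,
) -> list[np.ndarray]:
    """FACT deterministic streamline tracking from seed voxels.

    Returns one polyline (n, 3) in physical µm per seed (possibly empty when
    the seed is below the FA threshold).  Propagation advances from voxel
    boundary to voxel boundary along each voxel's principal eigenvector.
    """
    if not 0.0 < fa_threshold < 1.0:
        raise ValueError("FA threshold must lie in (0, 1)")
    if not 0.0 < angle_threshold_deg < 90.0:
        raise ValueError("angle threshold must lie in (0°, 90°)")
    fa = fa_from_eigenvalues(field.eigenvalues)
    fa[~field.mask] = 0.0
    shape = np.asarray(field.eigenvalues.shape[:3])
    sp = np.asarray(field.spacing, dtype=float)
    org = np.asarray(field.origin, dtype=float)
    cos_thresh = np.cos(np.deg2rad(angle_threshold_deg))
    eps = 1e-6

    def voxel_of(p_um: np.ndarray) -> np.ndarray:
        return np.floor((p_um - org) / sp + 0.5).astype(int)

    def inside(ijk: np.ndarray) -> bool:
        return bool((ijk >= 0).all() and (ijk < shape).all())

    def march(start_um: np.ndarray, init_dir: np.ndarray) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        pos = start_um.copy()
        prev_dir = init_dir / np.linalg.norm(init_dir)
        for _ in range(max_steps):
            ijk = voxel_of(pos)
            if not inside(ijk):
                break
            if fa[tuple(ijk)] < fa_threshold:
                break
            e = field.principal[tuple(ijk)].copy()
            n = np.linalg.norm(e)
            if n == 0:
                break
            e /= n
            if np.dot(e, prev_dir) < 0:
                e = -e
            if np.dot(e, prev_dir) < cos_thresh:
                break
            lo = org + (ijk - 0.5) * sp
            hi = org + (ijk + 0.5) * sp
            t = _first_positive_exit(pos, e, lo, hi)
            if not np.isfinite(t):
                break
            pos = pos + (t + eps) * e
            pts.append(pos.copy())
            prev_dir = e
        return pts

    lines: list[np.ndarray] = []
    for seed in seeds:
        ijk = np.asarray(seed, dtype=int)
        if not inside(ijk) or fa[tuple(ijk)] < fa_threshold:
            lines.append(np.empty((0, 3)))
            continue
        e0 = field.principal[tuple(ijk)]
        if np.linalg.norm(e0) == 0:
            lines.append(np.empty((0, 3)))
            continue
        start = org + ijk * sp
        fwd = march(start, e0)
        bwd = march(start, -e0)
        line = bwd[::-1] + [start] + fwd
        lines.append(np.asarray(line))
    return lines


def streamlines_table(lines: Sequence[np.ndarray]) -> "pd.DataFrame":
    """Streamlines flattened to an (id, x, y, z µm) table for CSV export."""
    import pandas as pd

    rows = []
    for i, line in enumerate(lines):
        for p in line:
            rows.append({"id": i, "x_um": p[0], "y_um": p[1], "z_um": p[2]})
    return pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um"])
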