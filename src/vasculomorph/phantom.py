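"""Synthetic vascular phantoms with analytic ground truth.

This module generates random vascular trees inside a box domain containing a
spherical "tumor" with a surrounding transition shell, rasterizes the trees
onto voxel grids, and simulates the two MR contrasts the pipeline consumes:
multi-echo gradient-echo magnitude volumes in which the vessel lumen is dark
(no mobile protons), and six-direction diffusion-weighted volumes from a
known tensor field.  Because every segment's endpoints and radius are known
exactly, the tree doubles as an analytic oracle for the morphometry stages.

Tree growth is a random-walk branching process whose step length, radius and
target density are drawn per zone: the tumor zone uses shorter, more
tortuous and denser segments than normal brain, with the transition shell
intermediate — the qualitative contrast between chaotic tumor vasculature
and the regular, hierarchical normal vasculature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume3D

Zone = Literal["normal", "transition", "tumor"]
ZONES: tuple[Zone, ...] = ("normal", "transition", "tumor")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One straight vessel segment in physical µm coordinates."""

    p_start: np.ndarray
    p_end: np.ndarray
    radius: float
    zone: Zone
    parent: int = -1

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end - self.p_start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p_start + self.p_end)


@dataclass
class VesselTree:
    """A collection of capsule-shaped segments with parent connectivity."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.segments):
            if s.radius <= 0:
                raise ValueError(f"segment {i}: radius must be > 0")
            if s.length <= 0:
                raise ValueError(f"segment {i}: zero-length segment")

    def __len__(self) -> int:
        return len(self.segments)

    def zones(self) -> list[Zone]:
        return [s.zone for s in self.segments]


@dataclass
class ZoneParams:
    """Per-zone segment statistics: log-normal lengths, normal radii, target FV."""

    length_mean_um: float = 250.0
    length_sd_um: float = 100.0
    radius_mean_um: float = 40.0
    radius_sd_um: float = 8.0
    target_fv: float = 0.03
    tortuosity: float = 0.3  # sd (radians) of the per-step direction perturbation


@dataclass
class PhantomSpec:
    """Geometry, per-zone vessel statistics and noise for one phantom.

    The domain is the box ``[0, domain_size]`` µm; the tumor is a sphere of
    radius ``tumor_radius_um`` at ``tumor_center_um`` and the transition zone
    is the spherical shell of width ``transition_width_um`` around it.  Zone
    of a point: tumor if inside the sphere, transition if within the shell,
    normal otherwise.
    """

    domain_size_um: tuple[float, float, float] = (2000.0, 2000.0, 2000.0)
    spacing_um: tuple[float, float, float] = (62.0, 62.0, 63.0)
    tumor_center_um: tuple[float, float, float] = (1000.0, 1000.0, 1000.0)
    tumor_radius_um: float = 500.0
    transition_width_um: float = 200.0
    normal: ZoneParams = field(default_factory=lambda: ZoneParams(
        length_mean_um=300.0, length_sd_um=120.0, radius_mean_um=45.0,
        radius_sd_um=9.0, target_fv=0.03, tortuosity=0.25))
    transition: ZoneParams = field(default_factory=lambda: ZoneParams(
        length_mean_um=220.0, length_sd_um=100.0, radius_mean_um=40.0,
        radius_sd_um=9.0, target_fv=0.05, tortuosity=0.45))
    tumor: ZoneParams = field(default_factory=lambda: ZoneParams(
        length_mean_um=150.0, length_sd_um=70.0, radius_mean_um=35.0,
        radius_sd_um=8.0, target_fv=0.08, tortuosity=0.7))
    noise: Literal["none", "gaussian", "rician"] = "rician"
    snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for z in ZONES:
            fv = getattr(self, z).target_fv
            if not 0.0 < fv < 0.5:
                raise ValueError(f"{z} target FV {fv} outside (0, 0.5)")
        c = np.asarray(self.tumor_center_um)
        if self.tumor_radius_um > 0:
            lo = c - self.tumor_radius_um
            hi = c + self.tumor_radius_um
            if (lo < 0).any() or (hi > np.asarray(self.domain_size_um)).any():
                raise ValueError("tumor sphere extends outside the domain")

    def zone_params(self, zone: Zone) -> ZoneParams:
        return getattr(self, zone)

    def zone_of_points(self, pts: np.ndarray) -> np.ndarray:
        """Zone index (0=normal, 1=transition, 2=tumor) of each µm point.

        The transition shell is symmetric about the tumor surface, matching
        the dilate-minus-erode construction of the zonal-analysis stage.
        """
        pts = np.atleast_2d(pts)
        d = np.linalg.norm(pts - np.asarray(self.tumor_center_um), axis=1)
        out = np.zeros(len(pts), dtype=int)
        if self.tumor_radius_um > 0:
            w2 = self.transition_width_um / 2.0
            out[d <= self.tumor_radius_um + w2] = 1
            out[d <= self.tumor_radius_um - w2] = 2
        return out

    def zone_volumes_um3(self) -> dict[Zone, float]:
        """Analytic zone volumes (shell assumed fully inside the box)."""
        total = float(np.prod(self.domain_size_um))
        if self.tumor_radius_um <= 0:
            return {"normal": total, "transition": 0.0, "tumor": 0.0}
        w2 = self.transition_width_um / 2.0
        r_i = max(self.tumor_radius_um - w2, 0.0)
        r_o = self.tumor_radius_um + w2
        v_i = 4.0 / 3.0 * math.pi * r_i**3
        v_o = 4.0 / 3.0 * math.pi * r_o**3
        return {"normal": total - v_o, "transition": v_o - v_i, "tumor": v_i}


@dataclass
class SignalParams:
    """Signal model parameters for the MGE and DWI simulators.

    Echo times are in ms and R2* in 1/ms, so the decay exponent is unitless.
    The rim boost raises R2* within ``rim_width_vox`` voxels of a vessel,
    emulating the susceptibility gradient at the vessel boundary.
    """

    echo_times_ms: tuple[float, ...] = (4.9, 9.7, 14.5, 19.3)
    s0_tissue: float = 1000.0
    s0_vessel: float = 0.0
    r2star_tissue: float = 0.05   # 1/ms
    rim_delta_r2star: float = 0.03  # 1/ms added within the rim
    rim_width_vox: int = 1
    b_value: float = 1700.0  # s/mm^2
    directions: tuple[tuple[float, float, float], ...] = (
        (1, 1, 0), (1, 0, 1), (0, 1, 1), (-1, 1, 0), (1, 0, -1), (0, -1, 1))

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if len(te) >= 2 and not (np.diff(te) > 0).all():
            raise ValueError("echo times must be strictly increasing")
        if self.b_value <= 0:
            raise ValueError("b-value must be > 0")
        g = np.asarray(self.directions, dtype=float)
        if len(g) >= 2:
            gn = g / np.linalg.norm(g, axis=1, keepdims=True)
            if np.linalg.matrix_rank(gn) < 2:
                raise ValueError("gradient directions are collinear")


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perturb_direction(d: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    v = d + sd * rng.standard_normal(3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else d


def capsule_volume(radius: float, length: float) -> float:
    """Volume of a cylinder of given radius/length with hemispherical caps."""
    return math.pi * radius**2 * length + 4.0 / 3.0 * math.pi * radius**3


def generate_vessel_tree(spec: PhantomSpec, max_attempts: int = 200_000) -> VesselTree:
    """Grow a random branching vessel tree until per-zone target FVs are met.

    Walkers start at random points, step with zone-conditioned log-normal
    lengths and perturbed directions, and occasionally spawn child branches
    from segment endpoints.  Each finished segment is labelled by the zone of
    its midpoint, and its capsule volume is credited against that zone's
    fractional-volume budget; growth stops in a zone once its budget is met.

    Raises ``RuntimeError`` when the targets remain unreachable after
    ``max_attempts`` candidate segments.
    """
    rng = np.random.default_rng(spec.seed)
    dom = np.asarray(spec.domain_size_um, dtype=float)
    zone_vol = spec.zone_volumes_um3()
    budget = {z: spec.zone_params(z).target_fv * zone_vol[z] for z in ZONES}
    filled = {z: 0.0 for z in ZONES}

    segments: list[Segment] = []
    # active walkers: (position, direction, parent segment index)
    walkers: list[tuple[np.ndarray, np.ndarray, int]] = []

    def zone_at(p: np.ndarray) -> Zone:
        return ZONES[spec.zone_of_points(p[None])[0]]

    def need(z: Zone) -> bool:
        return budget[z] > 0 and filled[z] < budget[z]

    def spawn_walker() -> None:
        # bias new roots toward zones still under budget
        for _ in range(50):
            p = rng.uniform(0, 1, 3) * dom
            if need(zone_at(p)):
                break
        d = _random_unit(rng)[0]
        walkers.append((p, d, -1))

    attempts = 0
    while any(need(z) for z in ZONES):
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"vessel-tree growth exhausted {max_attempts} attempts; "
                f"realized FV {filled} vs budget {budget} — lower the targets "
                "or enlarge the domain")
        if not walkers:
            spawn_walker()
        p, d, parent = walkers.pop(rng.integers(len(walkers)))
        zp = spec.zone_params(zone_at(p))
        # log-normal step length parameterized by its mean/sd in µm
        mu = math.log(zp.length_mean_um**2 /
                      math.sqrt(zp.length_mean_um**2 + zp.length_sd_um**2))
        sg = math.sqrt(math.log(1.0 + (zp.length_sd_um / zp.length_mean_um)**2))
        length = float(rng.lognormal(mu, sg))
        radius = float(max(0.2 * zp.radius_mean_um,
                           rng.normal(zp.radius_mean_um, zp.radius_sd_um)))
        d_new = _perturb_direction(d, zp.tortuosity, rng)
        q = p + length * d_new
        if (q < 0).any() or (q > dom).any():
            # walker left the domain; restart elsewhere
            spawn_walker()
            continue
        seg = Segment(p_start=p.copy(), p_end=q, radius=radius,
                      zone=zone_at(0.5 * (p + q)), parent=parent)
        if not need(seg.zone):
            # this zone is full; drop the walker and reseed
            spawn_walker()
            continue
        # credit the *newly added* vessel volume per zone: sample points
        # inside the capsule and discount those already covered by earlier
        # segments, outside the domain, or in another zone — otherwise
        # overlaps and boundary straddling leave every zone under target
        npts = 64
        ts = rng.uniform(0, 1, npts)
        axis_pts = p[None] * (1 - ts[:, None]) + q[None] * ts[:, None]
        rad_dir = _random_unit(rng, npts)
        rad_mag = radius * np.cbrt(rng.uniform(0, 1, npts))
        samples = axis_pts + rad_dir * rad_mag[:, None]
        in_dom = ((samples >= 0) & (samples <= dom)).all(axis=1)
        if segments:
            prev = VesselTree.__new__(VesselTree)
            prev.segments = segments
            covered = _points_in_tree(samples, prev)
        else:
            covered = np.zeros(npts, dtype=bool)
        fresh = in_dom & ~covered
        zidx = spec.zone_of_points(samples)
        vol = capsule_volume(radius, seg.length)
        segments.append(seg)
        for zi, z in enumerate(ZONES):
            filled[z] += vol * float((fresh & (zidx == zi)).sum()) / npts
        idx = len(segments) - 1
        walkers.append((q, d_new, idx))
        # branch with probability raised in tortuous (tumor-like) tissue
        if rng.uniform() < 0.25 + 0.25 * zp.tortuosity:
            walkers.append((q.copy(), _random_unit(rng)[0], idx))
        if len(walkers) > 40:  # cap the frontier so memory stays bounded
            walkers = walkers[-40:]
    return VesselTree(segments=segments)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _segment_distance_field(
    starts: np.ndarray, ends: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Distance of each point to each segment axis: (npts, nseg)."""
    ab = ends - starts                                   # (nseg, 3)
    ab2 = np.einsum("sd,sd->s", ab, ab)
    ap = pts[:, None, :] - starts[None, :, :]            # (npts, nseg, 3)
    t = np.einsum("psd,sd->ps", ap, ab) / ab2[None, :]
    t = np.clip(t, 0.0, 1.0)
    closest = starts[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.linalg.norm(pts[:, None, :] - closest, axis=2)


def rasterize_tree(
    tree: VesselTree,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[Volume3D, Volume3D, Volume3D]:
    """Rasterize a vessel tree onto a voxel grid.

    A voxel is foreground iff its *centre* lies within the radius of some
    segment axis (capsule test: cylinder plus hemispherical caps); there is
    no anti-aliasing, matching the binary ground-truth semantics the Dice
    comparisons need.

    Returns ``(binary mask, segment-label map, radius map)``; the label map
    stores 1-based segment indices (0 = background) of the nearest covering
    segment and the radius map its radius in µm.
    """
    spacing = np.asarray(spacing, dtype=float)
    origin_a = np.asarray(origin, dtype=float)
    binary = np.zeros(shape, dtype=np.uint8)
    labels = np.zeros(shape, dtype=np.int32)
    radius = np.zeros(shape, dtype=np.float32)
    if len(tree) == 0:
        return (
            Volume3D(binary, tuple(spacing), tuple(origin_a), "binary"),
            Volume3D(labels, tuple(spacing), tuple(origin_a), "labels"),
            Volume3D(radius, tuple(spacing), tuple(origin_a), "parametric"),
        )
    starts = np.array([s.p_start for s in tree.segments], dtype=float)
    ends = np.array([s.p_end for s in tree.segments], dtype=float)
    radii = np.array([s.radius for s in tree.segments], dtype=float)

    # per-segment bounding boxes in voxel indices, padded by the radius
    lo_um = np.minimum(starts, ends) - radii[:, None]
    hi_um = np.maximum(starts, ends) + radii[:, None]
    lo = np.floor((lo_um - origin_a) / spacing).astype(int)
    hi = np.ceil((hi_um - origin_a) / spacing).astype(int) + 1
    lo = np.clip(lo, 0, np.asarray(shape))
    hi = np.clip(hi, 0, np.asarray(shape))

    for s in range(len(tree)):
        if (hi[s] <= lo[s]).any():
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[s, 0], hi[s, 0]),
            np.arange(lo[s, 1], hi[s, 1]),
            np.arange(lo[s, 2], hi[s, 2]),
            indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        pts = origin_a + idx * spacing
        d = _segment_distance_field(starts[s : s + 1], ends[s : s + 1], pts)[:, 0]
        inside = d <= radii[s]
        if not inside.any():
            continue
        sel = tuple(idx[inside].T)
        binary[sel] = 1
        # later segments do not overwrite an existing label unless closer
        new = labels[sel] == 0
        lab = labels[sel]
        rad = radius[sel]
        lab[new] = s + 1
        rad[new] = radii[s]
        labels[sel] = lab
        radius[sel] = rad
    return (
        Volume3D(binary, tuple(spacing), tuple(origin_a), "binary"),
        Volume3D(labels, tuple(spacing), tuple(origin_a), "labels"),
        Volume3D(radius, tuple(spacing), tuple(origin_a), "parametric"),
    )


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def _apply_noise(
    signal: np.ndarray,
    model: str,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if model == "none" or sigma == 0:
        return signal
    if model == "gaussian":
        return signal + sigma * rng.standard_normal(signal.shape)
    if model == "rician":
        # magnitude of a complex Gaussian centred on the noiseless signal
        re = signal + sigma * rng.standard_normal(signal.shape)
        im = sigma * rng.standard_normal(signal.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_mge(
    vessels: Volume3D,
    params: SignalParams,
    noise: str = "none",
    snr: float = np.inf,
    seed: int = 0,
    support: Volume3D | None = None,
    r2star_map: np.ndarray | None = None,
) -> list[Volume3D]:
    """Simulate multi-echo gradient-echo magnitude volumes.

    Tissue voxels decay as ``S0_tissue * exp(-R2*_eff * TE)`` where the
    effective R2* gains ``rim_delta_r2star`` within ``rim_width_vox`` voxels
    of a vessel (the susceptibility rim).  Vessel lumen voxels read
    ``s0_vessel`` (≈0: no mobile protons) at every echo.  Voxels outside the
    optional ``support`` mask (the "head" region) have zero signal.  Noise is
    ``gaussian`` or ``rician`` with standard deviation ``s0_tissue / snr``.
    """
    if len(params.echo_times_ms) < 2:
        raise ValueError("simulate_mge needs at least 2 echoes")
    if noise != "none" and snr <= 0:
        raise ValueError(f"SNR must be positive, got {snr}")
    v = np.asarray(vessels.data) > 0
    rim = np.zeros_like(v)
    if params.rim_width_vox > 0:
        rim = ndimage.binary_dilation(v, iterations=params.rim_width_vox) & ~v
    if r2star_map is not None:
        r2 = np.asarray(r2star_map, dtype=float).copy()
    else:
        r2 = np.full(v.shape, params.r2star_tissue, dtype=float)
    r2[rim] += params.rim_delta_r2star
    sup = np.ones(v.shape, dtype=bool) if support is None else np.asarray(support.data) > 0
    rng = np.random.default_rng(seed)
    sigma = 0.0 if noise == "none" or not np.isfinite(snr) else params.s0_tissue / snr
    echoes = []
    for te in params.echo_times_ms:
        s = params.s0_tissue * np.exp(-r2 * te)
        s[v] = params.s0_vessel
        s[~sup] = 0.0
        s = _apply_noise(s, noise, sigma, rng)
        echoes.append(vessels.with_data(s.astype(np.float64), kind="intensity"))
    return echoes


def simulate_dwi(
    tensors: np.ndarray,
    params: SignalParams,
    s0: float | np.ndarray = 1000.0,
    noise: str = "none",
    snr: float = np.inf,
    seed: int = 0,
    spacing: Sequence[float] = (94.0, 97.0, 600.0),
) -> tuple[Volume3D, list[Volume3D]]:
    """Simulate one b0 and one DWI volume per gradient direction.

    ``tensors`` is an array of shape ``(nx, ny, nz, 3, 3)`` of symmetric
    diffusion tensors in mm²/s; signals follow the monoexponential tensor
    model ``S_i = S0 * exp(-b g_iᵀ D g_i)`` with unit-normalized gradients.
    Tensors with negative eigenvalues are rejected.
    """
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim != 5 or tensors.shape[-2:] != (3, 3):
        raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
    if len(params.directions) < 6:
        raise ValueError("need at least 6 gradient directions plus b0")
    evals = np.linalg.eigvalsh(tensors.reshape(-1, 3, 3))
    if (evals < -1e-15).any():
        raise ValueError("requested tensor field is not positive semi-definite")
    g = np.asarray(params.directions, dtype=float)
    g = g / np.linalg.norm(g, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    s0_arr = np.broadcast_to(np.asarray(s0, dtype=float), tensors.shape[:3])
    mean_s0 = float(np.mean(s0_arr)) if np.ndim(s0) else float(s0)
    sigma = 0.0 if noise == "none" or not np.isfinite(snr) else mean_s0 / snr
    b0_data = _apply_noise(s0_arr.copy(), noise, sigma, rng)
    b0 = Volume3D(b0_data, tuple(spacing), kind="intensity")
    dwis = []
    for gi in g:
        adc = np.einsum("i,...ij,j->...", gi, tensors, gi)  # g^T D g
        s = s0_arr * np.exp(-params.b_value * adc)
        dwis.append(Volume3D(_apply_noise(s, noise, sigma, rng),
                             tuple(spacing), kind="intensity"))
    return b0, dwis


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _capsules_intersect(tree: VesselTree) -> bool:
    if len(tree) < 2:
        return False
    starts = np.array([s.p_start for s in tree.segments])
    ends = np.array([s.p_end for s in tree.segments])
    radii = np.array([s.radius for s in tree.segments])
    for i in range(len(tree)):
        # distance from sampled points of segment i to every other axis
        t = np.linspace(0, 1, 9)[:, None]
        pts = starts[i] * (1 - t) + ends[i] * t
        d = _segment_distance_field(starts, ends, pts)
        d[:, i] = np.inf
        if (d < radii[i] + radii[None, :]).any():
            return True
    return False


def _points_in_tree(pts: np.ndarray, tree: VesselTree, block: int = 4096) -> np.ndarray:
    starts = np.array([s.p_start for s in tree.segments])
    ends = np.array([s.p_end for s in tree.segments])
    radii = np.array([s.radius for s in tree.segments])
    out = np.zeros(len(pts), dtype=bool)
    for i in range(0, len(pts), block):
        d = _segment_distance_field(starts, ends, pts[i : i + block])
        out[i : i + block] = (d <= radii[None, :]).any(axis=1)
    return out


def ground_truth_morphometry(
    tree: VesselTree,
    spec: PhantomSpec,
    mc_samples: int = 200_000,
    mc_seed: int = 12345,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Exact per-segment morphometry and per-zone fractional vascular volume.

    Segment lengths and radii are exact (Euclidean).  The whole-domain FV is
    the analytic sum of capsule volumes when no two capsules intersect;
    overlapping trees fall back to seeded Monte-Carlo estimation of the
    union volume.  Per-zone FVs are always Monte-Carlo (capsules straddle
    zone boundaries), except that a zone containing no sampled vessel point
    reports exactly 0.
    """
    rows = [
        {
            "segment": i,
            "length_um": s.length,
            "radius_um": s.radius,
            "zone": s.zone,
            "x0": s.p_start[0], "y0": s.p_start[1], "z0": s.p_start[2],
            "x1": s.p_end[0], "y1": s.p_end[1], "z1": s.p_end[2],
            "parent": s.parent,
        }
        for i, s in enumerate(tree.segments)
    ]
    table = pd.DataFrame(
        rows,
        columns=["segment", "length_um", "radius_um", "zone",
                 "x0", "y0", "z0", "x1", "y1", "z1", "parent"],
    )
    dom_vol = float(np.prod(spec.domain_size_um))
    fv: dict[str, float] = {}
    if len(tree) == 0:
        fv["total"] = 0.0
        for z in ZONES:
            fv[z] = 0.0
        return table, fv

    if not _capsules_intersect(tree):
        fv["total"] = sum(capsule_volume(s.radius, s.length) for s in tree.segments) / dom_vol
    else:
        rng = np.random.default_rng(mc_seed)
        pts = rng.uniform(0, 1, (mc_samples, 3)) * np.asarray(spec.domain_size_um)
        fv["total"] = float(_points_in_tree(pts, tree).mean())

    rng = np.random.default_rng(mc_seed + 1)
    pts = rng.uniform(0, 1, (mc_samples, 3)) * np.asarray(spec.domain_size_um)
    inside = _points_in_tree(pts, tree)
    zidx = spec.zone_of_points(pts)
    present_zones = set(s.zone for s in tree.segments)
    for zi, z in enumerate(ZONES):
        sel = zidx == zi
        if z not in present_zones or not sel.any():
            fv[z] = 0.0
        else:
            fv[z] = float(inside[sel].mean())
    return table, fv
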