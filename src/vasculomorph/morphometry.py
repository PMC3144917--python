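"""Skeleton-based vascular morphometry.

The binary vasculature is reduced to a one-voxel-thick, topology-preserving
centerline (Lee-style 3D thinning), decomposed into branches between
junction and endpoint voxels, and measured:

* *branch length* — the polyline length of consecutive skeleton voxel
  centres in physical µm (axis steps and face/edge/corner diagonals each
  contribute their true Euclidean step);
* *vessel radius* — the Euclidean distance map (EDM) of the binary mask,
  sampled on the skeleton, i.e. the distance from each centerline voxel to
  the nearest background voxel centre;
* *fractional vascular volume* (FV) — the fractional occupancy of the
  binary vasculature inside an ROI, also available on a coarse cell grid
  for cross-modality comparisons.

Partial-volume effects inflate apparent radius and FV on coarse grids; the
measurements here report the digital values without correction, and the
recovery bias on digital cylinders is bounded by about half a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .volume import Volume3D, require_same_grid

_N26 = [
    (di, dj, dk)
    for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]

SEGMENT_COLUMNS = [
    "branch", "n_voxels", "length_um", "mean_radius_um", "max_radius_um",
    "zone", "x0", "y0", "z0", "x1", "y1", "z1",
]


@dataclass
class Branch:
    """An ordered path of skeleton voxels between two node voxels."""

    voxels: np.ndarray  # (n, 3) int indices, ordered start → end
    start_kind: str     # "endpoint" | "junction" | "isolated"
    end_kind: str


@dataclass
class Skeleton:
    """Centerline voxels of a binary structure plus their branch graph."""

    mask: Volume3D          # binary skeleton volume
    branches: list[Branch]
    junctions: np.ndarray   # (nj, 3) voxel indices of junction voxels
    endpoints: np.ndarray   # (ne, 3) voxel indices of endpoint voxels

    def __len__(self) -> int:
        return int(np.asarray(self.mask.data).sum())


def _neighbor_graph(coords: np.ndarray) -> nx.Graph:
    """26-connectivity graph over skeleton voxel coordinates."""
    g = nx.Graph()
    index = {tuple(c): i for i, c in enumerate(coords)}
    g.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for d in _N26:
            j = index.get((c[0] + d[0], c[1] + d[1], c[2] + d[2]))
            if j is not None and j > i:
                g.add_edge(i, j)
    return g


def _extract_branches(coords: np.ndarray, g: nx.Graph) -> tuple[list[Branch], np.ndarray, np.ndarray]:
    deg = dict(g.degree())
    junction = {n for n, d in deg.items() if d >= 3}
    endpoint = {n for n, d in deg.items() if d == 1}
    nodes = junction | endpoint
    # adjacent junction voxels form one junction *node* (digital thinning
    # often leaves 2-3 mutually adjacent high-degree voxels at a furcation)
    cluster_id: dict[int, int] = {}
    clusters = list(nx.connected_components(g.subgraph(junction)))
    for ci, comp in enumerate(sorted(clusters, key=min)):
        for n in comp:
            cluster_id[n] = ci

    def kind(n: int) -> str:
        if n in junction:
            return "junction"
        if n in endpoint:
            return "endpoint"
        return "isolated"

    branches: list[Branch] = []
    visited_edges: set[tuple[int, int]] = set()

    def edge_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for n in sorted(nodes):  # deterministic raster order
        for nb in sorted(g.neighbors(n)):
            if edge_key(n, nb) in visited_edges:
                continue
            path = [n, nb]
            visited_edges.add(edge_key(n, nb))
            cur, prev = nb, n
            while cur not in nodes:
                nxt = [x for x in g.neighbors(cur) if x != prev]
                if not nxt:
                    break
                nxt_n = sorted(nxt)[0]
                if edge_key(cur, nxt_n) in visited_edges:
                    break
                visited_edges.add(edge_key(cur, nxt_n))
                path.append(nxt_n)
                prev, cur = cur, nxt_n
            # drop intra-cluster stubs: both ends in one junction node with
            # at most one interior voxel between them
            a, b = path[0], path[-1]
            if (a in junction and b in junction
                    and cluster_id[a] == cluster_id[b] and len(path) <= 3):
                continue
            branches.append(Branch(
                voxels=coords[np.asarray(path)],
                start_kind=kind(path[0]),
                end_kind=kind(path[-1]),
            ))
    # pure cycles (no nodes at all): walk each untouched component
    left = set(range(len(coords))) - {n for e in visited_edges for n in e}
    left -= nodes
    comp_seen: set[int] = set()
    for n in sorted(left):
        if n in comp_seen or deg.get(n, 0) == 0:
            comp_seen.add(n)
            continue
        cyc = [n]
        comp_seen.add(n)
        prev, cur = n, sorted(g.neighbors(n))[0]
        while cur != n:
            cyc.append(cur)
            comp_seen.add(cur)
            nxt = [x for x in g.neighbors(cur) if x != prev]
            if not nxt:
                break
            prev, cur = cur, sorted(nxt)[0]
        branches.append(Branch(voxels=coords[np.asarray(cyc)],
                               start_kind="isolated", end_kind="isolated"))
    # one representative voxel per junction cluster
    if clusters:
        junc = coords[[min(comp) for comp in sorted(clusters, key=min)]]
    else:
        junc = np.empty((0, 3), dtype=int)
    ends = coords[sorted(endpoint)] if endpoint else np.empty((0, 3), dtype=int)
    return branches, junc, ends


def skeletonize(binary: Volume3D, prune_spurs: bool = True, spur_len: int = 2) -> Skeleton:
    """Topology-preserving 3D thinning to a one-voxel-thick centerline.

    Branch decomposition classifies skeleton voxels by 26-neighbour degree
    (1 = endpoint, ≥3 = junction) and walks the degree-2 chains between
    them.  Spur branches of at most ``spur_len`` voxels beyond a junction —
    artifacts of digital thinning — are pruned by default.
    """
    fg = np.asarray(binary.data) > 0
    if not fg.any():
        empty = binary.with_data(np.zeros_like(fg, dtype=np.uint8), kind="binary")
        return Skeleton(mask=empty, branches=[],
                        junctions=np.empty((0, 3), dtype=int),
                        endpoints=np.empty((0, 3), dtype=int))
    skel = _sk_skeletonize(fg)  # Lee et al. thinning for 3D input
    coords = np.argwhere(skel)
    g = _neighbor_graph(coords)
    branches, junc, ends = _extract_branches(coords, g)

    if prune_spurs and junc.size:
        keep: list[Branch] = []
        removed = np.zeros(fg.shape, dtype=bool)
        for b in branches:
            is_spur = (
                {b.start_kind, b.end_kind} == {"junction", "endpoint"}
                and len(b.voxels) <= spur_len + 1  # path includes the junction voxel
            )
            if is_spur:
                interior = b.voxels[1:] if b.start_kind == "junction" else b.voxels[:-1]
                removed[tuple(interior.T)] = True
            else:
                keep.append(b)
        if removed.any():
            skel = skel & ~removed
            coords = np.argwhere(skel)
            g = _neighbor_graph(coords)
            branches, junc, ends = _extract_branches(coords, g)

    return Skeleton(
        mask=binary.with_data(skel.astype(np.uint8), kind="binary"),
        branches=branches, junctions=junc, endpoints=ends,
    )


def branch_lengths(skel: Skeleton, spacing: tuple[float, float, float] | None = None) -> pd.DataFrame:
    """Polyline length of each branch in physical µm."""
    sp = np.asarray(spacing if spacing is not None else skel.mask.spacing, dtype=float)
    rows = []
    for i, b in enumerate(skel.branches):
        steps = np.diff(b.voxels.astype(float), axis=0) * sp
        length = float(np.linalg.norm(steps, axis=1).sum())
        p0 = skel.mask.voxel_to_physical(b.voxels[0])
        p1 = skel.mask.voxel_to_physical(b.voxels[-1])
        rows.append({
            "branch": i, "n_voxels": len(b.voxels), "length_um": length,
            "x0": p0[0], "y0": p0[1], "z0": p0[2],
            "x1": p1[0], "y1": p1[1], "z1": p1[2],
        })
    return pd.DataFrame(rows, columns=["branch", "n_voxels", "length_um",
                                       "x0", "y0", "z0", "x1", "y1", "z1"])


def distance_map(binary: Volume3D) -> Volume3D:
    """Anisotropy-aware exact Euclidean distance transform in µm.

    Each foreground voxel gets the distance from its centre to the nearest
    *background voxel centre*; the map is 0 outside the foreground.
    """
    fg = np.asarray(binary.data) > 0
    if not fg.any():
        return binary.with_data(np.zeros(fg.shape), kind="parametric")
    edm = ndimage.distance_transform_edt(fg, sampling=binary.spacing)
    return binary.with_data(np.asarray(edm, dtype=float), kind="parametric")


def vessel_radii(skel: Skeleton, edm: Volume3D) -> pd.DataFrame:
    """Per-branch mean/max radius: the EDM sampled along the centerline."""
    require_same_grid(skel.mask, edm, "skeleton and distance map")
    e = np.asarray(edm.data, dtype=float)
    rows = []
    for i, b in enumerate(skel.branches):
        vals = e[tuple(b.voxels.T)]
        if (vals <= 0).any():
            raise ValueError(
                f"branch {i}: skeleton voxel outside the distance-map foreground")
        rows.append({"branch": i, "mean_radius_um": float(vals.mean()),
                     "max_radius_um": float(vals.max())})
    return pd.DataFrame(rows, columns=["branch", "mean_radius_um", "max_radius_um"])


def branch_table(skel: Skeleton, edm: Volume3D | None = None) -> pd.DataFrame:
    """Combined per-branch morphometry (lengths, and radii when EDM given)."""
    t = branch_lengths(skel)
    if edm is not None:
        t = t.merge(vessel_radii(skel, edm), on="branch")
    return t


def fractional_volume(binary: Volume3D, roi: Volume3D) -> float:
    """Fraction of ROI voxels occupied by the binary vasculature."""
    require_same_grid(binary, roi, "vessels and ROI")
    r = np.asarray(roi.data) > 0
    n_roi = int(r.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    v = np.asarray(binary.data) > 0
    return float((v & r).sum() / n_roi)


def coarse_grid_fv(
    binary: Volume3D, grid_dims: tuple[int, int, int]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell fractional occupancy on a coarse grid.

    The volume is split into ``grid_dims`` cells along each axis; the last
    cell of an axis absorbs the division remainder.  The occupancies
    recompose exactly: sum over cells of occupancy × cell voxel count equals
    the global vessel voxel count.
    """
    shape = np.asarray(binary.shape)
    dims = np.asarray(grid_dims, dtype=int)
    if (dims > shape).any():
        raise ValueError(f"more cells {tuple(dims)} than voxels {tuple(shape)}")
    v = np.asarray(binary.data) > 0
    edges = [np.linspace(0, shape[a], dims[a] + 1).astype(int) for a in range(3)]
    # make edges exact integer blocks with the remainder in the last cell
    for a in range(3):
        step = shape[a] // dims[a]
        edges[a] = np.array([i * step for i in range(dims[a])] + [shape[a]])
    fv = np.zeros(tuple(dims))
    rows = []
    sp = np.asarray(binary.spacing)
    org = np.asarray(binary.origin)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                sl = (slice(edges[0][i], edges[0][i + 1]),
                      slice(edges[1][j], edges[1][j + 1]),
                      slice(edges[2][k], edges[2][k + 1]))
                cell = v[sl]
                fv[i, j, k] = cell.mean()
                lo = np.array([edges[0][i], edges[1][j], edges[2][k]])
                hi = np.array([edges[0][i + 1], edges[1][j + 1], edges[2][k + 1]])
                lo_um = org + (lo - 0.5) * sp
                hi_um = org + (hi - 0.5) * sp
                rows.append({
                    "i": i, "j": j, "k": k,
                    "fv": float(fv[i, j, k]), "n_voxels": int(cell.size),
                    "x_lo_um": lo_um[0], "y_lo_um": lo_um[1], "z_lo_um": lo_um[2],
                    "x_hi_um": hi_um[0], "y_hi_um": hi_um[1], "z_hi_um": hi_um[2],
                })
    return fv, pd.DataFrame(rows)
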