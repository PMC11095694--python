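"""Tunnel detection from a buried start point to the bulk solvent.

The void space is discretized on a regular grid carrying the *free radius*
field: for each voxel center, the distance to the nearest atom surface
(negative inside an atom).  Bulk solvent is the region a probe of
``shell_radius`` can reach from outside, eroded inward by ``shell_depth``
so that shallow surface dimples do not count as tunnel mouths.  Tunnels
are minimum-cost paths from the start voxel to each distinct bulk-contact
region, found by Dijkstra search with a per-step cost ``ds / r**2`` that
prefers short, wide corridors.

Throughput maps path cost into (0, 1]: ``exp(-cost * 1 Å² / d)`` where
``d`` is the straight start-to-exit distance.  For a straight cylindrical
channel of radius r this reduces to ``exp(-1/r²)``, independent of length;
detours and constrictions only lower it.  The score reproduces the
qualitative ordering of tunnel-ranking tools; absolute values are not
comparable across packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .structures import MolecularStructure

__all__ = [
    "GridMap",
    "TunnelPath",
    "TunnelCluster",
    "free_radius_map",
    "find_tunnels",
    "tunnel_profile",
    "resample_centerline",
    "cluster_tunnels",
    "cluster_statistics",
]

COST_EPSILON = 0.05  # Å; floor for the radius in the cost denominator


@dataclass
class GridMap:
    """Regular grid of the free-radius field (Å)."""

    origin: np.ndarray
    spacing: float
    free_radius: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.free_radius.shape

    def voxel_center(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(ijk) + 0.5) * self.spacing

    def voxel_of(self, point: np.ndarray) -> np.ndarray:
        ijk = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return np.clip(ijk, 0, np.array(self.shape) - 1)


@dataclass
class TunnelPath:
    """A single tunnel: centerline with per-point free radii."""

    centerline: np.ndarray  # (n_points, 3), start -> exit
    radii: np.ndarray  # (n_points,)
    cost: float
    snapshot: int = 0
    bottleneck_radius: float = field(init=False)
    length: float = field(init=False)
    curvature: float = field(init=False)
    throughput: float = field(init=False)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.centerline) != len(self.radii) or len(self.centerline) < 2:
            raise ValueError("centerline and radii must align and have >= 2 points")
        self.bottleneck_radius = float(self.radii.min())
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        self.length = float(seg.sum())
        straight = float(np.linalg.norm(self.centerline[-1] - self.centerline[0]))
        self.curvature = self.length / straight if straight > 0 else np.inf
        d = max(straight, 1e-9)
        self.throughput = float(np.exp(-self.cost / d))


@dataclass
class TunnelCluster:
    """A family of tunnels recurring across snapshots."""

    members: list[TunnelPath]
    priority: float


def free_radius_map(
    structure: MolecularStructure,
    spacing: float = 0.4,
    padding: float = 8.0,
) -> GridMap:
    """Free-radius field on a regular grid over the padded bounding box.

    Each voxel value is ``min over atoms of (|voxel - center| - radius)``,
    exact at the voxel center (spatial indexing per distinct radius value,
    so unequal radii are handled without approximation).
    """
    if structure.n_atoms == 0:
        raise ValueError("cannot grid an empty structure")
    if not (0.2 < spacing <= 1.0):
        raise ValueError(f"spacing must be in (0.2, 1.0] Å, got {spacing}")
    coords = structure.coords
    radii = structure.radii()
    origin = coords.min(axis=0) - padding
    upper = coords.max(axis=0) + padding
    shape = np.ceil((upper - origin) / spacing).astype(int)
    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    points = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)

    best = np.full(points.shape[0], np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        dist, _ = tree.query(points, workers=-1)
        np.minimum(best, dist - r, out=best)
    return GridMap(origin=origin, spacing=spacing, free_radius=best.reshape(shape))


_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
)


def _stop_region(grid: GridMap, shell_radius: float, shell_depth: float) -> np.ndarray:
    """Voxels belonging to bulk solvent or the surface shell layer.

    Bulk is the region a probe of ``shell_radius`` reaches from the grid
    boundary; the shell layer extends ``shell_depth`` inward from it.
    Tunnels run through the void *deeper* than this region and terminate
    on first contact with it — paths may never crawl along the outside of
    the structure.
    """
    probe_ok = grid.free_radius >= shell_radius
    labels, _ = ndimage.label(probe_ok, structure=np.ones((3, 3, 3), dtype=int))
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    outside = np.isin(labels, sorted(border_labels)) if border_labels else np.zeros_like(probe_ok)
    if not outside.any():
        return outside
    dist_to_bulk = ndimage.distance_transform_edt(~outside, sampling=grid.spacing)
    return outside | (dist_to_bulk <= shell_depth)


def _voxel_graph(passable_flat: np.ndarray, shape: tuple[int, int, int],
                 inv_r2: np.ndarray, spacing: float) -> tuple[coo_matrix, np.ndarray]:
    """Sparse 26-neighbor graph over passable voxels.

    Edge cost is the step length times the mean of 1/max(r, eps)^2 at the
    two endpoints.  Returns the graph and the passable-voxel flat indices.
    """
    nodes = np.flatnonzero(passable_flat)
    node_id = np.full(passable_flat.size, -1, dtype=np.int64)
    node_id[nodes] = np.arange(nodes.size)
    ijk = np.stack(np.unravel_index(nodes, shape), axis=1)
    rows, cols, costs = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        nbr = ijk + off
        valid = np.all((nbr >= 0) & (nbr < np.array(shape)), axis=1)
        src = nodes[valid]
        dst = np.ravel_multi_index(tuple(nbr[valid].T), shape)
        ok = passable_flat[dst]
        src, dst = src[ok], dst[ok]
        step = spacing * float(np.linalg.norm(off))
        w = step * 0.5 * (inv_r2[src] + inv_r2[dst])
        rows.append(node_id[src])
        cols.append(node_id[dst])
        costs.append(w)
    graph = coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nodes.size, nodes.size),
    ).tocsr()
    return graph, nodes


def find_tunnels(
    structure: MolecularStructure,
    start_point: np.ndarray,
    min_probe: float = 0.9,
    shell_radius: float = 3.0,
    shell_depth: float = 4.0,
    spacing: float = 0.4,
    max_tunnels: int = 10,
    padding: float | None = None,
    snapshot: int = 0,
    grid: GridMap | None = None,
) -> list[TunnelPath]:
    """Find tunnels from ``start_point`` to the bulk solvent.

    The start point is first snapped to the widest voxel within 3 Å (so a
    start placed on an atom, e.g. the heme iron, moves into the adjacent
    void).  Paths whose bottleneck is below ``min_probe`` are discarded;
    the rest are returned sorted by decreasing throughput.
    """
    if grid is None:
        if padding is None:
            padding = shell_radius + shell_depth + 1.0
        grid = free_radius_map(structure, spacing=spacing, padding=padding)
    F = grid.free_radius
    shape = F.shape
    flatF = F.ravel()

    # Snap the start to the most open voxel within 3 Å.
    start_ijk = grid.voxel_of(start_point)
    reach = max(1, int(np.ceil(3.0 / grid.spacing)))
    lo = np.maximum(start_ijk - reach, 0)
    hi = np.minimum(start_ijk + reach + 1, shape)
    sub = F[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ijk_local = np.stack(np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"), axis=-1)
    centers = grid.origin + (ijk_local + 0.5) * grid.spacing
    within = np.linalg.norm(centers - np.asarray(start_point), axis=-1) <= 3.0
    masked = np.where(within, sub, -np.inf)
    best_local = np.unravel_index(np.argmax(masked), masked.shape)
    start_ijk = np.array([lo[d] + best_local[d] for d in range(3)])
    if F[tuple(start_ijk)] <= 0:
        raise ValueError("start point lies inside an atom (free radius <= 0) and no open voxel is within 3 Å")

    stop = _stop_region(grid, shell_radius, shell_depth)
    if not stop.any():
        return []
    interior = (flatF > 0.0) & ~stop.ravel()
    inv_r2 = 1.0 / np.maximum(flatF, COST_EPSILON) ** 2
    graph, nodes = _voxel_graph(interior, shape, inv_r2, grid.spacing)
    node_id = np.full(flatF.size, -1, dtype=np.int64)
    node_id[nodes] = np.arange(nodes.size)

    start_flat = np.ravel_multi_index(tuple(start_ijk), shape)
    if node_id[start_flat] < 0:
        raise ValueError("start point is not inside the structure's buried void space")
    dist, predecessors = csgraph_dijkstra(
        graph, indices=node_id[start_flat], return_predecessors=True, directed=False
    )

    # Exit candidates: reachable interior voxels adjacent to void in the
    # bulk/shell region (the tunnel continues into solvent there).
    stop_void = stop & (F > 0.0)
    near_stop = ndimage.binary_dilation(stop_void, structure=np.ones((3, 3, 3), dtype=bool))
    reachable = np.zeros(flatF.size, dtype=bool)
    reachable[nodes[np.isfinite(dist)]] = True
    boundary = np.flatnonzero(interior & near_stop.ravel() & reachable)
    if boundary.size == 0:
        return []

    # Distinct exits: connected components of the boundary voxels (the
    # mouths of different tunnels are separated by protein or by the stop
    # region).  Exits whose cheapest voxels lie within shell_radius of a
    # cheaper exit are merged into it.
    boundary_mask = np.zeros(flatF.size, dtype=bool)
    boundary_mask[boundary] = True
    labels, n_regions = ndimage.label(
        boundary_mask.reshape(shape), structure=np.ones((3, 3, 3), dtype=int)
    )
    flat_labels = labels.ravel()
    candidates = []
    for region in range(1, n_regions + 1):
        region_nodes = np.flatnonzero(flat_labels == region)
        costs = dist[node_id[region_nodes]]
        k = int(np.argmin(costs))
        candidates.append((float(costs[k]), int(region_nodes[k])))
    candidates.sort()
    kept: list[tuple[float, int]] = []
    kept_points: list[np.ndarray] = []
    for cost, exit_flat in candidates:
        p = grid.voxel_center(np.array(np.unravel_index(exit_flat, shape)))
        if any(np.linalg.norm(p - q) <= shell_radius for q in kept_points):
            continue
        kept.append((cost, exit_flat))
        kept_points.append(p)

    paths = []
    for cost, exit_flat in kept:
        node_path = []
        cur = node_id[exit_flat]
        while cur >= 0:
            node_path.append(cur)
            cur = predecessors[cur]
        node_path.reverse()
        flat_path = nodes[node_path]
        centerline = grid.voxel_center(np.stack(np.unravel_index(flat_path, shape), axis=1))
        radii = flatF[flat_path]
        if len(centerline) < 2:
            continue
        path = TunnelPath(centerline=centerline, radii=radii, cost=cost, snapshot=snapshot)
        if path.bottleneck_radius >= min_probe:
            paths.append(path)

    paths.sort(key=lambda p: p.throughput, reverse=True)
    return paths[:max_tunnels]


def resample_centerline(path: TunnelPath, n_points: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline and radii resampled at equal arclength.

    Returns (arclengths, points, radii), each with ``n_points`` entries.
    """
    if n_points < 2:
        raise ValueError("need at least 2 resample points")
    seg = np.linalg.norm(np.diff(path.centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n_points)
    points = np.stack([np.interp(target, s, path.centerline[:, d]) for d in range(3)], axis=1)
    radii = np.interp(target, s, path.radii)
    return target, points, radii


def tunnel_profile(path: TunnelPath, resample: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """(arclength, radius) series resampled at equal arclength intervals."""
    s, _, r = resample_centerline(path, resample)
    return s, r


def cluster_tunnels(
    paths: list[TunnelPath],
    threshold: float = 3.5,
    resample: int = 20,
    n_snapshots: int | None = None,
) -> list[TunnelCluster]:
    """Group tunnels into pathway families by average-link clustering.

    The pairwise tunnel distance is the mean Euclidean distance between
    corresponding equal-arclength centerline points; the average-linkage
    dendrogram is cut at ``threshold`` (Å).  Clusters are ordered by
    priority: the mean member throughput over all snapshots, where
    snapshots with no member contribute zero.
    """
    if not paths:
        raise ValueError("no tunnels to cluster")
    if n_snapshots is None:
        n_snapshots = max(len({p.snapshot for p in paths}), 1)
    pts = np.stack([resample_centerline(p, resample)[1] for p in paths])
    if len(paths) == 1:
        assignments = np.array([1])
    else:
        diffs = pts[:, None, :, :] - pts[None, :, :, :]
        dmat = np.linalg.norm(diffs, axis=-1).mean(axis=-1)
        Z = linkage(squareform(dmat, checks=False), method="average")
        assignments = fcluster(Z, t=threshold, criterion="distance")
    clusters = []
    for label in np.unique(assignments):
        members = [p for p, a in zip(paths, assignments) if a == label]
        priority = sum(p.throughput for p in members) / n_snapshots
        clusters.append(TunnelCluster(members=members, priority=priority))
    clusters.sort(key=lambda c: c.priority, reverse=True)
    return clusters


def cluster_statistics(cluster: TunnelCluster, n_snapshots: int) -> dict[str, float]:
    """Summary row for one tunnel cluster (population std. devs.).

    ``priority`` divides the summed throughput by ``n_snapshots`` so that
    snapshots where the pathway is absent drag it down; ``occurrence`` is
    the fraction of snapshots in which the pathway appears at all.
    """
    if not cluster.members:
        raise ValueError("empty tunnel cluster")
    tags = {p.snapshot for p in cluster.members}
    if n_snapshots < len(tags):
        raise ValueError("n_snapshots smaller than the number of distinct snapshot tags")
    bn = np.array([p.bottleneck_radius for p in cluster.members])
    ln = np.array([p.length for p in cluster.members])
    cv = np.array([p.curvature for p in cluster.members])
    tp = np.array([p.throughput for p in cluster.members])
    return {
        "n_members": float(len(cluster.members)),
        "avg_bottleneck": float(bn.mean()),
        "std_bottleneck": float(bn.std()),
        "max_bottleneck": float(bn.max()),
        "avg_length": float(ln.mean()),
        "std_length": float(ln.std()),
        "avg_curvature": float(cv.mean()),
        "std_curvature": float(cv.std()),
        "avg_throughput": float(tp.mean()),
        "std_throughput": float(tp.std()),
        "priority": float(tp.sum() / n_snapshots),
        "occurrence": float(len(tags) / n_snapshots),
    }
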