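"""Alpha-sphere pocket detection with Monte-Carlo volumes.

An alpha sphere is tangent to four atoms: its center is a Voronoi vertex
of the atom centers and its radius the common center-to-atom distance.
Vertices are found as Delaunay-tetrahedron circumcenters (the dual
construction, which also yields the four defining atoms directly).
Medium-radius spheres — by default 3.4 Å to 6.2 Å, measured to atom
*centers* — sit in concavities the right size for ligand binding; tight
clusters of at least 15 of them define pockets.

Pocket volume is estimated by rejection sampling over the sphere union's
bounding box, counting points inside at least one alpha sphere and
outside every atom (a solvent-accessible void volume), with the binomial
standard error reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .structures import MolecularStructure

__all__ = [
    "AlphaSphere",
    "Pocket",
    "alpha_spheres",
    "cluster_spheres",
    "pocket_volume",
    "pocket_hydrophobicity",
    "pockets_near",
]

APOLAR_ELEMENTS = {"C", "S"}


@dataclass
class AlphaSphere:
    center: np.ndarray
    radius: float
    defining_atoms: tuple[int, int, int, int]


@dataclass
class Pocket:
    spheres: list[AlphaSphere]
    centroid: np.ndarray
    volume: float | None = None
    volume_stderr: float | None = None
    hydrophobicity: float | None = None
    lining_atoms: np.ndarray | None = None

    @property
    def n_spheres(self) -> int:
        return len(self.spheres)


def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and circumradii of Delaunay tetrahedra (vectorized)."""
    a = points[simplices[:, 0]]
    rel = points[simplices[:, 1:]] - a[:, None, :]  # (m, 3, 3)
    sq = (rel ** 2).sum(axis=2)  # (m, 3)
    # Solve 2 * rel @ x = |rel|^2 for the center offset x from vertex a.
    centers = np.full((len(simplices), 3), np.nan)
    dets = np.linalg.det(rel)
    good = np.abs(dets) > 1e-10
    centers[good] = np.linalg.solve(2.0 * rel[good], sq[good][..., None])[..., 0]
    radii = np.linalg.norm(centers, axis=1)
    return a + centers, radii


def alpha_spheres(
    structure: MolecularStructure,
    rmin: float = 3.4,
    rmax: float = 6.2,
    heavy_only: bool = True,
) -> list[AlphaSphere]:
    """Candidate alpha spheres of a structure.

    Spheres outside [rmin, rmax] or centered outside the atom cloud's
    convex hull are discarded.  Radii are measured to atom centers.
    """
    if heavy_only:
        idx = np.array([i for i, a in enumerate(structure.atoms) if a.element.upper() != "H"])
    else:
        idx = np.arange(structure.n_atoms)
    if idx.size < 5:
        raise ValueError("need at least 5 heavy atoms for alpha-sphere detection")
    points = structure.coords[idx]
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError(
            "Voronoi tessellation failed (degenerate, e.g. coplanar, input); "
            "jitter the coordinates or supply a 3D structure"
        ) from exc
    centers, radii = _circumcenters(points, tri.simplices)
    ok = np.isfinite(radii) & (radii >= rmin) & (radii <= rmax)
    # Drop circumcenters outside the convex hull (they describe exterior
    # space, not pockets).
    inside = tri.find_simplex(centers[ok]) >= 0
    spheres = []
    for simplex, center, radius in zip(
        tri.simplices[ok][inside], centers[ok][inside], radii[ok][inside]
    ):
        spheres.append(AlphaSphere(
            center=center,
            radius=float(radius),
            defining_atoms=tuple(int(idx[v]) for v in simplex),
        ))
    return spheres


def cluster_spheres(
    spheres: list[AlphaSphere],
    link_cutoff: float = 1.8,
    min_spheres: int = 15,
) -> list[Pocket]:
    """Single-linkage clustering of sphere centers into pockets.

    Components joined below ``link_cutoff`` (Å, Euclidean) form one
    pocket; components with fewer than ``min_spheres`` members are
    discarded.  Pockets are returned largest (most spheres) first.
    """
    if not spheres:
        return []
    centers = np.array([s.center for s in spheres])
    if len(spheres) == 1:
        assignments = np.array([1])
    else:
        Z = linkage(pdist(centers), method="single")
        assignments = fcluster(Z, t=link_cutoff, criterion="distance")
    pockets = []
    for label in np.unique(assignments):
        members = [s for s, a in zip(spheres, assignments) if a == label]
        if len(members) < min_spheres:
            continue
        centroid = np.mean([s.center for s in members], axis=0)
        pockets.append(Pocket(spheres=members, centroid=centroid))
    pockets.sort(key=lambda p: p.n_spheres, reverse=True)
    return pockets


def pocket_volume(
    pocket: Pocket,
    structure: MolecularStructure | None,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo volume of the pocket's alpha-sphere union, Å³.

    Uniform samples over the union's bounding box count when they fall
    inside at least one alpha sphere and outside every atom sphere (pass
    ``structure=None`` to skip atom exclusion).  Returns (volume,
    binomial standard error); a fixed seed is bit-reproducible.
    """
    if n_samples < 10_000:
        raise ValueError("need at least 1e4 samples for a stable estimate")
    centers = np.array([s.center for s in pocket.spheres])
    radii = np.array([s.radius for s in pocket.spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box = hi - lo
    box_volume = float(np.prod(box))
    if box_volume <= 0:
        raise ValueError("zero-extent bounding box")
    rng = np.random.default_rng(seed)
    samples = lo + rng.random((n_samples, 3)) * box
    tree = cKDTree(centers)
    pairs = tree.query_ball_point(samples, r=float(radii.max()), workers=-1)
    inside = np.zeros(n_samples, dtype=bool)
    for i, cand in enumerate(pairs):
        if cand:
            d = np.linalg.norm(samples[i] - centers[cand], axis=1)
            inside[i] = bool(np.any(d <= radii[cand]))
    if structure is not None and structure.n_atoms:
        coords = structure.coords
        vdw = structure.radii()
        atom_tree = cKDTree(coords)
        hit_idx = np.flatnonzero(inside)
        if hit_idx.size:
            near = atom_tree.query_ball_point(samples[hit_idx], r=float(vdw.max()), workers=-1)
            for row, cand in zip(hit_idx, near):
                if cand:
                    d = np.linalg.norm(samples[row] - coords[cand], axis=1)
                    if np.any(d < vdw[cand]):
                        inside[row] = False
    p = inside.mean()
    volume = p * box_volume
    stderr = box_volume * float(np.sqrt(p * (1.0 - p) / n_samples))
    return float(volume), stderr


def pocket_hydrophobicity(
    pocket: Pocket,
    structure: MolecularStructure,
    contact_cutoff: float = 2.0,
) -> float:
    """Apolar fraction of the pocket's lining atoms.

    Lining atoms lie within ``contact_cutoff`` of any alpha-sphere
    surface; apolar means element C or S.  This is a simple proxy
    hydrophobicity score, not comparable to any external tool's scale.
    """
    coords = structure.coords
    centers = np.array([s.center for s in pocket.spheres])
    radii = np.array([s.radius for s in pocket.spheres])
    d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    lining = np.flatnonzero((d <= radii[None, :] + contact_cutoff).any(axis=1))
    if lining.size == 0:
        raise ValueError("pocket has no lining atoms at this cutoff")
    pocket.lining_atoms = lining
    apolar = sum(1 for i in lining if structure.atoms[i].element.upper() in APOLAR_ELEMENTS)
    frac = apolar / lining.size
    pocket.hydrophobicity = frac
    return frac


def pockets_near(pockets: list[Pocket], point: np.ndarray, cutoff: float) -> list[Pocket]:
    """Pockets whose centroid lies within ``cutoff`` (inclusive) of a
    point — e.g. near the heme iron.  Input order is preserved."""
    point = np.asarray(point, dtype=float)
    return [p for p in pockets if np.linalg.norm(p.centroid - point) <= cutoff]
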