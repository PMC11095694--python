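"""Superposition-based trajectory metrics.

RMSD/RMSF use least-squares (Kabsch) superposition; PCA operates on
cartesian backbone coordinates after superposing every frame onto the
iterated ensemble mean, the standard essential-dynamics convention.  The
radial distribution function uses minimum-image distances when the
trajectory carries an orthorhombic box, and otherwise requires an
explicit bulk-density override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import MolecularStructure, Trajectory

__all__ = [
    "kabsch",
    "superpose",
    "rmsd_series",
    "rmsf",
    "atom_rmsf",
    "PCAResult",
    "pca",
    "porcupine",
    "rdf",
    "smooth_trajectory",
]


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD.
    The rotation is proper (det = +1).  Collinear point sets raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    H = (w[:, None] * m0).T @ r0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate geometry: points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = m0 @ R.T
    rmsd = float(np.sqrt((w[:, None] * (moved - r0) ** 2).sum()))
    return R, t, rmsd


def superpose(frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto *reference* using the fit atoms;
    returns transformed copies of the full frames."""
    out = np.empty_like(frames)
    for k in range(frames.shape[0]):
        R, t, _ = kabsch(frames[k, fit_idx], reference[fit_idx])
        out[k] = frames[k] @ R.T + t
    return out


def _resolve(obj: MolecularStructure, selection: str | np.ndarray) -> np.ndarray:
    if isinstance(selection, str):
        idx = obj.select(selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def rmsd_series(
    trajectory: Trajectory,
    reference: MolecularStructure,
    fit_selection: str | np.ndarray = "name CA",
    calc_selection: str | np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) from a reference structure.

    Each frame is first superposed on the reference over
    ``fit_selection``; the RMSD is then computed over ``calc_selection``
    (defaults to the fit selection), mirroring 'calculated from the
    reference X-ray structure' conventions.
    """
    fit_idx = _resolve(reference, fit_selection)
    calc_idx = fit_idx if calc_selection is None else _resolve(reference, calc_selection)
    ref = reference.coords
    out = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        R, t, _ = kabsch(trajectory.frames[k, fit_idx], ref[fit_idx])
        moved = trajectory.frames[k, calc_idx] @ R.T + t
        out[k] = np.sqrt(((moved - ref[calc_idx]) ** 2).sum(axis=1).mean())
    return out


def _iterated_mean_superpose(
    frames: np.ndarray, fit_idx: np.ndarray, iterations: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames onto their iterated ensemble mean; returns
    (superposed frames, mean coordinates)."""
    ref = frames[0]
    current = frames
    for _ in range(iterations):
        current = superpose(current, ref, fit_idx)
        ref = current.mean(axis=0)
    return current, ref


def atom_rmsf(
    trajectory: Trajectory,
    selection: str | np.ndarray = "name CA",
    fit_selection: str | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom RMSF (Å) about the ensemble-mean position after
    superposition.  Returns (atom indices, values)."""
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    sel_idx = _resolve(trajectory.topology, selection)
    fit_idx = sel_idx if fit_selection is None else _resolve(trajectory.topology, fit_selection)
    frames, mean = _iterated_mean_superpose(trajectory.frames, fit_idx)
    dev = frames[:, sel_idx, :] - mean[sel_idx]
    values = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return sel_idx, values


def rmsf(
    trajectory: Trajectory,
    selection: str | np.ndarray = "name CA",
    fit_selection: str | np.ndarray | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (Å).

    The residue value is its C-alpha atom's RMSF when a CA is selected,
    otherwise the mean over the residue's selected atoms.  Restrict the
    selection (e.g. ``"name CA and not resnum 29-49"``) to omit noisy
    termini from the profile.
    """
    sel_idx, values = atom_rmsf(trajectory, selection, fit_selection)
    atoms = trajectory.topology.atoms
    per_res: dict[tuple[str, int], list[tuple[str, float]]] = {}
    for i, v in zip(sel_idx, values):
        a = atoms[i]
        per_res.setdefault((a.chain_id, a.residue_number), []).append((a.name.upper(), float(v)))
    out: dict[tuple[str, int], float] = {}
    for key, entries in per_res.items():
        ca = [v for name, v in entries if name == "CA"]
        out[key] = ca[0] if ca else float(np.mean([v for _, v in entries]))
    return out


@dataclass
class PCAResult:
    """Cartesian-coordinate principal components of a superposed ensemble."""

    mean_coordinates: np.ndarray  # (n_sel, 3)
    eigenvalues: np.ndarray  # (k,), Å², descending
    modes: np.ndarray  # (k, n_sel, 3), orthonormal
    projections: np.ndarray  # (n_frames, k), Å
    frame_tags: np.ndarray  # (n_frames,), source-trajectory index
    atom_indices: np.ndarray


def pca(
    trajectories: Trajectory | list[Trajectory],
    selection: str | np.ndarray = "name N CA C O",
) -> PCAResult:
    """Principal component analysis of cartesian coordinates.

    Frames from all trajectories are pooled (``frame_tags`` records the
    source, so e.g. bound and unbound ensembles can be projected apart),
    superposed onto the iterated pooled mean, and the positional
    covariance is eigen-decomposed.  Mode signs are fixed so each mode's
    largest-magnitude component is positive.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("no trajectories given")
    sel_idx = _resolve(trajectories[0].topology, selection)
    pools, tags = [], []
    for tag, traj in enumerate(trajectories):
        idx = _resolve(traj.topology, selection)
        if idx.size != sel_idx.size:
            raise ValueError("selection sizes differ between trajectories")
        pools.append(traj.frames[:, idx, :])
        tags.append(np.full(traj.n_frames, tag))
    frames = np.concatenate(pools, axis=0)
    tags = np.concatenate(tags)
    n_frames, n_sel = frames.shape[0], frames.shape[1]
    if n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    if n_frames <= 3 * n_sel:
        import warnings

        warnings.warn(
            f"only {n_frames} frames for {n_sel} atoms (3N = {3 * n_sel}); "
            "covariance is rank-deficient",
            stacklevel=2,
        )
    fit_all = np.arange(n_sel)
    frames, mean = _iterated_mean_superpose(frames, fit_all)
    X = (frames - mean).reshape(n_frames, 3 * n_sel)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = S ** 2 / n_frames
    modes = Vt  # (k, 3N), orthonormal rows
    # Deterministic sign: largest-magnitude component positive.
    for row in modes:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    projections = X @ modes.T
    return PCAResult(
        mean_coordinates=mean,
        eigenvalues=eigenvalues,
        modes=modes.reshape(-1, n_sel, 3),
        projections=projections,
        frame_tags=tags,
        atom_indices=sel_idx,
    )


def porcupine(
    result: PCAResult,
    component: int = 0,
    scale: float = 1.0,
    min_length: float = 2.0,
) -> np.ndarray:
    """Per-atom displacement vectors of one PCA mode for porcupine plots.

    Each vector is ``scale * sqrt(eigenvalue) * mode``; vectors shorter
    than ``min_length`` (Å) are zeroed so only large motions show.
    """
    vectors = scale * np.sqrt(result.eigenvalues[component]) * result.modes[component]
    lengths = np.linalg.norm(vectors, axis=1)
    vectors = vectors.copy()
    vectors[lengths < min_length] = 0.0
    return vectors


def rdf(
    trajectory: Trajectory,
    reference_selection: str | np.ndarray,
    target_selection: str | np.ndarray,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    density: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two selections.

    With a periodic box on the trajectory, minimum-image distances are
    used and the bulk density defaults to N_target / <V_box>.  Without a
    box, ``density`` (atoms/Å³) must be supplied and plain Euclidean
    distances are used (edge effects are then the caller's concern).

    Returns (bin centers, g).
    """
    ref_idx = _resolve(trajectory.topology, reference_selection)
    tgt_idx = _resolve(trajectory.topology, target_selection)
    if trajectory.box is None and density is None:
        raise ValueError("no box on trajectory: supply a bulk density override")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    same = ref_idx.size == tgt_idx.size and np.array_equal(ref_idx, tgt_idx)
    for k in range(trajectory.n_frames):
        box = trajectory.box[k] if trajectory.box is not None else None
        if same:
            pts = trajectory.frames[k, ref_idx]
            if box is not None:
                tree = cKDTree(np.mod(pts, box), boxsize=box)
            else:
                tree = cKDTree(pts)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if len(pairs) == 0:
                continue
            diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
            if box is not None:
                diff -= box * np.round(diff / box)
            d = np.linalg.norm(diff, axis=1)
            counts += 2.0 * np.histogram(d, bins=edges)[0]
        else:
            rp = trajectory.frames[k, ref_idx]
            tp = trajectory.frames[k, tgt_idx]
            if box is not None:
                t_ref = cKDTree(np.mod(rp, box), boxsize=box)
                t_tgt = cKDTree(np.mod(tp, box), boxsize=box)
            else:
                t_ref = cKDTree(rp)
                t_tgt = cKDTree(tp)
            dm = t_ref.sparse_distance_matrix(t_tgt, r_max, output_type="coo_matrix")
            d = dm.data
            shared = np.intersect1d(ref_idx, tgt_idx)
            if shared.size:
                self_pairs = (ref_idx[dm.row] == tgt_idx[dm.col])
                d = d[~self_pairs]
            counts += np.histogram(d, bins=edges)[0]
    if density is None:
        volume = float(np.mean(np.prod(trajectory.box, axis=1)))
        rho = tgt_idx.size / volume
    else:
        rho = density
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = trajectory.n_frames * ref_idx.size * shell * rho
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def smooth_trajectory(trajectory: Trajectory, window: int = 5) -> Trajectory:
    """Centered moving-average smoothing of coordinates.

    ``window`` must be odd; near the ends the window shrinks to the
    available frames.  Frame count is unchanged; window 1 is identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    n = trajectory.n_frames
    if window > n:
        raise ValueError(f"window {window} exceeds frame count {n}")
    half = window // 2
    frames = np.empty_like(trajectory.frames)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        frames[i] = trajectory.frames[lo:hi].mean(axis=0)
    box = trajectory.box.copy() if trajectory.box is not None else None
    return Trajectory(trajectory.topology.copy(), frames, box=box)
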