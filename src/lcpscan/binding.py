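"""Ligand-centric binding analyses.

Covers per-residue contact-fraction profiles, classification of polymer
binding modes (extended / folded / extended-like), near-attack-
conformation (NAC) profiling of double-bond-to-distal-oxygen distances
with the derived cleavage fragment spectrum, and a linear interaction
energy (LIE) decomposition into van der Waals and electrostatic terms.

The NAC criterion follows the reactive-geometry convention: a double
bond strictly below the threshold distance (default 4 Å) from the
heme-bound distal oxygen in a frame counts one potential cleavage event
for that bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import cdist

from .pockets import Pocket
from .polymer import PolymerModel, cleavage_products
from .structures import MolecularStructure, Trajectory

__all__ = [
    "ContactProfile",
    "CleavageProfile",
    "EnergyTerms",
    "ConformationLabel",
    "contact_profile",
    "classify_conformation",
    "bond_o2_distance",
    "nac_profile",
    "fragment_spectrum",
    "lie",
]

COULOMB_CONSTANT = 332.0636  # kcal Å / (mol e²)


@dataclass
class ContactProfile:
    """Per-residue ligand contact fractions over a trajectory."""

    fractions: dict[tuple[str, int], float]
    cutoff: float
    report_threshold: float
    n_frames: int

    def reported(self) -> dict[tuple[str, int], float]:
        """Residues whose fraction exceeds the report threshold."""
        return {k: v for k, v in self.fractions.items() if v > self.report_threshold}


@dataclass
class CleavageProfile:
    """Per-double-bond NAC counts and distance histograms."""

    counts: dict[int, int]  # bond number (1..n from dimethyl end) -> frames
    histograms: dict[int, tuple[np.ndarray, np.ndarray]]  # bond -> (edges, counts)
    threshold: float
    n_frames: int


@dataclass
class EnergyTerms:
    """Linear interaction energy decomposition, kcal/mol."""

    e_vdw: np.ndarray  # per frame
    e_ele: np.ndarray
    e_tot: np.ndarray = field(init=False)
    mean_vdw: float = field(init=False)
    mean_ele: float = field(init=False)
    std_vdw: float = field(init=False)
    std_ele: float = field(init=False)
    pct_vdw: float = field(init=False)
    pct_ele: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_tot = self.e_vdw + self.e_ele
        self.mean_vdw = float(self.e_vdw.mean())
        self.mean_ele = float(self.e_ele.mean())
        self.std_vdw = float(self.e_vdw.std())
        self.std_ele = float(self.e_ele.std())
        denom = abs(self.mean_vdw) + abs(self.mean_ele)
        # Percentage shares of the absolute mean term magnitudes.
        self.pct_vdw = 100.0 * abs(self.mean_vdw) / denom if denom > 0 else 0.0
        self.pct_ele = 100.0 - self.pct_vdw if denom > 0 else 0.0


@dataclass
class ConformationLabel:
    label: str  # extended | folded | extended_like
    terminus_in_pocket: tuple[bool, bool]
    terminus_at_surface: tuple[bool, bool]
    centroid_heme_distance: float
    ligand_span: float


def contact_profile(
    trajectory: Trajectory,
    ligand_selection: str | np.ndarray,
    cutoff: float = 5.0,
    report_threshold: float = 0.045,
    environment_selection: str | np.ndarray | None = None,
) -> ContactProfile:
    """Fraction of frames each residue contacts the ligand.

    A residue is in contact in a frame when the minimum heavy-atom
    distance between any of its atoms and any ligand atom is at most
    ``cutoff``.  Fractions below ``report_threshold`` are kept internally
    but suppressed from :meth:`ContactProfile.reported`.
    """
    top = trajectory.topology
    lig_idx = top.select(ligand_selection) if isinstance(ligand_selection, str) else np.asarray(ligand_selection)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    heavy = np.array([a.element.upper() != "H" for a in top.atoms])
    lig_heavy = lig_idx[heavy[lig_idx]]
    if environment_selection is None:
        env_mask = np.ones(top.n_atoms, dtype=bool)
        env_mask[lig_idx] = False
        env_idx = np.flatnonzero(env_mask & heavy)
    else:
        env_idx = (
            top.select(environment_selection)
            if isinstance(environment_selection, str)
            else np.asarray(environment_selection)
        )
        env_idx = env_idx[heavy[env_idx]]
    if env_idx.size == 0 or lig_heavy.size == 0:
        raise ValueError("ligand/environment heavy-atom selections must be non-empty")
    if np.intersect1d(env_idx, lig_idx).size:
        raise ValueError("ligand and environment selections overlap")

    residues: dict[tuple[str, int], np.ndarray] = {}
    for i in env_idx:
        a = top.atoms[i]
        residues.setdefault((a.chain_id, a.residue_number), []).append(i)
    residues = {k: np.array(v) for k, v in residues.items()}

    hits = {k: 0 for k in residues}
    for f in range(trajectory.n_frames):
        lig_tree = cKDTree(trajectory.frames[f, lig_heavy])
        dmin, _ = lig_tree.query(trajectory.frames[f, env_idx], workers=-1)
        near = dict(zip(env_idx, dmin))
        for key, idx in residues.items():
            if min(near[i] for i in idx) <= cutoff:
                hits[key] += 1
    fractions = {k: hits[k] / trajectory.n_frames for k in residues}
    return ContactProfile(fractions, cutoff, report_threshold, trajectory.n_frames)


def _burial_depth(point: np.ndarray, hull: ConvexHull) -> float:
    """Distance from a point inward to the convex hull surface; negative
    outside the hull."""
    # hull.equations: A x + b <= 0 inside
    return float(-(hull.equations[:, :3] @ point + hull.equations[:, 3]).max())


def classify_conformation(
    frame: np.ndarray,
    ligand_indices: np.ndarray,
    terminus_atoms: tuple[int, int],
    protein_indices: np.ndarray,
    pocket: Pocket,
    heme_center: np.ndarray,
    surface_probe: float = 3.0,
    pocket_cutoff: float = 2.5,
    heme_cutoff: float = 12.0,
) -> ConformationLabel:
    """Classify a bound polymer pose as extended, folded or extended-like.

    A terminus is *in the pocket* when within ``pocket_cutoff`` of any
    pocket alpha-sphere center, and *at the surface* when its burial
    depth below the protein heavy-atom convex hull is at most
    ``surface_probe``.  Extended: exactly one terminus in the pocket and
    the other at the surface.  Folded: both termini at the surface with
    the ligand centroid within ``heme_cutoff`` of the heme.  Anything
    else is extended-like.
    """
    frame = np.asarray(frame, dtype=float)
    if np.max(ligand_indices) >= len(frame) or max(terminus_atoms) >= len(frame):
        raise ValueError("ligand atom indices not present in frame")
    lig = frame[ligand_indices]
    termini = [frame[terminus_atoms[0]], frame[terminus_atoms[1]]]
    hull = ConvexHull(frame[protein_indices])
    sphere_centers = np.array([s.center for s in pocket.spheres])
    in_pocket = tuple(
        bool(np.min(np.linalg.norm(sphere_centers - t, axis=1)) <= pocket_cutoff) for t in termini
    )
    at_surface = tuple(_burial_depth(t, hull) <= surface_probe for t in termini)
    centroid = lig.mean(axis=0)
    heme_d = float(np.linalg.norm(centroid - np.asarray(heme_center)))
    span = float(np.linalg.norm(termini[0] - termini[1]))
    if (in_pocket[0] != in_pocket[1]) and (at_surface[1] if in_pocket[0] else at_surface[0]):
        label = "extended"
    elif not any(in_pocket) and all(at_surface) and heme_d <= heme_cutoff:
        label = "folded"
    else:
        label = "extended_like"
    return ConformationLabel(label, in_pocket, at_surface, heme_d, span)


def bond_o2_distance(
    frame: np.ndarray,
    bond: tuple[int, int],
    distal_oxygen: int,
    mode: str = "min",
) -> float:
    """Distance (Å) from a C=C bond to the distal oxygen.

    ``mode='min'`` (default) returns the smaller of the two carbon-oxygen
    distances; ``mode='midpoint'`` measures from the bond midpoint.
    """
    frame = np.asarray(frame, dtype=float)
    try:
        ca, cb = frame[bond[0]], frame[bond[1]]
        ox = frame[distal_oxygen]
    except IndexError as exc:
        raise ValueError("bond or oxygen atom index outside frame") from exc
    if mode == "min":
        return float(min(np.linalg.norm(ca - ox), np.linalg.norm(cb - ox)))
    if mode == "midpoint":
        return float(np.linalg.norm(0.5 * (ca + cb) - ox))
    raise ValueError("mode must be 'min' or 'midpoint'")


def nac_profile(
    trajectories: Trajectory | list[Trajectory],
    ligand: PolymerModel,
    distal_oxygen: int,
    threshold: float = 4.0,
    bin_width: float = 0.25,
    r_max: float = 30.0,
    ligand_offset: int = 0,
    mode: str = "min",
) -> CleavageProfile:
    """Near-attack-conformation counts per double bond, pooled over
    trajectories.

    Bond k (numbered from the dimethyl terminus) scores one event in each
    frame whose bond-to-oxygen distance (``mode='min'`` over the two
    carbons by default) is strictly below ``threshold``.  Per-bond
    distance histograms are also returned; distances beyond ``r_max``
    accumulate in the last bin so histogram counts always sum to the
    frame total.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not ligand.double_bonds:
        raise ValueError("ligand has no double bonds")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    n_bonds = len(ligand.double_bonds)
    counts = {k: 0 for k in range(1, n_bonds + 1)}
    hist = {k: np.zeros(len(edges) - 1, dtype=int) for k in range(1, n_bonds + 1)}
    total = 0
    for traj in trajectories:
        total += traj.n_frames
        for f in range(traj.n_frames):
            frame = traj.frames[f]
            for k, (ia, ib) in enumerate(ligand.double_bonds, start=1):
                d = bond_o2_distance(
                    frame, (ia + ligand_offset, ib + ligand_offset), distal_oxygen, mode=mode
                )
                if d < threshold:
                    counts[k] += 1
                b = min(int(d / bin_width), len(edges) - 2)
                hist[k][b] += 1
    histograms = {k: (edges, hist[k]) for k in hist}
    return CleavageProfile(counts, histograms, threshold, total)


def fragment_spectrum(profile: CleavageProfile, n: int) -> dict[int, float]:
    """Fragment-size spectrum implied by a cleavage profile.

    Each NAC event at bond k contributes one count to fragment sizes
    k-1 and n-k (intact double bonds of the two product oligomers);
    weights are normalized to fractions of all contributions.
    """
    if len(profile.counts) != n:
        raise ValueError(f"profile has {len(profile.counts)} bonds, expected {n}")
    weights: dict[int, float] = {}
    for k, c in profile.counts.items():
        if c == 0:
            continue
        for size in cleavage_products(n, k):
            weights[size] = weights.get(size, 0.0) + c
    total = sum(weights.values())
    if total == 0:
        return {}
    return {size: w / total for size, w in sorted(weights.items())}


def _lj_coulomb(
    pos_a: np.ndarray, pos_b: np.ndarray,
    q_a: np.ndarray, q_b: np.ndarray,
    eps_a: np.ndarray, eps_b: np.ndarray,
    rmh_a: np.ndarray, rmh_b: np.ndarray,
) -> tuple[float, float]:
    r = cdist(pos_a, pos_b)
    r = np.maximum(r, 1e-12)
    eps = np.sqrt(np.outer(eps_a, eps_b))
    rmin = rmh_a[:, None] + rmh_b[None, :]
    x6 = (rmin / r) ** 6
    e_vdw = float(np.sum(eps * (x6 * x6 - 2.0 * x6)))
    e_ele = float(COULOMB_CONSTANT * np.sum(np.outer(q_a, q_b) / r))
    return e_vdw, e_ele


def lie(
    trajectory: Trajectory,
    ligand_selection: str | np.ndarray,
    environment_selection: str | np.ndarray,
) -> EnergyTerms:
    """Linear interaction energy between ligand and environment.

    Per frame, all ligand-environment atom pairs contribute a 12-6
    Lennard-Jones term ``eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ]``
    with geometric-mean epsilon and summed Rmin/2 combination, and a
    Coulomb term ``k q_i q_j / r`` in vacuum (no cutoff, no periodic
    images).  Every atom in both selections must carry charge and LJ
    parameters.
    """
    top = trajectory.topology
    lig_idx = top.select(ligand_selection) if isinstance(ligand_selection, str) else np.asarray(ligand_selection)
    env_idx = (
        top.select(environment_selection)
        if isinstance(environment_selection, str)
        else np.asarray(environment_selection)
    )
    if lig_idx.size == 0 or env_idx.size == 0:
        raise ValueError("empty selection for LIE")
    missing = [
        top.atoms[i].serial
        for i in np.concatenate([lig_idx, env_idx])
        if top.atoms[i].partial_charge is None
        or top.atoms[i].lj_epsilon is None
        or top.atoms[i].lj_rmin_half is None
    ]
    if missing:
        raise ValueError(f"atoms missing charge/LJ parameters (serials): {missing[:10]}")

    def params(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q = np.array([top.atoms[i].partial_charge for i in idx])
        e = np.array([top.atoms[i].lj_epsilon for i in idx])
        rmh = np.array([top.atoms[i].lj_rmin_half for i in idx])
        return q, e, rmh

    q_l, e_l, r_l = params(lig_idx)
    q_e, e_e, r_e = params(env_idx)
    e_vdw = np.empty(trajectory.n_frames)
    e_ele = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        e_vdw[f], e_ele[f] = _lj_coulomb(
            trajectory.frames[f, lig_idx], trajectory.frames[f, env_idx],
            q_l, q_e, e_l, e_e, r_l, r_e,
        )
    return EnergyTerms(e_vdw=e_vdw, e_ele=e_ele)
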