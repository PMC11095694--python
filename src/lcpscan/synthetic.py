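"""Synthetic structures and trajectories with planted, analytic truth.

Every generator is seed-deterministic and returns ``(object, manifest)``
where the manifest is a JSON-serializable record of the planted ground
truth (clearances, volumes, schedules, state assignments).  Analysis
tests read only the manifest, never generator internals.

The fixtures stand in for the study systems — wall-atom channels for
tunnel search, hollow shells for pocket detection, planted contact and
distance schedules for binding profiles — without pretending to be
physically realistic molecular dynamics.
"""

from __future__ import annotations

import math

import numpy as np

from .polymer import PolymerModel
from .structures import Atom, MolecularStructure, Trajectory

__all__ = [
    "make_channel",
    "make_cavity",
    "make_binding_trajectory",
    "make_two_state_trajectory",
    "make_uniform_gas",
]


def _wall_atom(i: int, xyz: np.ndarray, radius: float, resname: str = "WAL") -> Atom:
    return Atom(
        serial=i + 1, name="C", element="C", residue_name=resname,
        residue_number=(i // 100) + 1, chain_id="A", position=xyz,
        vdw_radius=radius, record="HETATM",
    )


def make_channel(
    inner_radius: float,
    length: float = 15.0,
    wall_atom_radius: float = 1.7,
    spacing: float = 0.8,
    seed: int = 0,
    second_inner_radius: float | None = None,
) -> tuple[MolecularStructure, dict]:
    """A sealed 'test tube' of wall atoms with one open exit along +z.

    Wall-atom centers sit on a cylinder of radius ``inner_radius +
    wall_atom_radius`` so the analytic axial clearance is exactly
    ``inner_radius``.  The bottom is capped by a disk of atoms at z = 0;
    the top (z = length) is open.  With ``second_inner_radius`` a second
    tube of that clearance extends along -z, making two exits.

    Raises if the wall-atom lattice spacing would leave through-wall gaps.
    """
    if inner_radius <= 0:
        raise ValueError("inner_radius must be positive")
    # Worst-case wall gap: center of a lattice cell; must stay inside atoms.
    gap = math.hypot(spacing / 2, spacing / 2) - wall_atom_radius
    if gap > -0.1:
        raise ValueError(
            f"wall spacing {spacing} leaves gaps (clearance {gap:.2f} Å); "
            "decrease spacing or enlarge wall atoms"
        )
    rng = np.random.default_rng(seed)  # reserved: deterministic but seed-tagged
    del rng

    coords: list[np.ndarray] = []

    def tube(inner: float, z0: float, z1: float) -> None:
        rw = inner + wall_atom_radius
        n_phi = max(8, int(math.ceil(2 * math.pi * rw / spacing)))
        for z in np.arange(z0, z1 + 1e-9, spacing):
            for k in range(n_phi):
                phi = 2 * math.pi * k / n_phi
                coords.append(np.array([rw * math.cos(phi), rw * math.sin(phi), z]))

    def cap(z: float, r_in: float, r_out: float) -> None:
        for r in np.arange(r_in, r_out + 1e-9, spacing):
            if r < spacing / 2:
                coords.append(np.array([0.0, 0.0, z]))
                continue
            n_phi = max(6, int(math.ceil(2 * math.pi * r / spacing)))
            for k in range(n_phi):
                phi = 2 * math.pi * k / n_phi
                coords.append(np.array([r * math.cos(phi), r * math.sin(phi), z]))

    tube(inner_radius, 0.0, length)
    rw1 = inner_radius + wall_atom_radius
    if second_inner_radius is None:
        cap(0.0, 0.0, rw1)
        start = np.array([0.0, 0.0, wall_atom_radius + 2.0])
        exits = [[0.0, 0.0, float(length)]]
        clearances = [float(inner_radius)]
    else:
        tube(second_inner_radius, -length, 0.0)
        rw2 = second_inner_radius + wall_atom_radius
        lo, hi = sorted((rw1, rw2))
        if hi - lo > spacing / 2:
            cap(0.0, lo, hi)  # annulus sealing the radius step at the junction
        start = np.array([0.0, 0.0, 0.0])
        exits = [[0.0, 0.0, float(length)], [0.0, 0.0, -float(length)]]
        clearances = [float(inner_radius), float(second_inner_radius)]

    atoms = [_wall_atom(i, xyz, wall_atom_radius) for i, xyz in enumerate(coords)]
    structure = MolecularStructure(atoms)
    manifest = {
        "kind": "channel",
        "seed": seed,
        "inner_radius": float(inner_radius),
        "second_inner_radius": None if second_inner_radius is None else float(second_inner_radius),
        "length": float(length),
        "wall_atom_radius": float(wall_atom_radius),
        "wall_spacing": float(spacing),
        "start_point": start.tolist(),
        "exit_points": exits,
        "analytic_clearances": clearances,
        "n_atoms": len(atoms),
    }
    return structure, manifest


def make_cavity(
    cavity_radius: float,
    shell_atoms: int = 200,
    seed: int = 0,
    wall_atom_radius: float = 1.8,
    jitter: float = 0.12,
) -> tuple[MolecularStructure, dict]:
    """A hollow shell of atoms enclosing a spherical void at the origin.

    Atom centers lie on a Fibonacci sphere of radius ``cavity_radius``
    (small seeded jitter breaks the cospherical degeneracy), so interior
    Voronoi vertices sit near the center with tangent-sphere radii close
    to ``cavity_radius``.  The manifest records the analytic inscribed
    void volume (4/3)π(R - r_wall)³.
    """
    if shell_atoms < 20:
        raise ValueError("need at least 20 shell atoms to close a cavity")
    rng = np.random.default_rng(seed)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    coords = []
    for i in range(shell_atoms):
        z = 1.0 - 2.0 * (i + 0.5) / shell_atoms
        r = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        p = cavity_radius * np.array([r * math.cos(phi), r * math.sin(phi), z])
        coords.append(p + rng.normal(0.0, jitter, size=3))
    atoms = [_wall_atom(i, xyz, wall_atom_radius, resname="SHL") for i, xyz in enumerate(coords)]
    structure = MolecularStructure(atoms)
    void_radius = max(cavity_radius - wall_atom_radius, 0.0)
    manifest = {
        "kind": "cavity",
        "seed": seed,
        "cavity_radius": float(cavity_radius),
        "wall_atom_radius": float(wall_atom_radius),
        "jitter": float(jitter),
        "center": [0.0, 0.0, 0.0],
        "analytic_void_volume": 4.0 / 3.0 * math.pi * void_radius ** 3,
        "n_atoms": len(atoms),
    }
    return structure, manifest


def _even_schedule(n_frames: int, fraction: float) -> np.ndarray:
    """Deterministic evenly spread frame indices hitting floor(n*f) frames."""
    hits = np.flatnonzero(
        np.floor((np.arange(n_frames) + 1) * fraction) - np.floor(np.arange(n_frames) * fraction) >= 1
    )
    return hits


def make_binding_trajectory(
    n_frames: int,
    protein: MolecularStructure,
    ligand: PolymerModel,
    contact_schedule: dict[int, float] | None = None,
    distance_plan: dict[int, tuple[float, float, float]] | None = None,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    contact_cutoff: float = 5.0,
    nac_threshold: float = 4.0,
) -> tuple[Trajectory, dict]:
    """A protein+ligand trajectory realizing planted contact and
    near-attack schedules exactly.

    ``contact_schedule`` maps protein residue numbers to target contact
    fractions; scheduled residues are rigidly shifted frame-by-frame to
    sit just inside (cutoff − 1.5 Å) or well outside (≥ cutoff + 3 Å) the
    contact cutoff of the static ligand, on a deterministic evenly-spread
    frame schedule, so recovered fractions equal floor(f·n)/n exactly.

    ``distance_plan`` maps double-bond numbers to ``(baseline, dip,
    dip_fraction)``: the heme distal O2 pseudo-atom rests far from the
    chain and, in each bond's (contiguous, disjoint) dip block, moves to
    exactly ``dip`` Å from that bond's nearest carbon, perpendicular to
    the chain axis.  Overlapping dip demands raise, naming the pair.

    Gaussian per-axis jitter (``jitter_sigma``) is added to every atom
    afterwards; exact-recovery tests use zero jitter.
    """
    contact_schedule = contact_schedule or {}
    distance_plan = distance_plan or {}
    rng = np.random.default_rng(seed)

    # Topology: protein + ligand + a distal-O2 pseudo-atom (if absent).
    atoms = [a for a in protein.copy().atoms]
    ligand_offset = len(atoms)
    for a in ligand.structure.copy().atoms:
        atoms.append(a)
    o2_index = next(
        (i for i, a in enumerate(atoms) if a.name.upper() == "O2" and i < ligand_offset), None
    )
    lig_coords = ligand.structure.coords
    chain_centroid = lig_coords.mean(axis=0)
    axis = np.linalg.svd(lig_coords - chain_centroid, full_matrices=False)[2][0]
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    rest_distance = max([bl for bl, _, _ in distance_plan.values()] + [12.0])
    o2_rest = chain_centroid + perp * rest_distance
    if o2_index is None:
        o2_index = len(atoms)
        atoms.append(Atom(
            serial=len(atoms) + 1, name="O2", element="O", residue_name="OXY",
            residue_number=9999, chain_id="X", position=o2_rest, record="HETATM",
        ))
    topology = MolecularStructure(atoms)
    base = topology.coords

    lig_idx = np.arange(ligand_offset, ligand_offset + ligand.structure.n_atoms)
    lig_heavy = lig_idx[[a.element.upper() != "H" for a in ligand.structure.atoms]]

    # --- contact schedules -------------------------------------------------
    res_index = protein.residue_index()
    contact_frames: dict[int, set[int]] = {}
    residue_moves: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for resnum, fraction in contact_schedule.items():
        members = [idx for (ch, rn), idx in res_index.items() if rn == resnum]
        if not members:
            raise ValueError(f"contact_schedule residue {resnum} not found in protein")
        res_atoms = np.array(members[0])
        centroid = base[res_atoms].mean(axis=0)
        # nearest ligand heavy atom to this residue
        d = np.linalg.norm(base[lig_heavy] - centroid, axis=1)
        anchor = base[lig_heavy[np.argmin(d)]]
        u = centroid - anchor
        nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 1e-9 else perp
        # nearest residue atom to the anchor defines the controlled distance
        a_near = res_atoms[np.argmin(np.linalg.norm(base[res_atoms] - anchor, axis=1))]

        def placed(dist: float) -> np.ndarray:
            shift = (anchor + dist * u) - base[a_near]
            return base[res_atoms] + shift

        near = placed(contact_cutoff - 1.5)
        dist_far = contact_cutoff + 3.0
        far = placed(dist_far)
        # push farther until every ligand heavy atom is beyond the cutoff
        for _ in range(50):
            dmin = np.min(np.linalg.norm(far[:, None, :] - base[lig_heavy][None, :, :], axis=-1))
            if dmin > contact_cutoff + 0.5:
                break
            dist_far += 2.0
            far = placed(dist_far)
        residue_moves[resnum] = (res_atoms, near, far)
        contact_frames[resnum] = set(_even_schedule(n_frames, fraction).tolist())

    # --- NAC dip blocks (contiguous, disjoint) -----------------------------
    dip_frames: dict[int, range] = {}
    cursor = 0
    for bond_no in sorted(distance_plan):
        baseline, dip, dip_fraction = distance_plan[bond_no]
        if not (1 <= bond_no <= len(ligand.double_bonds)):
            raise ValueError(f"distance_plan bond {bond_no} outside 1..{len(ligand.double_bonds)}")
        count = int(math.floor(dip_fraction * n_frames + 1e-9))
        if cursor + count > n_frames:
            raise ValueError(
                f"conflicting dip demands: bonds {sorted(distance_plan)} need more frames than {n_frames}"
            )
        dip_frames[bond_no] = range(cursor, cursor + count)
        cursor += count

    o2_positions = np.tile(o2_rest, (n_frames, 1))
    planted_nac = {k: 0 for k in range(1, len(ligand.double_bonds) + 1)}
    for bond_no, frames_range in dip_frames.items():
        dip = distance_plan[bond_no][1]
        ca, cb = ligand.double_bonds[bond_no - 1]
        pos = base[lig_idx[ca]] + perp * dip
        # verify no other bond dips below threshold at this O2 position
        for other in range(1, len(ligand.double_bonds) + 1):
            if other == bond_no:
                continue
            oa, ob = ligand.double_bonds[other - 1]
            dmin = min(np.linalg.norm(pos - base[lig_idx[oa]]), np.linalg.norm(pos - base[lig_idx[ob]]))
            if dmin < nac_threshold:
                raise ValueError(
                    f"conflicting plan: dip for bond {bond_no} drags bond {other} "
                    f"to {dmin:.2f} Å (< threshold {nac_threshold})"
                )
        for f in frames_range:
            o2_positions[f] = pos
        planted_nac[bond_no] = len(frames_range)

    # --- assemble frames ---------------------------------------------------
    frames = np.tile(base, (n_frames, 1, 1))
    for resnum, (res_atoms, near, far) in residue_moves.items():
        hits = contact_frames[resnum]
        for f in range(n_frames):
            frames[f, res_atoms] = near if f in hits else far
    frames[:, o2_index] = o2_positions
    if jitter_sigma > 0:
        frames += rng.normal(0.0, jitter_sigma, size=frames.shape)

    manifest = {
        "kind": "binding",
        "seed": seed,
        "n_frames": n_frames,
        "ligand_offset": int(ligand_offset),
        "ligand_indices": lig_idx.tolist(),
        "o2_index": int(o2_index),
        "contact_cutoff": contact_cutoff,
        "nac_threshold": nac_threshold,
        "jitter_sigma": jitter_sigma,
        "planted_contact_fractions": {
            str(rn): len(contact_frames[rn]) / n_frames for rn in contact_frames
        },
        "planted_nac_counts": {str(k): v for k, v in planted_nac.items()},
    }
    return Trajectory(topology, frames), manifest


def _remove_rigid_component(coords: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Project a per-atom displacement field off the 6 infinitesimal
    rigid-body modes (3 translations, 3 rotations about the centroid)."""
    n = len(coords)
    rel = coords - coords.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
        axis = np.zeros(3)
        axis[k] = 1.0
        basis.append(np.cross(axis, rel).ravel())
    Q, _ = np.linalg.qr(np.stack(basis, axis=1))
    flat = displacement.ravel()
    return (flat - Q @ (Q.T @ flat)).reshape(n, 3)


def make_two_state_trajectory(
    reference: MolecularStructure,
    displacement: np.ndarray,
    occupancy: float,
    n_frames: int,
    noise_sigma: float = 0.1,
    seed: int = 0,
    remove_rigid: bool = True,
) -> tuple[Trajectory, dict]:
    """Frames drawn from two rigid states: the reference (A) and the
    reference plus a per-atom displacement field (B), with isotropic
    Gaussian noise.  ``occupancy`` is the probability of state B.

    By default the displacement is first projected off the rigid-body
    modes (net translation/rotation), since superposition would remove
    those anyway; the manifest records the displacement actually applied.
    """
    if not (0.0 < occupancy < 1.0):
        raise ValueError("occupancy must be in (0, 1)")
    displacement = np.asarray(displacement, dtype=float)
    base = reference.coords
    if displacement.shape != base.shape:
        raise ValueError("displacement must be a per-atom (n, 3) field")
    if remove_rigid:
        displacement = _remove_rigid_component(base, displacement)
    rng = np.random.default_rng(seed)
    states = (rng.random(n_frames) < occupancy).astype(int)
    frames = np.tile(base, (n_frames, 1, 1))
    frames[states == 1] += displacement
    frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    manifest = {
        "kind": "two_state",
        "seed": seed,
        "occupancy": occupancy,
        "noise_sigma": noise_sigma,
        "n_frames": n_frames,
        "state_assignments": states.tolist(),
        "displacement_norm": float(np.linalg.norm(displacement)),
        "applied_displacement": displacement.tolist(),
    }
    return Trajectory(reference.copy(), frames), manifest


def make_uniform_gas(
    n_atoms: int,
    box: tuple[float, float, float],
    n_frames: int,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Independent uniform positions in an orthorhombic box per frame —
    the ideal-gas reference whose radial distribution function is 1."""
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    frames = rng.random((n_frames, n_atoms, 3)) * box_arr
    atoms = [
        Atom(serial=i + 1, name="O", element="O", residue_name="GAS",
             residue_number=i + 1, chain_id="A", position=frames[0, i], record="HETATM")
        for i in range(n_atoms)
    ]
    topology = MolecularStructure(atoms)
    boxes = np.tile(box_arr, (n_frames, 1))
    manifest = {
        "kind": "gas",
        "seed": seed,
        "n_atoms": n_atoms,
        "n_frames": n_frames,
        "box": box_arr.tolist(),
        "density": n_atoms / float(np.prod(box_arr)),
    }
    return Trajectory(topology, frames, box=boxes), manifest
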