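"""Idealized cis-1,4-polyisoprene chain models.

The repeat unit is ``-CH2-C(CH3)=CH-CH2-`` (C1-C2(=C3)-C4 backbone with the
C5 methyl on C2).  Both termini are hydrogen-capped, so an n-mer has the
formula C(5n)H(8n+2) — the 10-mer is the C50H82 substrate model.  Double
bonds are numbered 1..n starting from the *dimethyl* terminus (the end
whose first unit carries two methyl groups, R-C=C-(CH3)2).

Geometry is idealized: C-C 1.54 Å, C=C 1.34 Å, C-H 1.09 Å, sp2 angles
120°, sp3 angles 109.47°, backbone single-bond torsions trans (180°) and a
cis torsion (0°) across every double bond.  Atoms are placed by natural
extension of internal coordinates (the NeRF construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import Atom, MolecularStructure

__all__ = ["PolymerModel", "build_polyisoprene", "chain_width", "cleavage_products"]

CC_SINGLE = 1.54
CC_DOUBLE = 1.34
CH_BOND = 1.09
SP3_ANGLE = 109.47
SP2_ANGLE = 120.0
HYDROGEN_ALLOWANCE = 1.1  # Å added to the heavy-atom width for C-H extent


@dataclass
class PolymerModel:
    """A built polyisoprene chain.

    ``double_bonds[k-1]`` holds the atom-index pair (C2, C3) of bond number
    k, counted from the dimethyl terminus.  ``terminus_atoms`` are the two
    terminal backbone carbons (dimethyl end first).
    """

    monomer_count: int
    structure: MolecularStructure
    double_bonds: list[tuple[int, int]]
    terminus_atoms: tuple[int, int]


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D with |CD| = bond, angle(B,C,D) and torsion(A,B,C,D)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        -bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sp3_pair(center: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> list[np.ndarray]:
    """Two substituent positions completing a tetrahedron around *center*
    whose two heavy neighbors sit at *n1*, *n2*."""
    u1, u2 = _unit(n1 - center), _unit(n2 - center)
    bisector = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    half = math.radians(SP3_ANGLE / 2.0)
    return [
        center + CH_BOND * (bisector * math.cos(half) + perp * math.sin(half)),
        center + CH_BOND * (bisector * math.cos(half) - perp * math.sin(half)),
    ]


def _sp3_cap(center: np.ndarray, neighbor: np.ndarray, ref: np.ndarray) -> list[np.ndarray]:
    """Three staggered substituents around *center* with one heavy
    neighbor; *ref* fixes the azimuth deterministically."""
    n = _unit(neighbor - center)
    r = ref - center
    e1 = r - np.dot(r, n) * n
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    e1 = _unit(e1)
    e2 = np.cross(n, e1)
    cos_t = math.cos(math.radians(SP3_ANGLE))
    sin_t = math.sin(math.radians(SP3_ANGLE))
    out = []
    for k in range(3):
        az = math.radians(60.0 + 120.0 * k)
        d = cos_t * n + sin_t * (math.cos(az) * e1 + math.sin(az) * e2)
        out.append(center + CH_BOND * d)
    return out


def _sp2_third(center: np.ndarray, n1: np.ndarray, n2: np.ndarray, bond: float) -> np.ndarray:
    """In-plane third substituent of an sp2 center with neighbors n1, n2."""
    direction = -_unit(_unit(n1 - center) + _unit(n2 - center))
    return center + bond * direction


def build_polyisoprene(
    n: int,
    torsion_overrides: dict[tuple[int, str], float] | None = None,
) -> PolymerModel:
    """Build an idealized extended cis-1,4-polyisoprene n-mer.

    Parameters
    ----------
    n:
        Monomer count (>= 1).  n=10 gives the C50H82 substrate model.
    torsion_overrides:
        Optional ``{(unit, atom): torsion_deg}`` replacing the default
        backbone torsion used when placing that unit's backbone atom
        (atom one of ``"C1"``, ``"C2"``, ``"C3"``, ``"C4"``); the double
        bond stays cis regardless.  Used to build folded test poses.

    Raises
    ------
    ValueError
        If ``n <= 0`` or an override produces a steric clash (< 1.0 Å
        between non-bonded atoms).
    """
    if n < 1:
        raise ValueError(f"monomer count must be >= 1, got {n}")
    overrides = torsion_overrides or {}

    # --- backbone carbons -------------------------------------------------
    # positions[(unit, name)] -> xyz
    pos: dict[tuple[int, str], np.ndarray] = {}
    pos[(1, "C1")] = np.zeros(3)
    pos[(1, "C2")] = np.array([CC_SINGLE, 0.0, 0.0])
    a120 = math.radians(180.0 - SP2_ANGLE)
    pos[(1, "C3")] = pos[(1, "C2")] + CC_DOUBLE * np.array([math.cos(a120), math.sin(a120), 0.0])

    # Placement recipe per backbone atom: (bond, angle at previous atom,
    # default torsion magnitude).  The cis double bond is the 0° torsion at
    # C4.  Single-bond torsions are skew (s+ / s-), with the handedness
    # alternating unit to unit — an all-trans pattern would curl the cis
    # chain back onto itself; the alternating-skew pattern extends it
    # (~4.7 Å per unit) and keeps all non-bonded atoms > 1.8 Å apart.
    recipe = {
        "C4": (CC_SINGLE, SP2_ANGLE, 0.0),    # torsion C1-C2-C3-C4 (cis)
        "C1": (CC_SINGLE, SP3_ANGLE, 120.0),  # torsion C2-C3-C4-C1'
        "C2": (CC_SINGLE, SP3_ANGLE, 60.0),   # torsion C3-C4-C1'-C2'
        "C3": (CC_DOUBLE, SP2_ANGLE, 120.0),  # torsion C4-C1'-C2'-C3'
    }
    chain: list[tuple[int, str]] = [(1, "C1"), (1, "C2"), (1, "C3")]
    to_place: list[tuple[int, str]] = [(1, "C4")]
    for u in range(2, n + 1):
        to_place += [(u, "C1"), (u, "C2"), (u, "C3"), (u, "C4")]
    for u, name in to_place:
        bond, angle, torsion = recipe[name]
        if name == "C4":
            torsion = 0.0  # cis is structural, not overridable
        else:
            handedness = -1.0 if u % 2 == 0 else 1.0
            torsion = overrides.get((u, name), handedness * torsion)
        a, b, c = (pos[k] for k in chain[-3:])
        pos[(u, name)] = _place(a, b, c, bond, angle, torsion)
        chain.append((u, name))

    # --- substituents ------------------------------------------------------
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    index: dict[tuple[int, str], int] = {}

    def add(unit_i: int, name: str, element: str, xyz: np.ndarray) -> int:
        i = len(atoms)
        atoms.append(Atom(
            serial=i + 1, name=name, element=element, residue_name="IPR",
            residue_number=unit_i, chain_id="A", position=xyz,
        ))
        index[(unit_i, name)] = i
        return i

    for u in range(1, n + 1):
        c1, c2, c3, c4 = (pos[(u, k)] for k in ("C1", "C2", "C3", "C4"))
        add(u, "C1", "C", c1)
        add(u, "C2", "C", c2)
        add(u, "C3", "C", c3)
        add(u, "C4", "C", c4)
        c5 = _sp2_third(c2, c1, c3, CC_SINGLE)
        add(u, "C5", "C", c5)

        # C1 hydrogens: 2 for internal units, 3 at the dimethyl terminus.
        if u == 1:
            for k, h in enumerate(_sp3_cap(c1, c2, c3), start=1):
                add(u, f"H1{k}", "H", h)
        else:
            prev_c4 = pos[(u - 1, "C4")]
            for k, h in enumerate(_sp3_pair(c1, prev_c4, c2), start=1):
                add(u, f"H1{k}", "H", h)
        # C3 vinylic hydrogen (in the sp2 plane).
        add(u, "H3", "H", _sp2_third(c3, c2, c4, CH_BOND))
        # C4 hydrogens: 2 internal, 3 at the far terminus.
        if u == n:
            for k, h in enumerate(_sp3_cap(c4, c3, c2), start=1):
                add(u, f"H4{k}", "H", h)
        else:
            next_c1 = pos[(u + 1, "C1")]
            for k, h in enumerate(_sp3_pair(c4, c3, next_c1), start=1):
                add(u, f"H4{k}", "H", h)
        # Methyl hydrogens.
        for k, h in enumerate(_sp3_cap(c5, c2, c1), start=1):
            add(u, f"H5{k}", "H", h)

    # --- bond list ---------------------------------------------------------
    for u in range(1, n + 1):
        bonds.append((index[(u, "C1")], index[(u, "C2")]))
        bonds.append((index[(u, "C2")], index[(u, "C3")]))
        bonds.append((index[(u, "C3")], index[(u, "C4")]))
        bonds.append((index[(u, "C2")], index[(u, "C5")]))
        if u < n:
            bonds.append((index[(u, "C4")], index[(u + 1, "C1")]))
    for (u, name), i in index.items():
        if atoms[i].element != "H":
            continue
        carbon = "C" + name[1]
        bonds.append((index[(u, carbon)], i))

    structure = MolecularStructure(atoms, bonds)
    _check_clashes(structure)

    double_bonds = [(index[(u, "C2")], index[(u, "C3")]) for u in range(1, n + 1)]
    terminus = (index[(1, "C1")], index[(n, "C4")])
    return PolymerModel(n, structure, double_bonds, terminus)


def _check_clashes(structure: MolecularStructure, min_dist: float = 1.0) -> None:
    from scipy.spatial import cKDTree

    coords = structure.coords
    bonded = {frozenset(b) for b in structure.bonds}
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        if frozenset((i, j)) not in bonded:
            raise ValueError(
                f"steric clash: atoms {i} and {j} are "
                f"{np.linalg.norm(coords[i] - coords[j]):.2f} Å apart"
            )


def chain_width(model: PolymerModel, radius_if_single: float = 1.7) -> float:
    """Maximum cross-sectional width of an extended chain, Å.

    Heavy atoms are projected onto the plane perpendicular to the chain's
    principal axis; the width is the largest pairwise distance among the
    projections plus a 1.1 Å hydrogen allowance.  A single-atom model
    degenerates to its own vdW diameter.
    """
    heavy = [a for a in model.structure.atoms if a.element.upper() != "H"]
    if len(heavy) == 1:
        r = heavy[0].vdw_radius if heavy[0].vdw_radius else radius_if_single
        return 2.0 * r
    if len(heavy) < 3:
        raise ValueError("chain axis undefined for fewer than 3 heavy atoms")
    coords = np.array([a.position for a in heavy])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered - np.outer(centered @ axis, axis)
    diffs = proj[:, None, :] - proj[None, :, :]
    width = float(np.sqrt((diffs ** 2).sum(-1)).max())
    return width + HYDROGEN_ALLOWANCE


def polymer_from_structure(structure: MolecularStructure, resname: str = "IPR") -> PolymerModel:
    """Recover a :class:`PolymerModel` view (double-bond and terminus
    indices) from a structure containing a built polyisoprene chain,
    using the builder's atom naming (C2=C3 per residue of ``resname``)."""
    units: dict[int, dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name.upper() == resname.upper() and a.name.upper() in ("C1", "C2", "C3", "C4"):
            units.setdefault(a.residue_number, {})[a.name.upper()] = i
    if not units:
        raise ValueError(f"no residues named {resname!r} with polymer carbon naming found")
    numbers = sorted(units)
    double_bonds = []
    for u in numbers:
        if "C2" not in units[u] or "C3" not in units[u]:
            raise ValueError(f"residue {u} lacks C2/C3 double-bond carbons")
        double_bonds.append((units[u]["C2"], units[u]["C3"]))
    terminus = (units[numbers[0]]["C1"], units[numbers[-1]]["C4"])
    return PolymerModel(len(numbers), structure, double_bonds, terminus)


def cleavage_products(n: int, k: int) -> tuple[int, int]:
    """Intact-double-bond counts of the two oligomers left by cleaving
    bond number k (from the dimethyl terminus) of an n-mer.

    The cleaved bond's own unit loses its C=C, so the products carry
    ``k - 1`` and ``n - k`` intact double bonds: cleaving bond 5 of the
    10-mer gives the 4- and 5-unit oligomers.
    """
    if n < 1:
        raise ValueError(f"monomer count must be >= 1, got {n}")
    if not (1 <= k <= n):
        raise ValueError(f"bond number must be in 1..{n}, got {k}")
    return (k - 1, n - k)
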