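"""Solvent-accessible surface area and receptor:peptide interface analysis.

SASA uses the Shrake–Rupley quadrature: each atom is expanded by the
probe radius and covered with a fixed golden-section spiral point set;
the accessible fraction of points (those outside every neighbour's
expanded sphere) times the expanded-sphere area is the atom's SASA.
The quadrature directions are expressed in a frame derived from the
molecule's principal axes, so the result is invariant under rigid
motion of the whole input by construction.

Interface quantities follow the standard ΔSASA definition:
``buried_total = SASA(A alone) + SASA(B alone) − SASA(A∪B)`` with the
isolated parts kept at their complex coordinates.  Because the
literature reports interface size under both the total-ΔSASA and the
per-side ("PISA interface area" = total/2) conventions, both numbers
are carried in the report.

Hydrogen bonds are detected on heavy-atom geometry (donor–acceptor
distance plus the angle at the donor measured via its covalent
antecedent); salt bridges pair the guanidinium/amino/imidazolium
nitrogens with carboxylate oxygens.  BH3 hot-spot burial is the
fractional loss of side-chain SASA upon complexation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomKey, AtomRecord, ResidueKey, Structure

AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}

DEFAULT_RADII = {  # NACCESS-like van der Waals radii, Å
    "C_aliphatic": 1.87,
    "C_sp2": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "default": 1.80,
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def atom_radius(atom: AtomRecord, radii: dict[str, float]) -> float:
    """vdW radius by element and atom class (carbonyl/aromatic C vs aliphatic)."""
    el = atom.element.upper()
    if el == "C":
        if atom.name == "C":  # backbone carbonyl
            return radii["C_sp2"]
        if atom.name in AROMATIC_CARBONS.get(atom.resname, ()):
            return radii["C_sp2"]
        if atom.name in {"CG", "CD"} and atom.resname in {"ASP", "GLU", "ASN", "GLN", "ARG"}:
            return radii["C_sp2"]  # carboxylate/amide/guanidinium carbon
        return radii["C_aliphatic"]
    if el in radii:
        return radii[el]
    if "default" in radii:
        return radii["default"]
    raise ValueError(f"no vdW radius for element {atom.element!r} (atom {atom.atom_key})")


@dataclass
class SASAParams:
    probe_radius: float = 1.4
    sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    include_het: bool = False
    include_water: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be ≥ 0")
        if self.sphere_points < 60:
            raise ValueError("need ≥ 60 quadrature points")


@dataclass
class SASAResult:
    per_atom: dict[AtomKey, float]
    per_residue: dict[ResidueKey, float]
    total: float


def sphere_quadrature(n: int) -> np.ndarray:
    """n unit vectors on a golden-section spiral (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (1 + 5**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame that co-rotates with the molecule.

    Built from reference atoms chosen by input order and geometry (first
    atom, last atom, and the atom farthest from the line through them),
    so a rigid motion of the whole coordinate set rotates the frame — and
    with it the quadrature directions — identically, making SASA
    rigid-motion invariant by construction.  Principal-axis frames are
    not used because elongated symmetric molecules (helices) have
    degenerate transverse moments.  Near-collinear inputs fall back to
    the identity frame.
    """
    if len(coords) < 3:
        return np.eye(3)
    e1 = coords[-1] - coords[0]
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        return np.eye(3)
    e1 = e1 / n1
    rel = coords - coords[0]
    perp = rel - np.outer(rel @ e1, e1)
    far = int(np.argmax((perp * perp).sum(axis=1)))
    v2 = perp[far]
    n2 = np.linalg.norm(v2)
    if n2 < 1e-6:  # collinear
        return np.eye(3)
    e2 = v2 / n2
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _sasa_atoms(
    atoms: list[AtomRecord], params: SASAParams, frame: np.ndarray | None = None
) -> np.ndarray:
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([atom_radius(a, params.radii_table) for a in atoms])
    expanded = radii + params.probe_radius
    if frame is None:
        frame = _principal_frame(coords)
    dirs = sphere_quadrature(params.sphere_points) @ frame.T
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        ri = expanded[i]
        pts = coords[i] + ri * dirs
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = expanded[neigh]
            keep = (np.abs(nc - coords[i]).max(axis=1) < ri + nr)
            nc, nr = nc[keep], nr[keep]
        accessible = np.ones(params.sphere_points, dtype=bool)
        if len(neigh) and len(nc):
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 > (nr**2)[None, :]).all(axis=1)
        frac = accessible.mean()
        areas[i] = frac * 4.0 * math.pi * ri * ri
    return areas


def _select_atoms(structure: Structure, params: SASAParams) -> list[AtomRecord]:
    out = []
    for a in structure.atoms:
        if a.is_water and not params.include_water:
            continue
        if a.het and not a.is_water and not params.include_het:
            continue
        if a.element.upper() == "H":
            continue
        out.append(a)
    return out


def sasa(
    structure: Structure,
    params: SASAParams | None = None,
    frame: np.ndarray | None = None,
) -> SASAResult:
    """Shrake–Rupley SASA of a structure (waters/heteroatoms excluded by default).

    *frame* fixes the quadrature orientation explicitly; interface
    calculations pass the complex's frame so that isolated-part and
    complex SASA are evaluated with identical point sets.
    """
    params = params or SASAParams()
    atoms = _select_atoms(structure, params)
    if not atoms:
        raise ValueError("no atoms with known radii to compute SASA over")
    areas = _sasa_atoms(atoms, params, frame=frame)
    per_atom: dict[AtomKey, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for a, area in zip(atoms, areas):
        per_atom[a.atom_key] = float(area)
        per_residue[a.residue_key] = per_residue.get(a.residue_key, 0.0) + float(area)
    return SASAResult(per_atom=per_atom, per_residue=per_residue, total=float(areas.sum()))


# ---------------------------------------------------------------------------
# interface


@dataclass
class HBond:
    donor: AtomKey
    acceptor: AtomKey
    distance: float
    angle: float | None  # degrees at donor (antecedent–donor–acceptor)


@dataclass
class SaltBridge:
    basic_atom: AtomKey
    acidic_atom: AtomKey
    distance: float


@dataclass
class HotspotBurial:
    residue: ResidueKey
    resname: str
    sasa_free: float
    sasa_complexed: float
    burial_fraction: float
    engaged: bool


@dataclass
class InterfaceReport:
    buried_total: float
    buried_per_partner: tuple[float, float]
    interface_area_pisa: float
    hbonds: list[HBond] = field(default_factory=list)
    salt_bridges: list[SaltBridge] = field(default_factory=list)
    hotspots: list[HotspotBurial] = field(default_factory=list)


def buried_surface(
    complex_structure: Structure,
    part_a: set[str] | list[str],
    part_b: set[str] | list[str],
    params: SASAParams | None = None,
) -> InterfaceReport:
    """ΔSASA interface area between two disjoint chain sets of one complex."""
    params = params or SASAParams()
    part_a, part_b = set(part_a), set(part_b)
    if part_a & part_b:
        raise ValueError(f"chain sets overlap: {sorted(part_a & part_b)}")
    union = complex_structure.subset(part_a | part_b)
    # one quadrature frame for all three evaluations: atoms common to an
    # isolated part and the complex then see identical point sets, so
    # non-contacting atoms contribute exactly zero ΔSASA
    frame = _principal_frame(
        np.array([[a.x, a.y, a.z] for a in _select_atoms(union, params)])
    )
    sasa_a = sasa(complex_structure.subset(part_a), params, frame=frame)
    sasa_b = sasa(complex_structure.subset(part_b), params, frame=frame)
    sasa_ab = sasa(union, params, frame=frame)
    buried_a = sum(
        area - sasa_ab.per_atom.get(k, 0.0) for k, area in sasa_a.per_atom.items()
    )
    buried_b = sum(
        area - sasa_ab.per_atom.get(k, 0.0) for k, area in sasa_b.per_atom.items()
    )
    total = sasa_a.total + sasa_b.total - sasa_ab.total
    return InterfaceReport(
        buried_total=total,
        buried_per_partner=(buried_a, buried_b),
        interface_area_pisa=total / 2.0,
    )


# donor atom name → covalent antecedent name (per residue where specific)
_DONORS: dict[str, dict[str, str]] = {
    "*": {"N": "CA"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

BASIC_ATOMS = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}

ACIDIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _residue_atoms(structure: Structure) -> dict[ResidueKey, dict[str, AtomRecord]]:
    by_res: dict[ResidueKey, dict[str, AtomRecord]] = {}
    for a in structure.atoms:
        by_res.setdefault(a.residue_key, {})[a.name] = a
    return by_res


def _donors_of(structure: Structure, chains: set[str]) -> list[tuple[AtomRecord, AtomRecord | None]]:
    by_res = _residue_atoms(structure)
    out = []
    for a in structure.protein_atoms():
        if a.chain not in chains:
            continue
        table = {**_DONORS["*"], **_DONORS.get(a.resname, {})}
        if a.name in table:
            antecedent = by_res[a.residue_key].get(table[a.name])
            out.append((a, antecedent))
    return out


def _acceptors_of(structure: Structure, chains: set[str]) -> list[AtomRecord]:
    out = []
    for a in structure.protein_atoms():
        if a.chain not in chains:
            continue
        names = _ACCEPTORS["*"] | _ACCEPTORS.get(a.resname, set())
        if a.name in names:
            out.append(a)
    return out


def _angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def find_hbonds(
    complex_structure: Structure,
    part_a: set[str] | list[str],
    part_b: set[str] | list[str],
    d_max: float = 3.5,
    angle_min: float = 90.0,
) -> list[HBond]:
    """Cross-interface hydrogen bonds on heavy-atom geometry.

    A donor–acceptor pair is reported when the distance is ≤ *d_max* and
    the angle antecedent–donor–acceptor is ≥ *angle_min* (no explicit
    hydrogens; if the donor's antecedent is missing the angle test is
    waived).  Each unordered atom pair is reported once.
    """
    part_a, part_b = set(part_a), set(part_b)
    found: dict[tuple[AtomKey, AtomKey], HBond] = {}
    for da_chains, acc_chains in ((part_a, part_b), (part_b, part_a)):
        donors = _donors_of(complex_structure, da_chains)
        acceptors = _acceptors_of(complex_structure, acc_chains)
        if not donors or not acceptors:
            continue
        acc_coords = np.array([a.coord for a in acceptors])
        tree = cKDTree(acc_coords)
        for donor, antecedent in donors:
            for j in tree.query_ball_point(donor.coord, d_max):
                acc = acceptors[j]
                if acc.residue_key == donor.residue_key:
                    continue
                dist = float(np.linalg.norm(acc.coord - donor.coord))
                angle = None
                if antecedent is not None:
                    angle = _angle_deg(antecedent.coord, donor.coord, acc.coord)
                    if angle < angle_min:
                        continue
                key = tuple(sorted((donor.atom_key, acc.atom_key)))
                if key not in found or found[key].distance > dist:
                    found[key] = HBond(
                        donor=donor.atom_key, acceptor=acc.atom_key,
                        distance=dist, angle=angle,
                    )
    return sorted(found.values(), key=lambda h: (h.donor, h.acceptor))


def find_salt_bridges(
    complex_structure: Structure,
    part_a: set[str] | list[str],
    part_b: set[str] | list[str],
    d_max: float = 4.0,
) -> list[SaltBridge]:
    """Cross-interface basic/acidic heavy-atom pairs within *d_max* Å."""
    part_a, part_b = set(part_a), set(part_b)

    def pick(chains: set[str], table: dict[str, set[str]]) -> list[AtomRecord]:
        return [
            a for a in complex_structure.protein_atoms()
            if a.chain in chains and a.name in table.get(a.resname, set())
        ]

    bridges: list[SaltBridge] = []
    for basic_chains, acidic_chains in ((part_a, part_b), (part_b, part_a)):
        basics = pick(basic_chains, BASIC_ATOMS)
        acidics = pick(acidic_chains, ACIDIC_ATOMS)
        for b in basics:
            for ac in acidics:
                dist = float(np.linalg.norm(b.coord - ac.coord))
                if dist <= d_max:
                    bridges.append(
                        SaltBridge(basic_atom=b.atom_key, acidic_atom=ac.atom_key,
                                   distance=dist)
                    )
    return sorted(bridges, key=lambda s: (s.basic_atom, s.acidic_atom))


def hotspot_burial(
    complex_structure: Structure,
    receptor_chains: set[str] | list[str],
    peptide_chain: str,
    hotspot_residues: list[ResidueKey],
    params: SASAParams | None = None,
    engaged_threshold: float = 0.7,
) -> list[HotspotBurial]:
    """Fractional side-chain burial of BH3 hot-spot residues upon binding.

    burial = 1 − SASA(side chain, complex)/SASA(side chain, free peptide),
    with the free peptide kept at complex coordinates.
    """
    params = params or SASAParams()
    receptor_chains = set(receptor_chains)
    peptide = complex_structure.subset({peptide_chain})
    whole = complex_structure.subset(receptor_chains | {peptide_chain})
    frame = _principal_frame(
        np.array([[a.x, a.y, a.z] for a in _select_atoms(whole, params)])
    )
    sasa_free = sasa(peptide, params, frame=frame)
    sasa_cplx = sasa(whole, params, frame=frame)
    by_res = _residue_atoms(peptide)
    out: list[HotspotBurial] = []
    for key in hotspot_residues:
        if key not in by_res:
            raise KeyError(f"hotspot residue {key} not in peptide chain {peptide_chain}")
        atoms = by_res[key]
        resname = next(iter(atoms.values())).resname
        side = [a for a in atoms.values() if a.name not in BACKBONE_NAMES
                and a.element.upper() != "H"]
        if not side:
            warnings.warn(f"hotspot {key} ({resname}) has no side chain", stacklevel=2)
            out.append(HotspotBurial(key, resname, 0.0, 0.0, 0.0, False))
            continue
        free = sum(sasa_free.per_atom.get(a.atom_key, 0.0) for a in side)
        cplx = sum(sasa_cplx.per_atom.get(a.atom_key, 0.0) for a in side)
        if free <= 0:
            warnings.warn(f"hotspot {key} side chain already fully buried in the "
                          f"free peptide", stacklevel=2)
            frac = 0.0
        else:
            frac = min(max(1.0 - cplx / free, 0.0), 1.0)
        out.append(HotspotBurial(key, resname, free, cplx, frac,
                                 frac >= engaged_threshold))
    return out
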