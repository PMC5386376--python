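"""Synthetic fixtures: parametric helices and bundles, rigid motions,
coordinate noise, peptide-in-groove toy complexes, and motif-bearing
sequences.

Everything here is a pure function of its spec and seed.  The
geometry is idealised (helical wheels, pseudo side-chain atoms,
contact placements at exact target distances) — adequate for
exercising superposition, SASA and contact detection, with no claim
of force-field realism.  Complex generators return a ground-truth
sidecar describing the contacts that were planted, so downstream
tests assert against the plan rather than re-deriving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, Structure

IDEAL_RISE = 1.5       # Å per residue along the helix axis
IDEAL_TWIST = 100.0    # degrees per residue
IDEAL_RADIUS = 2.3     # Å, Cα helical-wheel radius


@dataclass
class HelixSpec:
    n_residues: int
    rise: float = IDEAL_RISE
    twist: float = IDEAL_TWIST
    radius: float = IDEAL_RADIUS
    sequence: str | None = None  # one-letter; defaults to poly-Ala
    with_sidechains: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("a helix needs at least 3 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must match n_residues")


@dataclass
class NoiseSpec:
    sigma: float  # Å per coordinate axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _helix_coords(spec: HelixSpec) -> np.ndarray:
    i = np.arange(spec.n_residues, dtype=float)
    theta = np.radians(spec.twist) * i
    return np.column_stack(
        [spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * i]
    )


def make_helix(
    spec: HelixSpec, chain: str = "A", start_resseq: int = 1, structure_id: str = "helix"
) -> Structure:
    """Cα-trace α-helix along +z, optionally with outward CB pseudo-atoms."""
    coords = _helix_coords(spec)
    seq = spec.sequence or "A" * spec.n_residues
    atoms: list[AtomRecord] = []
    serial = 0
    for idx in range(spec.n_residues):
        resname = _ONE_TO_THREE.get(seq[idx].upper(), "ALA")
        x, y, z = coords[idx]
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="CA", altloc="", resname=resname, chain=chain,
            resseq=start_resseq + idx, icode="", x=x, y=y, z=z,
            occupancy=1.0, bfactor=20.0, element="C",
        ))
        if spec.with_sidechains and resname != "GLY":
            # CB pseudo-atom 1.5 Å further out along the wheel radius
            r = math.hypot(x, y)
            scale = (r + 1.5) / r if r > 0 else 1.0
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name="CB", altloc="", resname=resname, chain=chain,
                resseq=start_resseq + idx, icode="", x=x * scale, y=y * scale, z=z,
                occupancy=1.0, bfactor=20.0, element="C",
            ))
    return Structure(id=structure_id, atoms=atoms)


def make_bundle(
    n_helices: int = 4,
    helix_length: int = 15,
    bundle_radius: float = 8.0,
    chain: str = "A",
    spec: HelixSpec | None = None,
) -> Structure:
    """Antiparallel helical bundle: helices on a circle, alternating direction.

    All helices share one chain with sequential residue numbering, which
    is what the superposition and RMSD-matrix tests operate on.
    """
    base = spec or HelixSpec(n_residues=helix_length)
    atoms: list[AtomRecord] = []
    serial = 0
    resseq = 0
    for h in range(n_helices):
        helix = make_helix(base, chain=chain)
        coords = np.array([[a.x, a.y, a.z] for a in helix.atoms])
        if h % 2 == 1:  # antiparallel: flip along z
            coords[:, 2] = coords[:, 2].max() - coords[:, 2]
        phi = 2 * math.pi * h / n_helices
        offset = np.array(
            [bundle_radius * math.cos(phi), bundle_radius * math.sin(phi), 0.0]
        )
        coords = coords + offset
        for a, (x, y, z) in zip(helix.atoms, coords):
            serial += 1
            if a.name == "CA":
                resseq += 1
            atoms.append(AtomRecord(
                serial=serial, name=a.name, altloc="", resname=a.resname,
                chain=chain, resseq=resseq, icode="", x=x, y=y, z=z,
                occupancy=1.0, bfactor=20.0, element=a.element,
            ))
    return Structure(id="bundle", atoms=atoms)


def transform_structure(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Apply a rigid motion (rotation then translation) to every atom."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    atoms = []
    for a in structure.atoms:
        x, y, z = R @ np.array([a.x, a.y, a.z]) + t
        atoms.append(AtomRecord(
            serial=a.serial, name=a.name, altloc=a.altloc, resname=a.resname,
            chain=a.chain, resseq=a.resseq, icode=a.icode, x=x, y=y, z=z,
            occupancy=a.occupancy, bfactor=a.bfactor, element=a.element, het=a.het,
        ))
    return Structure(id=structure.id, atoms=atoms, model_index=structure.model_index)


def rotation_about_z(degrees: float) -> np.ndarray:
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def perturb(structure: Structure, noise: NoiseSpec) -> Structure:
    """Add iid per-axis Gaussian coordinate noise; reproducible by seed."""
    rng = np.random.default_rng(noise.seed)
    atoms = []
    for a in structure.atoms:
        dx, dy, dz = rng.normal(0.0, noise.sigma, size=3) if noise.sigma > 0 else (0, 0, 0)
        atoms.append(AtomRecord(
            serial=a.serial, name=a.name, altloc=a.altloc, resname=a.resname,
            chain=a.chain, resseq=a.resseq, icode=a.icode,
            x=a.x + dx, y=a.y + dy, z=a.z + dz,
            occupancy=a.occupancy, bfactor=a.bfactor, element=a.element, het=a.het,
        ))
    return Structure(id=structure.id, atoms=atoms, model_index=structure.model_index)


# ---------------------------------------------------------------------------
# peptide-in-groove toy complexes


@dataclass
class ContactPlan:
    """Planted interface features for a toy receptor:peptide complex.

    ``hbonds``/``salt_bridges`` list (peptide_residue_index, distance Å)
    pairs; ``hotspots`` lists peptide residue indices whose side chain
    is to be enclosed by a receptor cage.  Indices are 1-based residue
    numbers within the peptide chain.
    """

    hbonds: list[tuple[int, float]] = field(default_factory=list)
    salt_bridges: list[tuple[int, float]] = field(default_factory=list)
    hotspots: list[int] = field(default_factory=list)
    separation: float = 0.0  # extra receptor displacement, Å


MIN_CONTACT_CLEARANCE = 1.5  # Å


class PlacementError(ValueError):
    pass


def make_groove_complex(
    peptide_length: int = 15,
    plan: ContactPlan | None = None,
    peptide_chain: str = "P",
    receptor_chain: str = "R",
) -> tuple[Structure, dict]:
    """Build a two-chain toy complex realising a contact plan exactly.

    The peptide is an ideal helix (chain P).  For each planted hydrogen
    bond the peptide residue becomes Ser (CB–OG) and a receptor Glu
    (CD–OE1) is placed with OE1 at the target distance along the
    outward OG direction; for each salt bridge the peptide residue
    becomes Asp (CB–OD1) and a receptor Arg (CZ–NH1) is placed the same
    way; each hotspot residue becomes Leu (CB–CG) and its CG is
    enclosed in a 12-atom carbon cage of radius 4 Å.  Returns the
    complex and a ground-truth sidecar dict.
    """
    plan = plan or ContactPlan()
    helix = make_helix(
        HelixSpec(n_residues=peptide_length, with_sidechains=True),
        chain=peptide_chain,
        structure_id="groove_complex",
    )
    atoms = list(helix.atoms)
    by_res: dict[int, dict[str, AtomRecord]] = {}
    for a in atoms:
        by_res.setdefault(a.resseq, {})[a.name] = a

    def outward(res: int) -> tuple[np.ndarray, np.ndarray]:
        ca = by_res[res]["CA"].coord
        cb = by_res[res]["CB"].coord
        direction = cb - ca
        return cb, direction / np.linalg.norm(direction)

    def rename(res: int, resname: str) -> None:
        for name, a in list(by_res[res].items()):
            idx = atoms.index(a)
            new = AtomRecord(
                serial=a.serial, name=a.name, altloc="", resname=resname,
                chain=a.chain, resseq=a.resseq, icode="", x=a.x, y=a.y, z=a.z,
                occupancy=1.0, bfactor=20.0, element=a.element,
            )
            atoms[idx] = new
            by_res[res][name] = new

    def add_atom(name: str, resname: str, resseq: int, pos: np.ndarray,
                 element: str, chain: str) -> AtomRecord:
        a = AtomRecord(
            serial=len(atoms) + 1, name=name, altloc="", resname=resname,
            chain=chain, resseq=resseq, icode="",
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            occupancy=1.0, bfactor=20.0, element=element,
        )
        atoms.append(a)
        return a

    truth: dict = {"hbonds": [], "salt_bridges": [], "hotspots": [],
                   "buried_positive": bool(plan.hbonds or plan.salt_bridges
                                           or plan.hotspots)}
    rec_resseq = 0
    sep = np.array([0.0, 0.0, 0.0])

    for res, dist in plan.hbonds:
        rename(res, "SER")
        cb, u = outward(res)
        og = add_atom("OG", "SER", res, cb + 1.4 * u, "O", peptide_chain)
        by_res[res]["OG"] = og
        rec_resseq += 1
        oe1 = og.coord + dist * u + sep
        cd = oe1 + 1.25 * u
        add_atom("OE1", "GLU", rec_resseq, oe1, "O", receptor_chain)
        add_atom("CD", "GLU", rec_resseq, cd, "C", receptor_chain)
        truth["hbonds"].append({
            "donor": [peptide_chain, res, "", "OG"],
            "acceptor": [receptor_chain, rec_resseq, "", "OE1"],
            "distance": dist,
        })

    for res, dist in plan.salt_bridges:
        rename(res, "ASP")
        cb, u = outward(res)
        od1 = add_atom("OD1", "ASP", res, cb + 1.4 * u, "O", peptide_chain)
        by_res[res]["OD1"] = od1
        rec_resseq += 1
        nh1 = od1.coord + dist * u + sep
        cz = nh1 + 1.33 * u
        add_atom("NH1", "ARG", rec_resseq, nh1, "N", receptor_chain)
        add_atom("CZ", "ARG", rec_resseq, cz, "C", receptor_chain)
        truth["salt_bridges"].append({
            "basic": [receptor_chain, rec_resseq, "", "NH1"],
            "acidic": [peptide_chain, res, "", "OD1"],
            "distance": dist,
        })

    # icosahedron + dodecahedron directions for hotspot cages (32 vertices,
    # dense enough that every solvent-exposed direction is occluded);
    # vertices that would clash with the peptide itself are dropped —
    # those directions are already occluded by the peptide
    phi = (1 + 5**0.5) / 2
    verts = [(0, 1, phi), (0, -1, phi), (0, 1, -phi), (0, -1, -phi),
             (1, phi, 0), (-1, phi, 0), (1, -phi, 0), (-1, -phi, 0),
             (phi, 0, 1), (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1)]
    verts += [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    verts += [(0, sy / phi, sz * phi) for sy in (1, -1) for sz in (1, -1)]
    verts += [(sx / phi, sy * phi, 0) for sx in (1, -1) for sy in (1, -1)]
    verts += [(sx * phi, 0, sz / phi) for sx in (1, -1) for sz in (1, -1)]
    cage_dirs = np.array(verts, dtype=float)
    cage_dirs /= np.linalg.norm(cage_dirs, axis=1)[:, None]

    for res in plan.hotspots:
        rename(res, "LEU")
        cb, u = outward(res)
        cg = add_atom("CG", "LEU", res, cb + 1.5 * u, "C", peptide_chain)
        by_res[res]["CG"] = cg
        rec_resseq += 1
        pep_coords = np.array(
            [[a.x, a.y, a.z] for a in atoms if a.chain == peptide_chain]
        )
        placed = 0
        for v in cage_dirs:
            pos = cg.coord + 4.0 * v
            clearance = np.sqrt(((pep_coords - pos) ** 2).sum(axis=1)).min()
            if clearance < MIN_CONTACT_CLEARANCE + 0.5:
                continue
            placed += 1
            add_atom(f"C{placed}", "CAG", rec_resseq, pos, "C", receptor_chain)
        if placed == 0:
            raise PlacementError(f"no cage vertex placeable around residue {res}")
        truth["hotspots"].append({"residue": [peptide_chain, res, ""],
                                  "cage_radius": 4.0})

    if plan.separation > 0:
        shifted = []
        for a in atoms:
            if a.chain == receptor_chain:
                shifted.append(AtomRecord(
                    serial=a.serial, name=a.name, altloc="", resname=a.resname,
                    chain=a.chain, resseq=a.resseq, icode="",
                    x=a.x + plan.separation, y=a.y, z=a.z,
                    occupancy=1.0, bfactor=20.0, element=a.element,
                ))
            else:
                shifted.append(a)
        atoms = shifted
        truth["buried_positive"] = False
        truth["hbonds"] = []
        truth["salt_bridges"] = []

    pep = np.array([[a.x, a.y, a.z] for a in atoms if a.chain == peptide_chain])
    rec = np.array([[a.x, a.y, a.z] for a in atoms if a.chain == receptor_chain])
    if len(rec):
        d = np.sqrt(((pep[:, None, :] - rec[None, :, :]) ** 2).sum(axis=2))
        if d.min() < MIN_CONTACT_CLEARANCE:
            raise PlacementError(
                f"receptor/peptide clash at {d.min():.2f} Å (< "
                f"{MIN_CONTACT_CLEARANCE} Å); adjust the contact plan"
            )
    return Structure(id="groove_complex", atoms=atoms), truth


# ---------------------------------------------------------------------------
# motif-bearing sequences

#: canonical 12-residue BH3 template: V...L..F.D.V with polar spacers
BH3_TEMPLATE = "VGQSLSNFSDGV"
DEFAULT_FLANK_ALPHABET = "STNQGKR"  # scores zero at every template slot


def make_bh3_sequence(
    position: int,
    total_length: int = 120,
    flank_alphabet: str = DEFAULT_FLANK_ALPHABET,
    seed: int = 0,
    extra_positions: list[int] | None = None,
) -> str:
    """Random-flank sequence with the BH3 consensus template at *position*.

    *position* is the 1-based location of h1.  Additional embeddings go
    at *extra_positions*; overlapping placements raise.
    """
    if position < 1:
        raise ValueError("position must be ≥ 1")
    placements = sorted([position] + list(extra_positions or []))
    for p, q in zip(placements, placements[1:]):
        if q < p + len(BH3_TEMPLATE):
            raise ValueError(f"template placements at {p} and {q} overlap")
    if placements[-1] + len(BH3_TEMPLATE) - 1 > total_length:
        raise ValueError("template does not fit in total_length")
    rng = np.random.default_rng(seed)
    letters = list(rng.choice(list(flank_alphabet), size=total_length))
    for p in placements:
        letters[p - 1 : p - 1 + len(BH3_TEMPLATE)] = list(BH3_TEMPLATE)
    return "".join(letters)
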