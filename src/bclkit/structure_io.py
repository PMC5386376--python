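"""Reading, writing and selecting protein coordinate models.

PDB-format files are parsed with :mod:`gemmi` and converted to a flat,
explicit atom-record representation.  Alternate locations are collapsed
deterministically (highest occupancy wins; ties go to the alphabetically
first altloc identifier), water and other heteroatoms are retained but
flagged, and residue numbering is kept exactly as deposited — mapping to
any other numbering scheme (e.g. Uniprot) is the caller's job.

Coordinates are Ångström throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: residue key: (chain, resseq, icode)
ResidueKey = tuple[str, int, str]
#: atom key: (chain, resseq, icode, atom name)
AtomKey = tuple[str, int, str, str]


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptySelectionError(ValueError):
    """Raised when a selection yields no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a coordinate model (PDB ATOM/HETATM semantics)."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    bfactor: float
    element: str
    het: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_key(self) -> AtomKey:
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """A single-model collection of atom records."""

    id: str
    atoms: list[AtomRecord]
    model_index: int = 1

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain]

    def atom_classes(self) -> dict[str, int]:
        """Partition atom counts into protein / water / other-hetero classes."""
        counts = {"protein": 0, "water": 0, "hetero": 0}
        for a in self.atoms:
            if a.is_water:
                counts["water"] += 1
            elif a.het:
                counts["hetero"] += 1
            else:
                counts["protein"] += 1
        return counts

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.het and not a.is_water]

    def subset(self, chains: set[str] | list[str]) -> "Structure":
        chains = set(chains)
        atoms = [a for a in self.atoms if a.chain in chains]
        if not atoms:
            raise EmptySelectionError(
                f"no atoms in chains {sorted(chains)}; available: {self.chains}"
            )
        return Structure(id=self.id, atoms=atoms, model_index=self.model_index)


@dataclass
class CoordSet:
    """Labelled N×3 coordinate matrix (typically one Cα per residue)."""

    labels: list[ResidueKey]
    coords: np.ndarray
    resnames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N×3")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("label count must equal coordinate row count")
        if self.coords.shape[0] < 1:
            raise ValueError("empty coordinate set")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def sequence(self) -> str:
        """One-letter sequence (X for non-standard residues)."""
        return "".join(
            seq1(rn.capitalize(), undef_code="X") if rn else "X"
            for rn in self.resnames
        )


def _element_from_name(name: str) -> str:
    """Infer the element symbol from an atom name (older PDB dialects)."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "NA",
                                                       "CL", "BR", "CA", "CU", "SE"}:
        # only trust two-letter symbols for names occupying the element column;
        # CA/CB etc. in proteins are carbon
        if name[:1] != " " and len(name.strip()) <= 2:
            return stripped[:2].capitalize()
    return stripped[0].upper()


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one altloc per atom site: highest occupancy, ties alphabetical."""
    best: dict[AtomKey, AtomRecord] = {}
    order: list[AtomKey] = []
    for a in atoms:
        k = a.atom_key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _altloc_rank(a.altloc)) > (
                b.occupancy, _altloc_rank(b.altloc)
            ):
                best[k] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins on occupancy tie → alphabetically FIRST altloc wins
    return -ord(altloc) if altloc else 1.0


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Altlocs are collapsed, waters and heteroatoms retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptySelectionError(f"{path}: no models / no ATOM records")
    model_obj = None
    for m in st:
        if m.num == model:
            model_obj = m
            break
    if model_obj is None:
        if model == 1 and len(st) >= 1:
            model_obj = st[0]
        else:
            raise EmptySelectionError(
                f"{path}: model {model} not present (models: {[m.num for m in st]})"
            )
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model_obj:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                serial += 1
                elem = at.element.name if at.element else ""
                if not elem or elem == "X":
                    elem = _element_from_name(at.name)
                atoms.append(
                    AtomRecord(
                        serial=at.serial or serial,
                        name=at.name,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        resname=res.name,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        bfactor=at.b_iso,
                        element=elem.capitalize(),
                        het=het,
                    )
                )
    if not atoms:
        raise EmptySelectionError(f"{path}: model contains no atoms")
    return Structure(id=path.stem, atoms=_collapse_altlocs(atoms), model_index=model)


_COORD_LIMIT = (-999.999, 9999.999)


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write fixed-width PDB ATOM/HETATM records (single model)."""
    if not structure.atoms:
        raise EmptySelectionError("refusing to write an empty structure")
    lines: list[str] = []
    prev_chain: str | None = None
    serial = 0
    for a in structure.atoms:
        for v in (a.x, a.y, a.z):
            if not _COORD_LIMIT[0] <= v <= _COORD_LIMIT[1]:
                raise ValueError(
                    f"coordinate {v} does not fit the 8.3 PDB field for atom "
                    f"{a.atom_key}"
                )
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER")
        prev_chain = a.chain
        serial += 1
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{serial:5d} {name}{a.altloc or ' ':1s}{a.resname:>3s} "
            f"{a.chain[:1]:1s}{a.resseq:4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
            f"          {a.element[:2]:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def select_ca(structure: Structure, chain: str) -> CoordSet:
    """One Cα per residue of *chain*, in residue order.

    Residues lacking a Cα (including waters/ligands) are omitted with a
    warning only when they are protein residues.
    """
    if chain not in structure.chains:
        raise EmptySelectionError(
            f"chain {chain!r} not found; available chains: {structure.chains}"
        )
    by_res: dict[ResidueKey, dict[str, AtomRecord]] = {}
    resnames: dict[ResidueKey, str] = {}
    order: list[ResidueKey] = []
    for a in structure.chain_atoms(chain):
        if a.is_water:
            continue
        k = a.residue_key
        if k not in by_res:
            by_res[k] = {}
            order.append(k)
            resnames[k] = a.resname
        by_res[k][a.name] = a
    labels: list[ResidueKey] = []
    names: list[str] = []
    rows: list[np.ndarray] = []
    for k in order:
        ca = by_res[k].get("CA")
        if ca is None or ca.element != "C":
            if not by_res[k] or next(iter(by_res[k].values())).het:
                continue
            warnings.warn(
                f"residue {k} ({resnames[k]}) has no Cα; omitted", stacklevel=2
            )
            continue
        labels.append(k)
        names.append(resnames[k])
        rows.append(ca.coord)
    if not rows:
        raise EmptySelectionError(f"chain {chain!r} has no Cα atoms")
    return CoordSet(labels=labels, coords=np.vstack(rows), resnames=names)


def partition_chains_by_size(
    structure: Structure, peptide_max_residues: int = 40
) -> tuple[list[str], list[str]]:
    """Split chains into (receptor-sized, peptide-sized) by Cα count.

    BH3 peptides are short (≈26–34 residues) while the receptor domain is
    an order of magnitude larger, so a simple length threshold resolves
    which deposited chain is which without relying on chain naming.
    """
    receptors: list[str] = []
    peptides: list[str] = []
    for ch in structure.chains:
        try:
            n = len(select_ca(structure, ch))
        except EmptySelectionError:
            continue
        (peptides if n <= peptide_max_residues else receptors).append(ch)
    return receptors, peptides
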