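"""Crystal-content arithmetic: cell volume, Matthews coefficient and
solvent fraction, and unique-reflection counting.

These are the quantities a crystallographer can check from a data
table alone: the triclinic cell volume, V_m = V/(z·MW) with the 1.23
Da/Å³ protein-density convention for the solvent fraction, and the
number of symmetry-unique reflections in a resolution shell obtained
by direct enumeration of Miller indices with lattice-centering
extinctions and Laue-group (Friedel-merged) orbit reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight

MATTHEWS_DENSITY = 1.23  # Da/Å³, standard protein-density constant
MEAN_RESIDUE_MASS = 110.0  # Da, used when only residue counts are known
WATER_MASS = 18.02  # Da, one condensation water per chain


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P1"
    z_asu: int = 1  # asymmetric units per cell

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} outside (0, 180)")


@dataclass
class AsuContent:
    """Chains in the asymmetric unit, as sequences or residue counts."""

    chains: list[str | int] = field(default_factory=list)
    mw_override: float | None = None  # Da, wins when provided

    @property
    def molecular_weight(self) -> float:
        if self.mw_override is not None:
            if self.mw_override <= 0:
                raise ValueError("MW must be positive")
            return self.mw_override
        total = 0.0
        for chain in self.chains:
            if isinstance(chain, int):
                total += chain * MEAN_RESIDUE_MASS + WATER_MASS
            else:
                total += molecular_weight(chain.upper(), seq_type="protein")
        if total <= 0:
            raise ValueError("ASU content has no mass")
        return total


def cell_volume(cell: UnitCell) -> float:
    """Triclinic cell volume in Å³ (reduces to a·b·c·sin β for monoclinic)."""
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise ValueError("cell angles do not define a positive volume")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def solvent_content(cell: UnitCell, content: AsuContent) -> tuple[float, float]:
    """(Matthews coefficient Å³/Da, solvent fraction %) for the cell.

    solvent % = 100·(1 − 1.23/V_m).  A V_m at or below 1.23 would imply
    negative solvent and is rejected as physically implausible.
    """
    mw = content.molecular_weight
    vm = cell_volume(cell) / (cell.z_asu * mw)
    if vm <= MATTHEWS_DENSITY:
        raise ValueError(
            f"Matthews coefficient {vm:.3f} Å³/Da ≤ {MATTHEWS_DENSITY}: "
            "physically implausible packing (check MW and z)"
        )
    return vm, 100.0 * (1.0 - MATTHEWS_DENSITY / vm)


# ---------------------------------------------------------------------------
# reflection counting

_CENTERING_RULES = {
    "P": lambda h, k, l: np.ones_like(h, dtype=bool),
    "I": lambda h, k, l: (h + k + l) % 2 == 0,
    "C": lambda h, k, l: (h + k) % 2 == 0,
    "A": lambda h, k, l: (k + l) % 2 == 0,
    "B": lambda h, k, l: (h + l) % 2 == 0,
    "F": lambda h, k, l: ((h % 2 == k % 2) & (k % 2 == l % 2)),
}


def _reciprocal_metric(cell: UnitCell) -> np.ndarray:
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    G = np.array(
        [
            [cell.a**2, cell.a * cell.b * cg, cell.a * cell.c * cb],
            [cell.a * cell.b * cg, cell.b**2, cell.b * cell.c * ca],
            [cell.a * cell.c * cb, cell.b * cell.c * ca, cell.c**2],
        ]
    )
    return np.linalg.inv(G)


def _laue_mates(space_group: str) -> list[np.ndarray]:
    """Rotation parts of the Laue group (Friedel mates added separately)."""
    sg = space_group.replace(" ", "")
    rest = sg[1:]
    identity = np.eye(3, dtype=int)
    if rest in {"1", "-1", ""}:
        return [identity]
    # monoclinic, unique axis b: 2-fold about b
    monoclinic_symbols = {"2", "21", "2/m", "21/m", "2/c", "21/c", "m", "c"}
    if rest.lower() in monoclinic_symbols:
        twofold_b = np.diag([-1, 1, -1])
        return [identity, twofold_b]
    raise NotImplementedError(
        f"space group {space_group!r} not supported (P1/-1 and monoclinic only)"
    )


def count_unique_reflections(
    cell: UnitCell,
    d_min: float,
    d_max: float,
    completeness: float = 1.0,
    canonical: str = "min",
) -> int:
    """Count symmetry-unique reflections with d_max ≥ d(hkl) ≥ d_min.

    Enumerates all integer (h, k, l) inside the resolution sphere,
    applies the lattice-centering condition, merges each orbit under the
    Laue rotations plus Friedel inversion to a single canonical
    representative, drops (0,0,0), and scales by the completeness.
    The canonicalization rule ("min"/"max" lexicographic) must not and
    does not change the count.
    """
    if d_min >= d_max:
        raise ValueError("d_min must be smaller than d_max")
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must be in (0, 1]")
    lattice = cell.space_group.replace(" ", "")[0].upper()
    if lattice not in _CENTERING_RULES:
        raise NotImplementedError(f"unknown lattice centering {lattice!r}")
    mates = _laue_mates(cell.space_group)
    gstar = _reciprocal_metric(cell)

    hmax = int(math.ceil(cell.a / d_min)) + 1
    kmax = int(math.ceil(cell.b / d_min)) + 1
    lmax = int(math.ceil(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    inv_d2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl)
    keep = (inv_d2 >= 1.0 / d_max**2) & (inv_d2 <= 1.0 / d_min**2) & (inv_d2 > 0)
    hkl = hkl[keep]
    cmask = _CENTERING_RULES[lattice](hkl[:, 0], hkl[:, 1], hkl[:, 2])
    hkl = hkl[cmask]

    # orbit canonicalization: all Laue mates and their Friedel pairs
    variants = []
    for R in mates:
        m = hkl @ np.asarray(R).T
        variants.append(m)
        variants.append(-m)
    stack = np.stack(variants, axis=1)  # n × n_ops × 3
    # lexicographic extreme over the orbit
    keys = (
        stack[:, :, 0].astype(np.int64) * 4_000_000
        + stack[:, :, 1].astype(np.int64) * 2_000
        + stack[:, :, 2].astype(np.int64)
    )
    if canonical == "min":
        rep = keys.min(axis=1)
    elif canonical == "max":
        rep = keys.max(axis=1)
    else:
        raise ValueError("canonical must be 'min' or 'max'")
    n_unique = len(np.unique(rep))
    return int(round(n_unique * completeness))
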