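"""Rigid-body least-squares superposition and Cα RMSD.

The optimal proper rotation is obtained by the Kabsch SVD construction:
for centred coordinate matrices P (moving) and Q (fixed), the cross
covariance H = PᵀQ is decomposed H = U S Vᵀ and the rotation is
R = V diag(1, 1, det(VUᵀ)) Uᵀ, which enforces det(R) = +1 (no
reflection) by flipping the axis of the smallest singular value when
necessary.  RMSD is always recomputed from the transformed coordinates,
never from the singular values.

For structures without a prior residue correspondence,
:func:`iterative_structure_align` seeds pairs from a sequence alignment
(or a gapless sliding-window search when the sequences are too
dissimilar) and then alternates superposition with re-pairing of
mutually nearest Cα atoms inside a distance cutoff until the pair set is
stable — a lightweight stand-in for full structure-alignment programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .structure_io import CoordSet, ResidueKey, Structure, select_ca


class SuperpositionError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    """Proper rigid transform mapping `moving` onto `fixed`, plus the RMSD."""

    rotation: np.ndarray  # 3×3, det = +1
    translation: np.ndarray  # Å
    rmsd: float  # Å
    n_pairs: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")
        if self.rmsd < 0:
            raise ValueError("negative RMSD")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _as_coords(cs: CoordSet | np.ndarray) -> np.ndarray:
    if isinstance(cs, CoordSet):
        return cs.coords
    return np.asarray(cs, dtype=float)


def kabsch(moving: CoordSet | np.ndarray, fixed: CoordSet | np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of paired coordinate sets."""
    P = _as_coords(moving)
    Q = _as_coords(fixed)
    if P.shape != Q.shape:
        raise SuperpositionError(
            f"paired sets must have equal shape, got {P.shape} vs {Q.shape}"
        )
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired atoms, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def rmsd(a: CoordSet | np.ndarray, b: CoordSet | np.ndarray) -> float:
    """Minimum RMSD between two paired coordinate sets (after superposition)."""
    return kabsch(a, b).rmsd


# ---------------------------------------------------------------------------
# sequence-independent iterative alignment


def _sequence_seed(ca_a: CoordSet, ca_b: CoordSet) -> list[tuple[int, int]]:
    """Residue pairing from a global sequence alignment of the two chains."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    seq_a = ca_a.sequence.replace("X", "A")
    seq_b = ca_b.sequence.replace("X", "A")
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend(
            (a_start + k, b_start + k) for k in range(a_end - a_start)
        )
    return pairs


def _sliding_window_seed(
    ca_a: CoordSet, ca_b: CoordSet, min_pairs: int = 20
) -> list[tuple[int, int]]:
    """Best gapless offset pairing, scored by superposition RMSD."""
    na, nb = len(ca_a), len(ca_b)
    best: tuple[float, list[tuple[int, int]]] | None = None
    for offset in range(-(nb - min_pairs), na - min_pairs + 1):
        i0 = max(0, offset)
        j0 = i0 - offset
        n = min(na - i0, nb - j0)
        if n < min_pairs:
            continue
        idx = [(i0 + k, j0 + k) for k in range(n)]
        r = kabsch(
            ca_a.coords[[i for i, _ in idx]], ca_b.coords[[j for _, j in idx]]
        ).rmsd
        if best is None or r < best[0]:
            best = (r, idx)
    if best is None:
        raise SuperpositionError("no gapless seed correspondence found")
    return best[1]


def _mutual_nearest_pairs(
    moved_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    tree_b = cKDTree(coords_b)
    tree_a = cKDTree(moved_a)
    d_ab, j_ab = tree_b.query(moved_a, distance_upper_bound=cutoff)
    d_ba, i_ba = tree_a.query(coords_b, distance_upper_bound=cutoff)
    pairs = [
        (i, int(j))
        for i, (d, j) in enumerate(zip(d_ab, j_ab))
        if np.isfinite(d) and i_ba[j] == i
    ]
    pairs.sort()  # smallest residue-index pair first (deterministic)
    return pairs


def iterative_structure_align(
    mobile: Structure,
    mobile_chain: str,
    fixed: Structure,
    fixed_chain: str,
    cutoff: float = 4.5,
    max_iter: int = 50,
) -> tuple[SuperpositionResult, list[tuple[ResidueKey, ResidueKey]]]:
    """Sequence-seeded iterative Cα alignment of two (possibly unrelated) chains.

    Returns the final superposition and the list of residue-key pairs it
    was computed over.  The pair count depends on the cutoff and is not
    comparable across alignment programs.
    """
    ca_m = select_ca(mobile, mobile_chain)
    ca_f = select_ca(fixed, fixed_chain)
    if len(ca_m) < 20 or len(ca_f) < 20:
        raise SuperpositionError("iterative alignment needs ≥20 Cα per chain")
    pairs = _sequence_seed(ca_m, ca_f)
    if len(pairs) < 3:
        pairs = _sliding_window_seed(ca_m, ca_f)
    result: SuperpositionResult | None = None
    for _ in range(max_iter):
        im = [i for i, _ in pairs]
        jf = [j for _, j in pairs]
        result = kabsch(ca_m.coords[im], ca_f.coords[jf])
        moved = result.apply(ca_m.coords)
        new_pairs = _mutual_nearest_pairs(moved, ca_f.coords, cutoff)
        if len(new_pairs) < 3:
            raise SuperpositionError(
                "iterative re-pairing collapsed below 3 pairs; structures too dissimilar"
            )
        if new_pairs == pairs:
            break
        pairs = new_pairs
    else:
        warnings.warn(
            f"pair set did not stabilise within {max_iter} iterations", stacklevel=2
        )
    assert result is not None
    im = [i for i, _ in pairs]
    jf = [j for _, j in pairs]
    result = kabsch(ca_m.coords[im], ca_f.coords[jf])
    labelled = [(ca_m.labels[i], ca_f.labels[j]) for i, j in pairs]
    return result, labelled
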