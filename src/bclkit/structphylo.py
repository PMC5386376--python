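"""Structure-based phylogeny from pairwise Cα RMSD.

Given a (structure-guided) multiple sequence alignment whose rows map to
coordinate models, every aligned column with residues resolved in both
structures contributes one Cα pair; each structure pair is superposed
independently over its shared columns and the resulting RMSD matrix is
clustered agglomeratively.  The dendrogram can be exported as newick
with the ultrametric convention that a leaf sits at half the merge
height of its cluster.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import structure_io
from .structure_io import CoordSet, Structure, select_ca
from .superpose import kabsch

LINKAGES = ("average", "single", "complete", "ward")


class OverlapError(ValueError):
    """Too few shared alignment columns between two mapped structures."""


@dataclass
class MSA:
    """Aligned sequences with an id → (Structure, chain) mapping."""

    records: list[tuple[str, str]]
    structure_map: dict[str, tuple[Structure, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError(f"gapped sequences have unequal lengths: {lengths}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        for sid, (st, chain) in self.structure_map.items():
            seq = self.sequence(sid).replace("-", "").replace(".", "")
            chain_seq = select_ca(st, chain).sequence
            n = min(len(seq), len(chain_seq))
            mismatches = sum(
                1 for a, b in zip(seq[:n], chain_seq[:n])
                if a != b and "X" not in (a, b)
            )
            if mismatches > 0.2 * n:
                warnings.warn(
                    f"{sid}: alignment sequence disagrees with chain {chain} "
                    f"({mismatches}/{n} mismatches)",
                    stacklevel=2,
                )

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, sid: str) -> str:
        for i, seq in self.records:
            if i == sid:
                return seq
        raise KeyError(sid)


def load_msa(alignment_path: str | Path, structure_map: dict[str, tuple[str | Path, str]],
             fmt: str | None = None) -> MSA:
    """Read an aligned FASTA/Clustal file and attach coordinate models."""
    alignment_path = Path(alignment_path)
    if fmt is None:
        fmt = "clustal" if alignment_path.suffix in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(alignment_path), fmt)
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    mapped = {
        sid: (structure_io.read_structure(path), chain)
        for sid, (path, chain) in structure_map.items()
    }
    return MSA(records=records, structure_map=mapped)


def load_structure_map(map_path: str | Path) -> dict[str, tuple[Path, str]]:
    """Read a TOML file of ``[structures]`` entries: id = {path, chain}."""
    with open(map_path, "rb") as fh:
        cfg = tomllib.load(fh)
    table = cfg.get("structures", cfg)
    out: dict[str, tuple[Path, str]] = {}
    for sid, entry in table.items():
        out[sid] = (Path(entry["path"]), str(entry["chain"]))
    return out


GAP_CHARS = {"-", "."}


def equivalent_ca_pairs(msa: MSA, id_a: str, id_b: str) -> tuple[CoordSet, CoordSet]:
    """Cα pairs for alignment columns resolved in both structures."""
    for sid in (id_a, id_b):
        if sid not in msa.structure_map:
            raise KeyError(f"{sid} has no mapped structure")
    seq_a = msa.sequence(id_a)
    seq_b = msa.sequence(id_b)
    st_a, ch_a = msa.structure_map[id_a]
    st_b, ch_b = msa.structure_map[id_b]
    ca_a = select_ca(st_a, ch_a)
    ca_b = select_ca(st_b, ch_b)
    ia = ib = 0
    rows_a: list[int] = []
    rows_b: list[int] = []
    for col_a, col_b in zip(seq_a, seq_b):
        gap_a = col_a in GAP_CHARS
        gap_b = col_b in GAP_CHARS
        if not gap_a and not gap_b:
            if ia < len(ca_a) and ib < len(ca_b):
                rows_a.append(ia)
                rows_b.append(ib)
            else:
                warnings.warn(
                    f"column beyond resolved residues of {id_a}/{id_b}; dropped",
                    stacklevel=2,
                )
        if not gap_a:
            ia += 1
        if not gap_b:
            ib += 1
    if len(rows_a) < 3:
        raise OverlapError(
            f"{id_a} vs {id_b}: only {len(rows_a)} shared columns (need ≥3)"
        )
    sub = lambda cs, rows: CoordSet(  # noqa: E731
        labels=[cs.labels[i] for i in rows],
        coords=cs.coords[rows],
        resnames=[cs.resnames[i] for i in rows],
    )
    return sub(ca_a, rows_a), sub(ca_b, rows_b)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # n×n, Å

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def rmsd_matrix(msa: MSA) -> DistanceMatrix:
    """Pairwise Kabsch RMSD over equivalent Cα atoms, each pair independently."""
    ids = [sid for sid in msa.ids if sid in msa.structure_map]
    if len(ids) < 2:
        raise ValueError("need at least 2 mapped structures")
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = equivalent_ca_pairs(msa, ids[i], ids[j])
            values[i, j] = values[j, i] = kabsch(a.coords, b.coords).rmsd
    return DistanceMatrix(labels=ids, values=values)


@dataclass
class Dendrogram:
    """Agglomerative merge list in scipy linkage form, with leaf labels."""

    merges: np.ndarray  # (n-1)×4 scipy linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if n > 1 and self.merges.shape[0] != n - 1:
            raise ValueError("a tree over n leaves needs n−1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def cluster(matrix: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Hierarchical clustering of a structural distance matrix (heights in Å)."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if not np.isfinite(matrix.values).all():
        raise ValueError("distance matrix has missing/non-finite entries")
    condensed = squareform(matrix.values, checks=True)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(merges=Z, labels=list(matrix.labels))


def to_newick(tree: Dendrogram) -> str:
    """Newick export; leaf depth = merge height / 2 (ultrametric convention)."""
    n = len(tree.labels)
    if n == 1:
        return f"{tree.labels[0]};"
    # branch length of a node = (parent merge height − own merge height)/2,
    # so leaves of an ultrametric matrix sit at height/2 from their parent
    def render(k: int, parent_h: float | None) -> str:
        if k < n:
            own = 0.0
            label = tree.labels[k]
        else:
            row = tree.merges[k - n]
            own = row[2]
            left = render(int(row[0]), own)
            right = render(int(row[1]), own)
            label = f"({left},{right})"
        if parent_h is None:
            return label
        return f"{label}:{(parent_h - own) / 2:.6g}"

    root = 2 * n - 2
    return render(root, None) + ";"


def permutation_invariant_topology(tree: Dendrogram) -> frozenset[frozenset[str]]:
    """Set of leaf-label clusters implied by the merges (topology fingerprint)."""
    n = len(tree.labels)
    members: dict[int, frozenset[str]] = {
        i: frozenset({tree.labels[i]}) for i in range(n)
    }
    clusters: set[frozenset[str]] = set()
    for idx, row in enumerate(tree.merges):
        merged = members[int(row[0])] | members[int(row[1])]
        members[n + idx] = merged
        clusters.add(merged)
    return frozenset(clusters)
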