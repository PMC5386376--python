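import dendropy
import numpy as np
import pytest

from bclkit import structphylo as ph
from bclkit import structure_io as sio
from bclkit import synthetic_data as sd


def _msa_for(structures: dict[str, sio.Structure], gapped: dict[str, str] | None = None):
    records = []
    smap = {}
    for sid, st in structures.items():
        seq = sio.select_ca(st, "A").sequence
        records.append((sid, gapped[sid] if gapped else seq))
        smap[sid] = (st, "A")
    return ph.MSA(records=records, structure_map=smap)


class TestEquivalentPairs:
    def test_gapless_alignment_pairs_all_columns(self, bundle):
        msa = _msa_for({"x": bundle, "y": bundle})
        a, b = ph.equivalent_ca_pairs(msa, "x", "y")
        assert len(a) == len(b) == len(sio.select_ca(bundle, "A"))

    def test_gap_columns_dropped(self):
        st = sd.make_helix(sd.HelixSpec(n_residues=10))
        seq = sio.select_ca(st, "A").sequence
        gapped_x = seq
        gapped_y = seq[:3] + "---" + seq[6:]  # 3 gap columns in y
        short = sd.make_helix(sd.HelixSpec(n_residues=7))
        msa = ph.MSA(
            records=[("x", gapped_x), ("y", gapped_y)],
            structure_map={"x": (st, "A"), "y": (short, "A")},
        )
        a, b = ph.equivalent_ca_pairs(msa, "x", "y")
        assert len(a) == 10 - 3

    def test_insufficient_overlap_raises(self):
        st = sd.make_helix(sd.HelixSpec(n_residues=4))
        msa = ph.MSA(
            records=[("x", "AA--"), ("y", "--AA")],
            structure_map={"x": (st, "A"), "y": (st, "A")},
        )
        with pytest.raises(ph.OverlapError):
            ph.equivalent_ca_pairs(msa, "x", "y")

    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            ph.MSA(records=[("x", "AAA"), ("y", "AAAA")], structure_map={})


class TestRmsdMatrix:
    def test_same_structure_twice_gives_zero(self, bundle):
        msa = _msa_for({"x": bundle, "y": bundle})
        m = ph.rmsd_matrix(msa)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_three_rigid_copies_all_zero(self, bundle, rng):
        copies = {
            f"c{i}": sd.transform_structure(
                bundle, sd.random_rotation(rng), rng.normal(0, 10, 3)
            )
            for i in range(3)
        }
        m = ph.rmsd_matrix(_msa_for(copies))
        assert np.allclose(m.values, 0.0, atol=1e-8)

    def test_entries_monotone_in_noise(self, bundle):
        structures = {"clean": bundle}
        for i, sigma in enumerate((0.5, 1.0, 2.0)):
            structures[f"s{sigma}"] = sd.perturb(
                bundle, sd.NoiseSpec(sigma=sigma, seed=100 + i)
            )
        m = ph.rmsd_matrix(_msa_for(structures))
        clean_row = m.values[0, 1:]
        assert clean_row[0] < clean_row[1] < clean_row[2]

    def test_symmetry_and_zero_diagonal(self, bundle):
        structures = {
            "a": bundle,
            "b": sd.perturb(bundle, sd.NoiseSpec(sigma=1.0, seed=7)),
            "c": sd.perturb(bundle, sd.NoiseSpec(sigma=2.0, seed=8)),
        }
        m = ph.rmsd_matrix(_msa_for(structures))
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.allclose(np.diag(m.values), 0.0, atol=1e-9)


ULTRAMETRIC = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])


class TestCluster:
    def test_ultrametric_toy_matrix_reproduced_exactly(self):
        m = ph.DistanceMatrix(labels=["A", "B", "C"], values=ULTRAMETRIC)
        tree = ph.cluster(m, linkage="average")
        assert list(tree.heights) == [2.0, 6.0]
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # {A, B} merge first

    def test_label_permutation_invariance(self):
        m1 = ph.DistanceMatrix(labels=["A", "B", "C"], values=ULTRAMETRIC)
        perm = [2, 0, 1]
        m2 = ph.DistanceMatrix(
            labels=[m1.labels[i] for i in perm],
            values=ULTRAMETRIC[np.ix_(perm, perm)],
        )
        t1, t2 = ph.cluster(m1), ph.cluster(m2)
        assert ph.permutation_invariant_topology(t1) == \
            ph.permutation_invariant_topology(t2)
        assert np.allclose(sorted(t1.heights), sorted(t2.heights))

    def test_topology_invariant_under_constant_shift(self):
        m1 = ph.DistanceMatrix(labels=["A", "B", "C"], values=ULTRAMETRIC)
        shifted = ULTRAMETRIC + 3.0
        np.fill_diagonal(shifted, 0.0)
        m2 = ph.DistanceMatrix(labels=["A", "B", "C"], values=shifted)
        assert ph.permutation_invariant_topology(ph.cluster(m1)) == \
            ph.permutation_invariant_topology(ph.cluster(m2))

    def test_outlier_joins_last(self, bundle):
        structures = {
            "host1": sd.perturb(bundle, sd.NoiseSpec(sigma=0.3, seed=1)),
            "host2": sd.perturb(bundle, sd.NoiseSpec(sigma=0.3, seed=2)),
            "path1": sd.perturb(bundle, sd.NoiseSpec(sigma=0.35, seed=3)),
            "outlier": sd.perturb(bundle, sd.NoiseSpec(sigma=4.0, seed=4)),
        }
        m = ph.rmsd_matrix(_msa_for(structures))
        tree = ph.cluster(m)
        last = tree.merges[-1]
        leaves = {int(last[0]), int(last[1])}
        assert m.labels.index("outlier") in leaves

    def test_asymmetric_matrix_rejected(self):
        bad = ULTRAMETRIC.copy()
        bad[0, 1] = 3.0
        with pytest.raises(ValueError, match="symmetric"):
            ph.DistanceMatrix(labels=["A", "B", "C"], values=bad)


class TestNewick:
    def test_single_leaf(self):
        t = ph.Dendrogram(merges=np.zeros((0, 4)), labels=["A"])
        assert ph.to_newick(t) == "A;"

    def test_ultrametric_branch_lengths(self):
        m = ph.DistanceMatrix(labels=["A", "B", "C"], values=ULTRAMETRIC)
        newick = ph.to_newick(ph.cluster(m))
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="force-rooted")
        depths = {}
        tree.calc_node_root_distances()
        for leaf in tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.root_distance
        # leaf depth = merge height / 2 → all leaves at 3, A/B via a node at 1
        assert depths == pytest.approx({"A": 3.0, "B": 3.0, "C": 3.0})
        ab_parent = tree.mrca(taxon_labels=["A", "B"])
        assert ab_parent.root_distance == pytest.approx(2.0)

    def test_roundtrip_preserves_topology(self, bundle):
        structures = {
            "a": sd.perturb(bundle, sd.NoiseSpec(sigma=0.5, seed=11)),
            "b": sd.perturb(bundle, sd.NoiseSpec(sigma=0.5, seed=12)),
            "c": sd.perturb(bundle, sd.NoiseSpec(sigma=2.0, seed=13)),
            "d": sd.perturb(bundle, sd.NoiseSpec(sigma=2.0, seed=14)),
        }
        m = ph.rmsd_matrix(_msa_for(structures))
        t = ph.cluster(m)
        newick = ph.to_newick(t)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        parsed_clusters = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in parsed.preorder_internal_node_iter()
        }
        ours = {c for c in ph.permutation_invariant_topology(t)}
        ours.add(frozenset(m.labels))
        assert parsed_clusters == ours
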