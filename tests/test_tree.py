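"""NJ/BIONJ agglomeration, rooting, and cross-checks against external oracles."""

import subprocess

import dendropy
import numpy as np
import pytest

from repeatarray import DistanceMatrix, TreeError, nj_tree, random_additive_case, robinson_foulds, root_tree


def three_taxon_matrix():
    return DistanceMatrix(
        labels=["A", "B", "C"],
        values=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
    )


def leaf_edge_lengths(pt):
    return {
        lf.taxon.label: lf.edge.length for lf in pt.tree.leaf_node_iter()
    }


def patristic(pt):
    pdm = pt.tree.phylogenetic_distance_matrix()
    taxa = list(pt.tree.taxon_namespace)
    out = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


class TestNJ:
    @pytest.mark.parametrize("method", ["nj", "bionj"])
    def test_three_taxon_exact_lengths(self, method):
        # three-point solution: a = (dAB+dAC-dBC)/2 = 1, b = 1, c = 2
        pt = nj_tree(three_taxon_matrix(), method=method)
        lens = leaf_edge_lengths(pt)
        assert lens == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    @pytest.mark.parametrize("method", ["nj", "bionj"])
    def test_four_taxon_additive_exact(self, method):
        # quartet ((A,B),(C,D)) with pendant lengths 1,2,3,4, internal 5
        labels = ["A", "B", "C", "D"]
        pend = dict(zip(labels, [1.0, 2.0, 3.0, 4.0]))
        internal = 5.0
        vals = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                d = pend[x] + pend[y]
                if {x, y} not in ({"A", "B"}, {"C", "D"}):
                    d += internal
                vals[i, j] = d
        pt = nj_tree(DistanceMatrix(labels=labels, values=vals), method=method)
        got = patristic(pt)
        for pair, d in got.items():
            x, y = sorted(pair)
            expect = pend[x] + pend[y] + (internal if {x, y} not in ({"A", "B"}, {"C", "D"}) else 0)
            assert d == pytest.approx(expect)

    @pytest.mark.parametrize("method", ["nj", "bionj"])
    def test_recovers_random_additive_topologies(self, method):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            dm, truth = random_additive_case(n, rng)
            pt = nj_tree(dm, method=method)
            assert robinson_foulds(pt, truth) == 0

    def test_star_matrix_zero_internal_branches(self):
        labels = [f"T{i}" for i in range(5)]
        vals = np.full((5, 5), 2.0)
        np.fill_diagonal(vals, 0.0)
        pt = nj_tree(DistanceMatrix(labels=labels, values=vals))
        internals = [
            e.length
            for e in pt.tree.preorder_edge_iter()
            if e.tail_node is not None and not e.head_node.is_leaf()
        ]
        assert all(abs(x) < 1e-9 for x in internals)

    def test_label_permutation_isomorphic(self):
        rng = np.random.default_rng(5)
        dm, _ = random_additive_case(8, rng)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in perm],
            values=dm.values[np.ix_(perm, perm)],
        )
        assert robinson_foulds(nj_tree(dm), nj_tree(dm2)) == 0

    def test_too_few_or_nonfinite_rejected(self):
        with pytest.raises(TreeError):
            nj_tree(DistanceMatrix(labels=["A", "B"], values=np.zeros((2, 2))))
        dm = three_taxon_matrix()
        dm.values[0, 1] = dm.values[1, 0] = np.inf
        with pytest.raises(TreeError):
            nj_tree(dm)


class TestRooting:
    @pytest.fixture
    def unrooted(self):
        rng = np.random.default_rng(3)
        dm, _ = random_additive_case(6, rng)
        return nj_tree(dm)

    def test_outgroup_becomes_root_child(self, unrooted):
        rooted = root_tree(unrooted, "T1")
        assert rooted.is_rooted
        children = rooted.tree.seed_node.child_nodes()
        assert len(children) == 2
        labels = {c.taxon.label for c in children if c.taxon}
        assert "T1" in labels

    def test_rooting_preserves_leaf_path_lengths(self, unrooted):
        rooted = root_tree(unrooted, "T2")
        before, after = patristic(unrooted), patristic(rooted)
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d)

    def test_unrooting_recovers_topology(self, unrooted):
        rooted = root_tree(unrooted, "T3")
        assert robinson_foulds(rooted, unrooted) == 0

    def test_unknown_outgroup_rejected(self, unrooted):
        with pytest.raises(TreeError):
            root_tree(unrooted, "nope")


class TestExternalOracles:
    """Independent implementations confirm topology and branch lengths."""

    def test_matches_scikit_bio_nj(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        dm, _ = random_additive_case(7, rng)
        ours = nj_tree(dm, method="nj")
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert robinson_foulds(ours, t2) == 0

    def test_matches_r_ape_bionj(self, tmp_path):
        rng = np.random.default_rng(23)
        dm, _ = random_additive_case(8, rng)
        dm.write_phylip(tmp_path / "m.phylip")
        script = tmp_path / "bionj.R"
        script.write_text(
            'm <- as.matrix(read.table("%s", skip=1, row.names=1))\n'
            "colnames(m) <- rownames(m)\n"
            "library(ape)\n"
            't <- bionj(as.dist(m))\n'
            'write.tree(t, "%s")\n' % (tmp_path / "m.phylip", tmp_path / "t.nwk")
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ape_tree = dendropy.Tree.get(path=str(tmp_path / "t.nwk"), schema="newick")
        ours = nj_tree(dm, method="bionj")
        assert robinson_foulds(ours, ape_tree) == 0
        # branch lengths agree on an additive matrix
        ns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=ours.newick(), schema="newick", taxon_namespace=ns)
        b = dendropy.Tree.get(path=str(tmp_path / "t.nwk"), schema="newick", taxon_namespace=ns)
        pa, pb = a.phylogenetic_distance_matrix(), b.phylogenetic_distance_matrix()
        for i, t1 in enumerate(ns):
            for t2 in list(ns)[i + 1 :]:
                assert pa.patristic_distance(t1, t2) == pytest.approx(
                    pb.patristic_distance(t1, t2), abs=1e-4
                )
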