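import numpy as np
import pytest
from scipy.stats import norm

from msatpop.bruvo import DistanceMatrix
from msatpop.genotype_io import to_repeat_table
from msatpop.trees import (
    DEFAULT_SCALES,
    Tree,
    _fit_au,
    multiscale_bootstrap,
    neighbor_joining,
    write_newick,
)

from conftest import make_table


def additive_matrix_4taxa():
    """A 4-taxon tree ((A:2,B:3):1,(C:4,D:5)); with known path lengths."""
    labels = ["A", "B", "C", "D"]
    # internal edge 1 between (A,B) node and (C,D) node
    d = {
        ("A", "B"): 5,
        ("A", "C"): 7,
        ("A", "D"): 8,
        ("B", "C"): 8,
        ("B", "D"): 9,
        ("C", "D"): 9,
    }
    m = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels, m), d


class TestNeighborJoining:
    def test_two_taxa(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = neighbor_joining(dm)
        pl = tree.path_lengths()
        assert pl[("a", "b")] == pytest.approx(0.6)

    def test_recovers_additive_distances_4taxa(self):
        dm, truth = additive_matrix_4taxa()
        tree = neighbor_joining(dm)
        pl = tree.path_lengths()
        for pair, v in truth.items():
            assert pl[pair] == pytest.approx(v), pair
        assert tree.n_clamped == 0

    def test_recovers_topology_4taxa(self):
        dm, _ = additive_matrix_4taxa()
        tree = neighbor_joining(dm)
        bips = tree.bipartitions()
        assert bips == {frozenset({"C", "D"})}

    def test_additive_random_trees(self):
        """NJ is exact on additive matrices: generate random trees, compute
        their path-length matrices, and check NJ returns the same distances."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # random binary coalescent-like topology with positive lengths
            import dendropy

            taxa = dendropy.TaxonNamespace(labels)
            t = dendropy.simulate.treesim.pure_kingman_tree(
                taxon_namespace=taxa,
                pop_size=1,
                rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            for e in t.edges():
                if e.length is not None:
                    e.length = float(rng.uniform(0.1, 2.0))
            pdm = t.phylogenetic_distance_matrix()
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    v = pdm.distance(taxa[i], taxa[j])
                    m[i, j] = m[j, i] = v
            tree = neighbor_joining(DistanceMatrix(labels, m))
            pl = tree.path_lengths()
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((labels[i], labels[j])))
                    assert pl[key] == pytest.approx(m[i, j], abs=1e-9)

    def test_matches_skbio_topology(self):
        """On a generic (tie-free) distance matrix the NJ join sequence is
        unique, so our topology must equal scikit-bio's exactly.  (On clonal
        data with many zero distances the Q-matrix has ties and NJ topologies
        legitimately differ between implementations.)"""
        import skbio

        rng = np.random.default_rng(99)
        for trial in range(5):
            n = 15
            labels = [f"t{i}" for i in range(n)]
            pts = rng.normal(size=(n, 4))
            m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix(labels, m)
            ours = neighbor_joining(dm)
            sk = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
            sk_bips = set()
            all_leaves = frozenset(labels)
            anchor = labels[0]
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = all_leaves - side
                if 1 < len(side) < len(all_leaves) - 1:
                    sk_bips.add(side)
            assert ours.bipartitions() == sk_bips

    def test_negative_branch_clamped_and_counted(self):
        # a non-additive matrix engineered to produce a negative branch
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 0.2],
                [1.0, 1.0, 0.0, 1.0],
                [1.0, 0.2, 1.0, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels, m))
        assert tree.n_clamped >= 1
        for node in tree.nodes:
            for _, bl in node.children:
                assert bl >= 0

    def test_rejects_nan(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        dm.values[0, 1] = dm.values[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(dm)


class TestAUFit:
    def test_inverts_forward_model(self):
        """Generate BP values exactly from z = v*sqrt(rho) + c/sqrt(rho) and
        check the WLS fit returns (v, c) and au = 1 - Phi(v - c)."""
        v_true, c_true = 1.0, 0.3
        rhos = np.array(DEFAULT_SCALES)
        z = v_true * np.sqrt(rhos) + c_true / np.sqrt(rhos)
        bps = norm.cdf(-z)
        v, c, au, degenerate = _fit_au(rhos, bps, n_boot=1000)
        assert not degenerate
        assert v == pytest.approx(v_true, abs=1e-6)
        assert c == pytest.approx(c_true, abs=1e-6)
        assert au == pytest.approx(1 - norm.cdf(v_true - c_true), abs=1e-6)

    def test_degenerate_always_recovered(self):
        rhos = np.array(DEFAULT_SCALES)
        v, c, au, degenerate = _fit_au(rhos, np.ones_like(rhos), 1000)
        assert degenerate and au == 1.0
        v, c, au, degenerate = _fit_au(rhos, np.zeros_like(rhos), 1000)
        assert degenerate and au == 0.0


class TestMultiscaleBootstrap:
    def test_clear_clusters_get_high_support(self, generic_loci):
        """Two tight groups separated at every locus: their bipartition should
        be recovered in essentially every replicate."""
        loci = generic_loci(12)
        cells = {}
        for s in range(3):
            cells[f"g1_{s}"] = {l.name: (10,) for l in loci}
            cells[f"g2_{s}"] = {l.name: (18,) for l in loci}
        # slight within-group jitter so strains are distinct
        cells["g1_1"]["L00"] = (11,)
        cells["g2_1"]["L01"] = (19,)
        table = make_table(cells, loci=list(loci))
        tree, fits = multiscale_bootstrap(table, n_boot=200, seed=5)
        group2 = frozenset({"g2_0", "g2_1", "g2_2"})
        # the anchor leaf is in g1, so the cluster is encoded as the g2 side
        assert group2 in fits
        assert fits[group2].au_p > 0.95
        assert fits[group2].bp > 0.95

    def test_few_loci_warning_and_determinism(self, generic_loci):
        loci = generic_loci(4)
        cells = {
            f"s{i}": {l.name: (10 + i,) for l in loci} for i in range(5)
        }
        table = make_table(cells, loci=list(loci))
        with pytest.warns(UserWarning, match="resampling units"):
            tree1, fits1 = multiscale_bootstrap(table, n_boot=100, seed=9)
        with pytest.warns(UserWarning):
            tree2, fits2 = multiscale_bootstrap(table, n_boot=100, seed=9)
        assert write_newick(tree1) == write_newick(tree2)
        for cl in fits1:
            assert fits1[cl].bp_per_scale == fits2[cl].bp_per_scale

    def test_rejects_small_n_boot(self, generic_loci):
        loci = generic_loci(12)
        cells = {f"s{i}": {l.name: (10 + i,) for l in loci} for i in range(4)}
        table = make_table(cells, loci=list(loci))
        with pytest.raises(ValueError, match="n_boot"):
            multiscale_bootstrap(table, n_boot=50, seed=1)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        dm, truth = additive_matrix_4taxa()
        tree = neighbor_joining(dm)
        text = write_newick(tree)
        import dendropy

        t = dendropy.Tree.get(data=text, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for (a, b), v in truth.items():
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(v)

    def test_quoting(self):
        dm = DistanceMatrix(
            ["str one", "two"], np.array([[0.0, 0.4], [0.4, 0.0]])
        )
        text = write_newick(neighbor_joining(dm))
        assert "'str one'" in text

    def test_support_labels_embedded(self):
        dm, _ = additive_matrix_4taxa()
        tree = neighbor_joining(dm)
        text = write_newick(tree, support={frozenset({"C", "D"}): 0.97})
        assert ")0.970000" in text
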