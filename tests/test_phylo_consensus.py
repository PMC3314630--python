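"""Bipartition extraction, 0/1 encoding, p-distance and BioNJ."""

import numpy as np
import pytest

from gobiseq.phylo_consensus import (
    MISSING,
    Bipartition,
    DistanceMatrix,
    bionj,
    consensus_pipeline,
    encode_matrix,
    extract_bipartitions,
    p_distance,
    parse_newick_support,
    robinson_foulds,
    tree_bipartitions,
)


class TestParseNewick:
    def test_support_attached_to_internal_edge(self):
        tree = parse_newick_support("((A:1,B:1)85:1,(C:1,D:1):1);")
        splits = tree_bipartitions(tree)
        ab = Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))
        assert splits[ab] == 85.0

    def test_tree_without_supports(self):
        tree = parse_newick_support("((A,B),(C,D));")
        assert all(v is None for v in tree_bipartitions(tree).values())

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(Exception):
            parse_newick_support("((A,A),(C,D));")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(Exception):
            parse_newick_support("((A,B),(C,D);")

    def test_write_then_parse_round_trip(self, rng):
        from gobiseq.synthetic_data import _random_binary_tree

        for _ in range(10):
            n = int(rng.integers(4, 10))
            tree = _random_binary_tree([f"T{i}" for i in range(n)], rng)
            text = tree.as_string(schema="newick", suppress_rooting=True)
            again = parse_newick_support(text)
            assert set(tree_bipartitions(again)) == set(tree_bipartitions(tree))


class TestExtractBipartitions:
    def test_four_taxon_split_above_threshold(self):
        tree = parse_newick_support("((A:1,B:1)85:1,(C:1,D:1):1);")
        (bp,) = extract_bipartitions(tree)
        assert {frozenset(bp.side), frozenset(bp.other_side)} == {
            frozenset("AB"),
            frozenset("CD"),
        }

    def test_low_support_excluded(self):
        tree = parse_newick_support("((A:1,B:1)60:1,(C:1,D:1):1);")
        assert extract_bipartitions(tree) == set()

    def test_threshold_inclusive(self):
        tree = parse_newick_support("((A:1,B:1)70:1,(C:1,D:1):1);")
        assert len(extract_bipartitions(tree)) == 1

    def test_fully_supported_tree_yields_n_minus_3_splits(self, rng):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

        cfg = SimConfig(
            seed=17, n_taxa=10, n_gene_trees=1, split_noise=0.0,
            support_true_bounds=(100, 100),
        )
        newicks, species, _ = simulate_gene_trees(cfg)
        tree = parse_newick_support(newicks[0])
        assert len(extract_bipartitions(tree, 70)) == 10 - 3


class TestEncodeMatrix:
    universe = ["A", "B", "C", "D"]
    ab = Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))

    def test_polarity_convention(self):
        m = encode_matrix([[self.ab]], self.universe)
        # side containing the smallest taxon (A) coded 0
        assert m.data[:, 0].tolist() == [0, 0, 1, 1]

    def test_duplicate_splits_kept_as_columns(self):
        m = encode_matrix([[self.ab], [self.ab]], self.universe)
        assert m.data.shape == (4, 2)
        assert (m.data[:, 0] == m.data[:, 1]).all()

    def test_missing_taxa_coded_missing(self):
        bp = Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))
        m = encode_matrix([[bp]], ["A", "B", "C", "D", "E"])
        assert m.data[4, 0] == MISSING

    def test_dimensions(self, rng):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

        cfg = SimConfig(seed=3, n_taxa=8, n_gene_trees=5, split_noise=0.2,
                        support_perturbed_bounds=(70, 100))
        newicks, _, _ = simulate_gene_trees(cfg)
        trees = [parse_newick_support(t) for t in newicks]
        sets = [extract_bipartitions(t, 70) for t in trees]
        m = encode_matrix(sets, [f"T{i + 1:02d}" for i in range(8)])
        assert m.data.shape == (8, sum(len(s) for s in sets))


class TestPDistance:
    def test_identical_rows_distance_zero(self):
        m = encode_matrix(
            [[Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))]],
            ["A", "B", "C", "D"],
        )
        d = p_distance(m)
        assert d.values[0, 1] == 0.0  # A,B on the same side

    def test_single_differing_column(self):
        m = encode_matrix(
            [[Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))]],
            ["A", "B", "C", "D"],
        )
        d = p_distance(m)
        assert d.values[d.taxa.index("A"), d.taxa.index("C")] == 1.0

    def test_polarity_flip_invariance(self, rng):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees
        from gobiseq.phylo_consensus import BipartitionMatrix

        cfg = SimConfig(seed=9, n_taxa=8, n_gene_trees=6, split_noise=0.1)
        newicks, _, _ = simulate_gene_trees(cfg)
        sets = [extract_bipartitions(parse_newick_support(t), 70) for t in newicks]
        m = encode_matrix(sets, [f"T{i + 1:02d}" for i in range(8)])
        base = p_distance(m).values
        for _ in range(500):
            flip = rng.random(m.data.shape[1]) < 0.5
            data = m.data.copy()
            cols = data[:, flip]
            defined = cols != MISSING
            cols[defined] = 1 - cols[defined]
            data[:, flip] = cols
            flipped = BipartitionMatrix(taxa=m.taxa, data=data)
            assert np.array_equal(p_distance(flipped).values, base)

    def test_disjoint_taxa_pair_is_error(self):
        bp1 = Bipartition(side=frozenset("CD"), leaf_set=frozenset("ABCD"))
        bp2 = Bipartition(side=frozenset("GH"), leaf_set=frozenset("EFGH"))
        m = encode_matrix([[bp1], [bp2]], list("ABCDEFGH"))
        with pytest.raises(ValueError, match="share no"):
            p_distance(m)


class TestBioNJ:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            taxa=("A", "B", "C"),
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        tree = bionj(d)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.seed_node.child_nodes()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_matrix(self):
        # path distances of ((A:1,B:1):1,(C:1,D:1))
        d = DistanceMatrix(
            taxa=("A", "B", "C", "D"),
            values=np.array(
                [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
            ),
        )
        tree = bionj(d)
        gen = parse_newick_support("((A:1,B:1):1,(C:1,D:1):0);")
        assert robinson_foulds(tree, gen) == 0
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node.is_internal() and e.length is not None
        ]
        assert internal == pytest.approx([1.0])

    def test_agrees_with_classic_nj_on_additive_matrices(self, rng):
        # on additive (tree) metrics the variance weighting cannot change
        # the topology, so BioNJ and dendropy's classic NJ must coincide
        import io

        import dendropy

        from gobiseq.synthetic_data import _random_binary_tree

        for _ in range(10):
            n = int(rng.integers(5, 9))
            gen = _random_binary_tree([f"T{i}" for i in range(n)], rng)
            taxa = sorted(t.label for t in gen.taxon_namespace)
            tx = {t.label: t for t in gen.taxon_namespace}
            pdm_gen = gen.phylogenetic_distance_matrix()
            m = np.array(
                [
                    [0.0 if a == b else pdm_gen.patristic_distance(tx[a], tx[b]) for b in taxa]
                    for a in taxa
                ]
            )
            mine = bionj(DistanceMatrix(taxa=tuple(taxa), values=m))
            pdm_src = ",".join([""] + taxa) + "\n" + "\n".join(
                ",".join([taxa[i]] + [str(m[i, j]) for j in range(n)])
                for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(pdm_src), delimiter=","
            )
            theirs = pdm.nj_tree()
            assert robinson_foulds(mine, theirs) == 0

    def test_lambda_stays_half_on_symmetric_cherry(self):
        # perfectly symmetric additive matrix: the variance correction sums
        # to zero, so branch lengths must equal the classic NJ values
        d = DistanceMatrix(
            taxa=("A", "B", "C", "D"),
            values=np.array(
                [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
            ),
        )
        tree = bionj(d)
        pendant = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert pendant == pytest.approx({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})

    def test_generating_tree_recovered(self, rng):
        from gobiseq.synthetic_data import _random_binary_tree

        for _ in range(100):
            n = int(rng.integers(4, 13))
            gen = _random_binary_tree([f"T{i:02d}" for i in range(n)], rng)
            taxa = sorted(t.label for t in gen.taxon_namespace)
            tx = {t.label: t for t in gen.taxon_namespace}
            pdm = gen.phylogenetic_distance_matrix()
            m = np.array(
                [
                    [0.0 if a == b else pdm.patristic_distance(tx[a], tx[b]) for b in taxa]
                    for a in taxa
                ]
            )
            rec = bionj(DistanceMatrix(taxa=tuple(taxa), values=m))
            assert robinson_foulds(rec, gen) == 0

    def test_binary_output_has_n_minus_3_internal_edges(self, rng):
        n = 9
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.uniform(0.5, 2.0, size=len(iu[0]))
        m += m.T
        tree = bionj(DistanceMatrix(taxa=tuple(f"T{i}" for i in range(n)), values=m))
        internal = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node.is_internal() and e.tail_node is not None
        ]
        assert len(internal) == n - 3

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            bionj(DistanceMatrix(taxa=("A", "B"), values=np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=("A", "B", "C"), values=bad)


class TestConsensusPipeline:
    def test_unanimous_trees_return_common_topology(self):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

        cfg = SimConfig(
            seed=21, n_taxa=9, n_gene_trees=12, split_noise=0.0,
            support_true_bounds=(100, 100),
        )
        newicks, species, _ = simulate_gene_trees(cfg)
        cons = consensus_pipeline(newicks)
        assert robinson_foulds(cons, species) == 0

    def test_single_tree_compatible_with_its_splits(self):
        text = "((A:1,B:1)90:1,((C:1,D:1)95:1,(E:1,F:1)40:1)80:1);"
        cons = consensus_pipeline([text])
        tree = parse_newick_support(text)
        wanted = extract_bipartitions(tree, 70)
        got = set(tree_bipartitions(cons))
        for bp in wanted:
            assert bp in got

    def test_order_of_gene_trees_irrelevant(self):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

        cfg = SimConfig(seed=31, n_taxa=7, n_gene_trees=8, split_noise=0.15)
        newicks, _, _ = simulate_gene_trees(cfg)
        t1 = consensus_pipeline(newicks)
        t2 = consensus_pipeline(list(reversed(newicks)))
        assert robinson_foulds(t1, t2) == 0

    def test_noisy_trees_consensus_no_worse_than_median_input(self):
        from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

        cfg = SimConfig(seed=41, n_taxa=10, n_gene_trees=20, split_noise=0.1)
        newicks, species, _ = simulate_gene_trees(cfg)
        cons = consensus_pipeline(newicks)
        rf_cons = robinson_foulds(cons, species)
        rf_inputs = sorted(
            robinson_foulds(parse_newick_support(t), species) for t in newicks
        )
        median = rf_inputs[len(rf_inputs) // 2]
        assert rf_cons <= median

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_pipeline([])
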