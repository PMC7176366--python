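import itertools

import dendropy
import numpy as np
import pytest

from abyssminer.homology import AnchorHit, AlignmentResult, default_scheme
from abyssminer.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloError,
    align_pair_global,
    align_progressive,
    detect_paralogs,
    flag_hgt_candidates,
    neighbor_joining,
    pdistance,
    read_newick,
    robinson_foulds,
    write_newick,
)
from abyssminer.seq_io import SequenceRecord
from abyssminer.synthetic_data import (
    GeneratorConfig,
    gene_tree_from_sequences,
    generate_hgt_scenario,
    random_protein,
)

from .oracles import global_affine_score

SCHEME = default_scheme()


def rec(name, seq):
    return SequenceRecord(name, "", seq)


def _score_of():
    idx = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    S = SCHEME.matrix
    return lambda a, b: int(S[idx[a], idx[b]])


class TestProgressiveAlignment:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_progressive([rec("a", "MKVLW"), rec("b", "MKVLW")])
        assert aln.rows == ["MKVLW", "MKVLW"]

    def test_pairwise_matches_global_bruteforce(self):
        """Pairwise global scores equal the recursive enumeration oracle."""
        rng = np.random.default_rng(5)
        score_of = _score_of()
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(2, 8)))
            b = random_protein(rng, int(rng.integers(2, 8)))
            got, _, _ = align_pair_global(rec("a", a), rec("b", b))
            assert got == global_affine_score(a, b, score_of, SCHEME.gap_open, SCHEME.gap_extend)

    def test_short_pair_gap_placement(self):
        score, ra, rb = align_pair_global(rec("a", "MKV"), rec("b", "MV"))
        assert ra.replace("-", "") == "MKV"
        assert rb.replace("-", "") == "MV"
        assert len(rb) == 3 and rb.count("-") == 1

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seqs = [
                rec(f"s{i}", random_protein(rng, int(rng.integers(10, 40))))
                for i in range(int(rng.integers(2, 6)))
            ]
            aln = align_progressive(seqs)
            assert len({len(r) for r in aln.rows}) == 1
            for i, s in enumerate(seqs):
                assert aln.ids[i] == s.id
                assert aln.ungapped(i) == s.residues

    def test_single_sequence_trivial_alignment(self):
        aln = align_progressive([rec("a", "MKV")])
        assert aln.rows == ["MKV"]


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAA"])
        assert pdistance(aln).matrix[0, 1] == 0.0

    def test_quarter_mismatch(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAT"])
        assert pdistance(aln).matrix[0, 1] == pytest.approx(0.25)

    def test_gapped_columns_excluded(self):
        aln = Alignment(["a", "b"], ["A-AA", "AGAT"])
        assert pdistance(aln).matrix[0, 1] == pytest.approx(1 / 3)

    def test_zero_overlap_pair_errors_naming_pair(self):
        aln = Alignment(["a", "b"], ["AA--", "--TT"])
        with pytest.raises(PhyloError, match="'a'.*'b'"):
            pdistance(aln)

    def test_poisson_correction_monotone(self):
        aln = Alignment(["a", "b"], ["AAAA", "AATT"])
        p = pdistance(aln).matrix[0, 1]
        c = pdistance(aln, poisson_correction=True).matrix[0, 1]
        assert c > p


def _tree_pdm(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


def _five_taxon_cases(seed=123):
    """All 15 unrooted 5-leaf topologies (two cherries + middle leaf)
    with random branch lengths, plus their additive distances."""
    taxa = list("ABCDE")
    rng = np.random.default_rng(seed)
    cases = []
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            if pair1 > pair2:
                continue  # unordered cherry pair
            middle = next(t for t in rest if t not in pair2)
            L = {t: rng.uniform(0.5, 2.0) for t in taxa}
            i1, i2 = rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5)
            newick = (
                f"(({pair1[0]}:{L[pair1[0]]},{pair1[1]}:{L[pair1[1]]}):{i1},"
                f"{middle}:{L[middle]},"
                f"({pair2[0]}:{L[pair2[0]]},{pair2[1]}:{L[pair2[1]]}):{i2});"
            )
            tree = dendropy.Tree.get(data=newick, schema="newick")
            cases.append((newick, tree))
    return cases


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances computed by path summation on ((A:1,B:2):1,(C:3,D:1))
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids, D))
        dist = _tree_pdm(tree)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert dist(a, b) == pytest.approx(D[i, j], abs=1e-9)

    def test_all_fifteen_five_taxon_topologies_recovered(self):
        """NJ is consistent on additive data: topology and path lengths."""
        for newick, true_tree in _five_taxon_cases():
            pdm = _tree_pdm(true_tree)
            ids = list("ABCDE")
            D = np.zeros((5, 5))
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i < j:
                        D[i, j] = D[j, i] = pdm(a, b)
            out = neighbor_joining(DistanceMatrix(ids, D))
            assert robinson_foulds(out, true_tree) == 0
            out_pdm = _tree_pdm(out)
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i < j:
                        assert out_pdm(a, b) == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        dist = _tree_pdm(tree)
        assert dist("A", "B") == pytest.approx(2.0)
        assert dist("A", "C") == pytest.approx(3.0)
        assert dist("B", "C") == pytest.approx(5.0)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 1.6], [1.6, 0.0]])))
        assert _tree_pdm(tree)("A", "B") == pytest.approx(1.6)

    def test_topology_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        rng = np.random.default_rng(31)
        for _ in range(8):
            n = 6
            ids = [f"t{i}" for i in range(n)]
            M = rng.uniform(0.1, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = neighbor_joining(DistanceMatrix(ids, D))
            theirs = dendropy.Tree.get(
                data=skbio.tree.nj(skbio.DistanceMatrix(D, ids)).write(StringIO()).getvalue(),
                schema="newick",
            )
            assert robinson_foulds(mine, theirs) == 0

    def test_negative_branches_clamped(self):
        # a non-additive matrix known to produce a negative NJ branch
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.65, 0.6], [0.6, 0.65, 0, 0.1], [0.6, 0.6, 0.1, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(ids, D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        assert robinson_foulds(t, t2) == 0

    def test_distinct_quartets_distance_two(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert robinson_foulds(t1, t2) == 2

    def test_symmetry_on_random_trees(self):
        rng = np.random.default_rng(12)
        ids = [f"x{i}" for i in range(8)]
        trees = []
        for _ in range(4):
            M = rng.uniform(0.1, 1.0, size=(8, 8))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            trees.append(neighbor_joining(DistanceMatrix(ids, D)))
        for t1, t2 in itertools.combinations(trees, 2):
            assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)

    def test_leaf_set_mismatch_lists_difference(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(PhyloError, match="D.*E"):
            robinson_foulds(t1, t2)


class TestHgtScreen:
    def test_congruent_scenario_flags_nothing(self):
        tree, seqs, genus_of, _ = generate_hgt_scenario(GeneratorConfig(seed=2), transfer=False)
        gt = gene_tree_from_sequences(seqs)
        screen = flag_hgt_candidates(gt, tree, genus_of)
        assert screen.flags == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_transferred_taxon_flagged(self, seed):
        tree, seqs, genus_of, truth = generate_hgt_scenario(GeneratorConfig(seed=seed))
        gt = gene_tree_from_sequences(seqs)
        screen = flag_hgt_candidates(gt, tree, genus_of)
        assert truth.transferred_taxon in [f.leaf for f in screen.flags]
        flag = next(f for f in screen.flags if f.leaf == truth.transferred_taxon)
        assert flag.gene_sisters and flag.species_sisters  # evidence recorded

    def test_unknown_genus_skipped_with_warning_record(self):
        tree, seqs, genus_of, _ = generate_hgt_scenario(GeneratorConfig(seed=2), transfer=False)
        gt = gene_tree_from_sequences(seqs)
        partial = {k: v for k, v in genus_of.items() if k != "Frankia_sp1"}
        screen = flag_hgt_candidates(gt, tree, partial)
        assert screen.skipped == ["Frankia_sp1"]

    def test_gene_tree_leaves_must_be_subset(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,Z));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(PhyloError, match="Z"):
            flag_hgt_candidates(t1, t2, {})

    def test_baseline_congruence_rate(self):
        """Without transfer the gene tree matches the species tree
        (RF 0 or 2) in at least 9/10 seeds."""
        good = 0
        for seed in range(10):
            tree, seqs, _, _ = generate_hgt_scenario(GeneratorConfig(seed=seed), transfer=False)
            gt = gene_tree_from_sequences(seqs)
            good += robinson_foulds(gt, tree) <= 2
        assert good >= 9


def _hit(genome, pid):
    res = AlignmentResult(100, 50.0, 1e-20, 0.9, 0.9, (0, 10), (0, 10))
    return AnchorHit(genome_id=genome, protein_id=pid, anchor_query="AbyU", result=res)


class TestParalogs:
    def test_two_hits_in_one_genome_reported(self):
        hits = [_hit("g1", "p1"), _hit("g1", "p2"), _hit("g2", "p3")]
        assert detect_paralogs(hits) == {"g1": ["p1", "p2"]}

    def test_all_single_hit_genomes_empty(self):
        hits = [_hit("g1", "p1"), _hit("g2", "p2")]
        assert detect_paralogs(hits) == {}

    def test_pigeonhole_on_inventory_totals(self):
        """74 homologs over 66 genomes force at least one paralog pair."""
        rng = np.random.default_rng(0)
        genomes = [f"g{i}" for i in range(66)]
        assignments = list(genomes)
        assignments += [genomes[int(rng.integers(0, 66))] for _ in range(74 - 66)]
        hits = [_hit(g, f"p{i}") for i, g in enumerate(assignments)]
        paralogs = detect_paralogs(hits)
        assert len(paralogs) >= 1
        assert sum(len(v) for v in paralogs.values()) >= 74 - 66 + 1


def test_newick_round_trip(tmp_path):
    tree, _, _, _ = generate_hgt_scenario(GeneratorConfig(seed=1), transfer=False)
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    back = read_newick(p)
    assert robinson_foulds(tree, back) == 0
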