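import numpy as np
import pytest

from abyssminer.catalog import (
    CatalogError,
    ReferenceCatalog,
    delimit_cluster,
    label_gene,
    label_genes,
    load_catalog,
    merge_overlapping,
    write_catalog,
)
from abyssminer.homology import align_local, default_scheme, find_anchor_hits
from abyssminer.seq_io import SequenceRecord
from abyssminer.synthetic_data import (
    GeneratorConfig,
    generate_genome,
    mutate_protein,
    plant_cluster,
    random_protein,
)

SCHEME = default_scheme()


class TestLoadCatalog:
    def test_shipped_fixture_loads_with_expected_inventory(self, fixture_catalog):
        aby = fixture_catalog.source_labels("aby")
        assert len(aby) >= 24  # the full published aby gene enumeration
        assert {"abyU", "abyB1", "abyA1", "abyA5", "abyT"}.issubset(set(aby))
        assert fixture_catalog.min_identity == 0.30
        assert fixture_catalog.min_coverage == 0.50
        assert set(fixture_catalog.mobile_labels()) == {"transposase", "integrase"}
        assert [a.id for a in fixture_catalog.anchors()] == ["AbyU", "AbsU", "AbmU"]

    def test_duplicate_label_errors(self, tmp_path, small_catalog):
        entries = tmp_path / "e.tsv"
        fasta = tmp_path / "p.faa"
        write_catalog(small_catalog, entries, fasta)
        text = entries.read_text().splitlines()
        text.append(text[1])  # repeat the first entry row
        entries.write_text("\n".join(text) + "\n")
        with pytest.raises(CatalogError, match="duplicate"):
            load_catalog(entries, fasta)

    def test_missing_reference_protein_errors(self, tmp_path, small_catalog):
        entries = tmp_path / "e.tsv"
        fasta = tmp_path / "p.faa"
        write_catalog(small_catalog, entries, fasta)
        lines = [
            l
            for l in fasta.read_text().split(">")
            if l and not l.startswith("abyU")
        ]
        fasta.write_text(">" + ">".join(lines))
        with pytest.raises(CatalogError, match="abyU"):
            load_catalog(entries, fasta)

    def test_empty_catalog_errors_on_missing_role_classes(self):
        with pytest.raises(CatalogError, match="role class"):
            ReferenceCatalog(entries={})


class TestLabeling:
    def test_exact_copy_gets_its_label(self, small_catalog):
        ref = small_catalog.entries["abyA1"].reference_protein
        label, ident, cov = label_gene(
            SequenceRecord("p", "", ref.residues), small_catalog, SCHEME
        )
        assert (label, ident, cov) == ("abyA1", 1.0, 1.0)

    def test_random_protein_is_unknown(self, small_catalog):
        rng = np.random.default_rng(555)
        label, _, _ = label_gene(
            SequenceRecord("p", "", random_protein(rng, 120)), small_catalog, SCHEME
        )
        assert label == "unknown"

    def test_missing_protein_is_unknown(self, small_catalog):
        assert label_gene(None, small_catalog, SCHEME)[0] == "unknown"

    def test_diverged_homolog_accepted_while_threshold_consistent(self, small_catalog):
        """A ~45%-identity mutant labels; a mutant measured below the
        identity floor does not — behavior tracks the measured alignment."""
        rng = np.random.default_rng(21)
        ref = small_catalog.entries["abyT"].reference_protein
        accept = SequenceRecord("m1", "", mutate_protein(ref.residues, 0.50, rng))
        res = align_local(ref, accept, SCHEME)
        label, ident, cov = label_gene(accept, small_catalog, SCHEME)
        if res.identity_fraction >= 0.30 and res.query_coverage >= 0.50:
            assert label == "abyT"
        reject = SequenceRecord("m2", "", mutate_protein(ref.residues, 0.92, rng))
        label2, ident2, cov2 = label_gene(reject, small_catalog, SCHEME)
        assert label2 == "unknown"
        assert ident2 < 0.30 or cov2 < 0.50

    def test_labeling_is_idempotent(self, small_catalog, small_config):
        planted, truth = plant_cluster("1a", small_catalog, small_config)
        genome, _ = generate_genome(small_config, planted, genome_id="g")
        first = label_genes(genome, "c1", (0, 10), small_catalog)
        second = label_genes(genome, "c1", (0, 10), small_catalog)
        assert [(l.label, l.identity) for l in first] == [(l.label, l.identity) for l in second]

    def test_window_bounds_checked(self, small_catalog, small_config):
        genome, _ = generate_genome(small_config, None, genome_id="g")
        with pytest.raises(ValueError, match="window"):
            label_genes(genome, "c1", (0, 10_000), small_catalog)


def _mine_one(cluster_type, seed, catalog, lengths=(90, 130), background=16, **kw):
    cfg = GeneratorConfig(
        seed=seed, catalog_protein_lengths=lengths, background_gene_count=background, **kw
    )
    planted, truth = plant_cluster(cluster_type, catalog, cfg)
    genome, truth = generate_genome(cfg, planted, genome_id=f"g{seed}", truth=truth)
    hits = find_anchor_hits(
        list(genome.proteins.values()), catalog.anchors(), genome_id=genome.genome_id
    )
    return genome, truth, hits


class TestDelimit:
    @pytest.mark.parametrize("cluster_type", ["1a", "1b", "2a", "2b", "3", "4", "5"])
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_noise_free_planted_cluster_recovered_exactly(
        self, cluster_type, seed, small_catalog
    ):
        """Boundary equality against the generator's ground truth."""
        genome, truth, hits = _mine_one(cluster_type, seed, small_catalog)
        assert len(hits) == 1
        cand = delimit_cluster(genome, hits[0], small_catalog)
        assert cand.span == truth.planted_span
        assert sorted(lg.gene.gene_id for lg in cand.genes) == sorted(truth.planted_gene_ids)

    def test_anchor_near_contig_start_sets_edge_flag(self, small_catalog):
        # seed scan: find a genome whose planted cluster starts within 1 kb
        for seed in range(30):
            genome, truth, hits = _mine_one("1a", seed, small_catalog)
            if truth.planted_span[0] <= 1000:
                cand = delimit_cluster(genome, hits[0], small_catalog)
                assert cand.edge_flags[0]
                return
        pytest.skip("no edge-adjacent layout in the scanned seeds")

    def test_isolated_anchor_trims_to_single_gene(self, small_catalog, small_config):
        anchor_ref = small_catalog.entries["abyU"].reference_protein
        planted, truth = plant_cluster("1a", small_catalog, small_config)
        only_anchor = [pg for pg in planted if pg.label == "abyU"]
        genome, truth = generate_genome(small_config, only_anchor, genome_id="g")
        hits = find_anchor_hits(list(genome.proteins.values()), small_catalog.anchors(), genome_id="g")
        cand = delimit_cluster(genome, hits[0], small_catalog)
        assert len(cand.genes) == 1
        assert cand.genes[0].label == "abyU"

    def test_orientation_normalizes_minus_strand_clusters(self, small_catalog):
        # scan seeds for a minus-strand planting; labels must read in
        # catalog orientation either way
        from abyssminer.synthetic_data import CLUSTER_TEMPLATES

        found = 0
        for seed in range(11, 25):
            genome, truth, hits = _mine_one("1a", seed, small_catalog)
            cand = delimit_cluster(genome, hits[0], small_catalog)
            assert cand.labels == list(CLUSTER_TEMPLATES["1a"])
            strand = next(
                g.strand for g in genome.genes if g.gene_id == truth.anchor_gene_id
            )
            expected = "catalog_reverse" if strand == "-" else "catalog_forward"
            assert cand.orientation == expected
            found += strand == "-"
            if found >= 2:
                return
        pytest.skip("no minus-strand layout in the scanned seeds")

    def test_gap_tolerance_monotonicity(self, small_catalog):
        """Larger max_gap_genes never shrinks the candidate span."""
        genome, truth, hits = _mine_one("3", 17, small_catalog)
        spans = []
        for gap in (1, 2, 4, 6):
            cand = delimit_cluster(genome, hits[0], small_catalog, max_gap_genes=gap)
            spans.append(cand.span)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            assert lo2 <= lo1 and hi2 >= hi1

    def test_absent_anchor_gene_errors(self, small_catalog, small_config):
        genome, _ = generate_genome(small_config, None, genome_id="g")
        fake = find_anchor_hits(
            [SequenceRecord("ghost", "", small_catalog.entries["abyU"].reference_protein.residues)],
            small_catalog.anchors(),
        )[0]
        with pytest.raises(CatalogError, match="ghost"):
            delimit_cluster(genome, fake, small_catalog)

    def test_overlapping_paralog_candidates_merge(self, small_catalog):
        cfg = GeneratorConfig(seed=31, catalog_protein_lengths=(90, 130), background_gene_count=10)
        planted, truth = plant_cluster("1a", small_catalog, cfg)
        # duplicate the anchor gene inside the arrangement: a paralog pair
        anchor = next(pg for pg in planted if pg.label == "abyU")
        from abyssminer.synthetic_data import PlantedGene

        paralog = PlantedGene("abyU", SequenceRecord("planted_dup_abyU", "", anchor.protein.residues))
        arrangement = planted[:5] + [paralog] + planted[5:]
        genome, truth = generate_genome(cfg, arrangement, genome_id="g", truth=truth)
        hits = find_anchor_hits(list(genome.proteins.values()), small_catalog.anchors(), genome_id="g")
        assert len(hits) == 2
        cands = [delimit_cluster(genome, h, small_catalog) for h in hits]
        merged = merge_overlapping(cands)
        assert len(merged) == 1
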