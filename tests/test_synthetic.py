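import itertools

import numpy as np
import pytest

from abyssminer.bgc_classify import classify_completeness, classify_syntype
from abyssminer.catalog import UNKNOWN
from abyssminer.homology import find_anchor_hits
from abyssminer.synthetic_data import (
    BOOKKEEPING_COUNTS,
    CLUSTER_TEMPLATES,
    GeneratorConfig,
    _global_identity,
    generate_bookkeeping_cohort,
    generate_catalog_proteins,
    generate_cohort,
    generate_genome,
    generate_hgt_scenario,
    mutate_protein,
    plant_cluster,
)

ALL_TYPES = ["1a", "1b", "2a", "2b", "3", "4", "5"]


class TestDeterminism:
    def test_catalog_identical_across_calls(self, small_config):
        a = generate_catalog_proteins(small_config)
        b = generate_catalog_proteins(small_config)
        assert {k: e.reference_protein.residues for k, e in a.entries.items()} == {
            k: e.reference_protein.residues for k, e in b.entries.items()
        }

    def test_genome_identical_across_calls(self, small_config, small_catalog):
        outs = []
        for _ in range(2):
            planted, _ = plant_cluster("2a", small_catalog, small_config)
            genome, truth = generate_genome(small_config, planted, genome_id="g")
            outs.append(
                (
                    [(g.gene_id, g.start, g.end, g.strand) for g in genome.genes],
                    sorted(genome.proteins),
                    truth.planted_span,
                )
            )
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self, small_catalog):
        g1, _ = generate_genome(GeneratorConfig(seed=1, background_gene_count=5))
        g2, _ = generate_genome(GeneratorConfig(seed=2, background_gene_count=5))
        assert [g.start for g in g1.genes] != [g.start for g in g2.genes]

    def test_cohort_identical_across_calls(self):
        a, _ = generate_cohort(GeneratorConfig(seed=6), 20, 20)
        b, _ = generate_cohort(GeneratorConfig(seed=6), 20, 20)
        assert [(r.sample_id, r.depth_bp, r.ontology_path) for r in a] == [
            (r.sample_id, r.depth_bp, r.ontology_path) for r in b
        ]


class TestCatalogGeneration:
    def test_lengths_within_configured_range(self, small_catalog, small_config):
        lo, hi = small_config.catalog_protein_lengths
        for e in small_catalog.entries.values():
            assert lo <= len(e.reference_protein) <= hi

    def test_distinct_entries_pairwise_dissimilar(self, small_catalog):
        """Spot-check the < 25% pairwise-identity guarantee."""
        labels = sorted(small_catalog.entries)[:10]
        for a, b in itertools.combinations(labels, 2):
            ident = _global_identity(
                small_catalog.entries[a].reference_protein.residues,
                small_catalog.entries[b].reference_protein.residues,
            )
            assert ident < 0.25, (a, b, ident)

    def test_required_role_classes_present(self, small_catalog):
        roles = {e.role_class for e in small_catalog.entries.values()}
        assert {"PKS", "tetronate", "diels_alderase"}.issubset(roles)


class TestMutation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_protein("MKVLW", 0.0, rng) == "MKVLW"

    def test_substitution_rate_calibration(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=5000))
        mut = mutate_protein(seq, 0.2, rng)
        frac = sum(a != b for a, b in zip(seq, mut)) / len(seq)
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_indel_mode_changes_length(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000))
        mut = mutate_protein(seq, 0.0, rng, indel_rate=0.05)
        assert len(mut) != len(seq)


class TestPlantedArrangements:
    def test_type_1b_carries_extra_abyV_downstream_of_pks(self):
        labels = list(CLUSTER_TEMPLATES["1b"])
        assert labels.count("abyV") == 2
        pks_end = max(labels.index(b) for b in ("abyB1", "abyB2", "abyB3"))
        assert "abyV" in labels[pks_end + 1 :]

    def test_type_2a_moves_abyA2_downstream(self):
        labels = list(CLUSTER_TEMPLATES["2a"])
        pks_start = min(labels.index(b) for b in ("abyB1", "abyB2", "abyB3"))
        assert "abyA2" not in labels[:pks_start]
        assert "abyA2" in labels[pks_start:]

    @pytest.mark.parametrize("cluster_type", ALL_TYPES)
    def test_round_trip_classification(self, cluster_type, small_catalog, small_config):
        planted, truth = plant_cluster(cluster_type, small_catalog, small_config)
        labels = [pg.label for pg in planted]
        assert classify_syntype(labels).cluster_type == cluster_type
        assert truth.cluster_type == cluster_type

    def test_proteins_mutated_at_configured_rate(self, small_catalog):
        cfg = GeneratorConfig(seed=3, mutation_rate=0.10, catalog_protein_lengths=(90, 130))
        planted, _ = plant_cluster("1a", small_catalog, cfg)
        diffs = []
        for pg in planted:
            ref = small_catalog.entries[pg.label].reference_protein.residues
            diffs.append(sum(a != b for a, b in zip(ref, pg.protein.residues)) / len(ref))
        assert np.mean(diffs) == pytest.approx(0.10, abs=0.03)


class TestGenerateGenome:
    def test_structural_invariants(self, small_config, small_catalog):
        planted, _ = plant_cluster("3", small_catalog, small_config)
        genome, truth = generate_genome(small_config, planted, genome_id="g")
        genome.validate()  # coordinates within contigs, unique ids
        genes = genome.genes_on("c1")
        for g1, g2 in zip(genes, genes[1:]):  # non-overlapping, gaps 50-500
            gap = g2.start - g1.end
            assert 50 <= gap <= 500

    def test_negative_control_has_no_anchor_hits(self, small_config, small_catalog):
        genome, _ = generate_genome(small_config, None, genome_id="neg")
        hits = find_anchor_hits(
            list(genome.proteins.values()), small_catalog.anchors(), genome_id="neg"
        )
        assert hits == []

    def test_planted_cluster_yields_exactly_one_hit_at_recorded_gene(
        self, small_config, small_catalog
    ):
        planted, truth = plant_cluster("1a", small_catalog, small_config)
        genome, truth = generate_genome(small_config, planted, genome_id="g", truth=truth)
        hits = find_anchor_hits(
            list(genome.proteins.values()), small_catalog.anchors(), genome_id="g"
        )
        assert len(hits) == 1
        anchor_gene = next(g for g in genome.genes if g.gene_id == truth.anchor_gene_id)
        assert anchor_gene.protein_id == hits[0].protein_id

    def test_truncation_splits_one_gene_across_contigs(self, small_catalog):
        cfg = GeneratorConfig(
            seed=13, catalog_protein_lengths=(90, 130), background_gene_count=16, truncation=10
        )
        planted, _ = plant_cluster("1a", small_catalog, cfg)
        genome, truth = generate_genome(cfg, planted, genome_id="g")
        assert set(genome.contigs) == {"c1", "c2"}
        halves = [g for g in genome.genes if g.partial_flags.any()]
        assert len(halves) == 2
        assert {g.contig_id for g in halves} == {"c1", "c2"}
        genome.validate()


class TestBookkeepingCohort:
    def test_counts_and_classification_match_construction(self, fixture_catalog):
        cohort = generate_bookkeeping_cohort(GeneratorConfig(seed=1))
        assert len(cohort) == sum(BOOKKEEPING_COUNTS.values()) == 66
        cats = [classify_completeness(c, fixture_catalog).category for _, c in cohort]
        from collections import Counter

        hist = Counter(cats)
        assert hist["abyssomicin_total"] == 5
        assert hist["abyssomicin_partial"] == 12
        assert (
            hist["potential_abyssomicin_total"] + hist["potential_abyssomicin_partial"] == 23
        )


class TestHgtGenerator:
    def test_species_tree_genera_monophyletic(self):
        tree, _, genus_of, _ = generate_hgt_scenario(GeneratorConfig(seed=4), transfer=False)
        for genus in set(genus_of.values()):
            members = {l for l, g in genus_of.items() if g == genus}
            mrca = tree.mrca(taxon_labels=members)
            clade = {l.taxon.label for l in mrca.leaf_iter()}
            assert clade == members

    def test_transfer_recorded_in_ground_truth(self):
        _, seqs, genus_of, truth = generate_hgt_scenario(GeneratorConfig(seed=4))
        assert truth.transferred_taxon is not None
        assert genus_of[truth.transferred_taxon] != genus_of[truth.donor_taxon]

    def test_same_genus_transfer_rejected(self):
        with pytest.raises(ValueError, match="different genera"):
            generate_hgt_scenario(
                GeneratorConfig(seed=1),
                donor="Streptomyces_sp1",
                recipient="Streptomyces_sp2",
            )


class TestCohortGenerator:
    def test_habitat_ontology_paths_valid(self):
        records, truth = generate_cohort(GeneratorConfig(seed=9), 50, 50)
        assert len(records) == 100
        for r in records:
            assert r.ontology_path[0] in ("aquatic", "terrestrial", "engineered", "host_associated")
            assert 0.0 <= r.abundance["Actinobacteria"] <= 1.0
            assert r.depth_bp > 0
        assert len(truth.habitat_by_sample) == 100

    def test_positives_never_aquatic_under_default_weights(self):
        records, _ = generate_cohort(GeneratorConfig(seed=10), 200, 0)
        assert all(r.ontology_path[0] != "aquatic" for r in records)
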