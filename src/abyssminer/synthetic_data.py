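"""Seeded generators for every input the mining pipeline consumes.

The generators emulate the study's data universe — proteomes with
planted anchor homologs, gene neighborhoods arranged per the seven
synteny cluster types, metagenome cohorts with habitat labels and
taxon-abundance/depth distributions, and species-tree + transferred-gene
scenarios — and return machine-checkable ground truth alongside, so
every downstream classifier decision can be scored exactly.

Everything is a pure function of its :class:`GeneratorConfig` (seed
included).  Protein mutation is substitution-only by default, which
keeps identity calibration analytic; a low-rate indel mode exists for
stress tests.  Background amino-acid frequencies are uniform over the
20 residues (simplest null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from . import bgc_classify
from .catalog import (
    ANCHOR_LABELS,
    CATALOG_INVENTORY,
    CatalogEntry,
    ClusterCandidate,
    LabeledGene,
    ReferenceCatalog,
    find_pks_block,
)
from .homology import RESIDUE_ORDER
from .seq_io import Gene, Genome, PartialFlags, SequenceRecord
from .stats_habitat import HabitatRecord

AA = RESIDUE_ORDER  # 20 residues, uniform background

#: habitat mix of anchor-positive metagenomes (soil / plant-associated /
#: arthropod-associated split reported for the AbyU screen)
POSITIVE_HABITAT_WEIGHTS: dict[str, float] = {
    "terrestrial/soil": 0.31,
    "host_associated/plants": 0.68,
    "host_associated/arthropoda": 0.01,
}

#: habitat mix of the full 3027-metagenome pool (27% aquatic, 31% soil,
#: 22% plant-associated, remainder engineered/host-associated)
POOL_HABITAT_WEIGHTS: dict[str, float] = {
    "aquatic/marine": 0.27,
    "terrestrial/soil": 0.31,
    "host_associated/plants": 0.22,
    "engineered/bioreactor": 0.10,
    "host_associated/mammals": 0.10,
}

DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "Bacteria": 0.10,
    "Actinobacteria": 0.20,
    "log10_depth_bp": 0.40,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic universe; defaults are the study conditions."""

    seed: int = 0
    catalog_protein_lengths: tuple[int, int] = (150, 450)
    mutation_rate: float = 0.0
    indel_rate: float = 0.0
    background_gene_count: int = 60
    habitat_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(POSITIVE_HABITAT_WEIGHTS)
    )
    effect_sizes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    cluster_type: str = "1a"
    truncation: int | None = None  # index within the planted arrangement
    hgt_gene_length: int = 300

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        total = sum(self.habitat_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"habitat weights sum to {total}, not 1")

    def rng(self, stream: str = "default") -> np.random.Generator:
        """Seeded generator; distinct ``stream`` names give decoupled
        streams so e.g. catalog references and background genes drawn
        from the same config can never collide."""
        return np.random.default_rng([self.seed, _STREAM_IDS.get(stream, 0)])


_STREAM_IDS = {
    "default": 0,
    "catalog": 1,
    "plant": 2,
    "genome": 3,
    "cohort": 4,
    "hgt": 5,
}


@dataclass
class GroundTruth:
    """Everything needed to score downstream decisions exactly."""

    planted_labels: list[str] = field(default_factory=list)
    planted_gene_ids: list[str] = field(default_factory=list)
    planted_span: tuple[int, int] | None = None
    contig_id: str | None = None
    cluster_type: str | None = None
    completeness_suffix: str = "total"  # total | partial
    anchor_gene_id: str | None = None
    transferred_taxon: str | None = None
    donor_taxon: str | None = None
    habitat_by_sample: dict[str, str] = field(default_factory=dict)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate_protein(
    residues: str,
    rate: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """Per-residue substitution (and optional indel) mutagenesis."""
    out: list[str] = []
    for c in residues:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(rng.choice(list(AA)))  # insertion before the residue
        if rate and rng.random() < rate:
            choices = [a for a in AA if a != c]
            out.append(str(rng.choice(choices)))
        else:
            out.append(c)
    return "".join(out) or residues[:1]


def _global_identity(a: str, b: str) -> float:
    from .phylo import align_pair_global

    _, ra, rb = align_pair_global(SequenceRecord("a", "", a), SequenceRecord("b", "", b))
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return matches / max(len(a), len(b))


def generate_catalog_proteins(
    config: GeneratorConfig, check_identity: bool = True, max_resample: int = 20
) -> ReferenceCatalog:
    """One i.i.d.-random reference protein per catalog label.

    Deterministic per seed; with ``check_identity`` any pair of distinct
    entries above 25% global identity triggers a resample of the newer
    entry (bounded retries).
    """
    rng = config.rng("catalog")
    lo, hi = config.catalog_protein_lengths
    entries: dict[str, CatalogEntry] = {}
    sequences: dict[str, str] = {}
    for label, (role, source, mobile) in CATALOG_INVENTORY.items():
        for _ in range(max_resample):
            length = int(rng.integers(lo, hi + 1))
            seq = random_protein(rng, length)
            if not check_identity or all(
                _global_identity(seq, other) < 0.25 for other in sequences.values()
            ):
                break
        sequences[label] = seq
        entries[label] = CatalogEntry(
            label=label,
            role_class=role,
            source_cluster=source,
            reference_protein=SequenceRecord(label, f"synthetic reference for {label}", seq),
            mobile_element=mobile,
        )
    return ReferenceCatalog(entries=entries)


# ---------------------------------------------------------------------------
# cluster templates (one canonical label order per synteny type)

_REF_DOWN_1 = ("abyC", "abyD", "abyE", "abyF1", "abyF2", "abyF3", "abyF4", "abyX", "abyV", "abyW")

CLUSTER_TEMPLATES: dict[str, tuple[str, ...]] = {
    "1a": (
        "abyI", "abyH", "abyK", "abyU",
        "abyA1", "abyA2", "abyA3", "abyA4", "abyA5",
        "abyB1", "abyB2", "abyB3",
        *_REF_DOWN_1, "abyZ", "abyR", "abyT",
    ),
    "1b": (
        "abyI", "abyH", "abyK", "abyU",
        "abyA1", "abyA2", "abyA3", "abyA4", "abyA5",
        *_REF_DOWN_1, "abyZ", "abyR", "abyT",
        "abyB1", "abyB2", "abyB3",
        "abyV",  # extra copy downstream of the PKS block
    ),
    "2a": (
        "abyU", "abyA1", "abyA3", "abyA4", "abyA5", "abyN",
        "abyB1", "abyB2", "abyB3",
        "abyA2", "abyC", *_REF_DOWN_1[1:], "abyK", "abyH", "abyI",
    ),
    "2b": (
        "abyU", "abyA1", "abyA3", "abyA4", "abyA5", "abyN",
        "abyC", *_REF_DOWN_1[1:], "abyK", "abyH", "abyI",
        "abyB1", "abyB2", "abyB3",
        "abyA2",
    ),
    "3": (
        "abyA1", "abyA2", "abyA3", "abyA4", "abyA5", "abyT", "abyU",
        "abyC", "abyD", "abyE",
        "abyB1", "abyB2", "abyB3",
        "abyF1", "abyF2", "abyM", "abyF3", "abyF4",
        "abyX", "abyV", "abyW", "abyZ", "abyR", "abyH", "abyI",
    ),
    "4": (
        "abyZ", "abyA3", "abyA2",
        "abyC", "abyD", "abyE", "abyH", "abyI", "abyK",
        "abyB1", "abyA1", "abyU", "abyA4", "abyB2", "abyB3",
        "abyF1", "abyF2", "abyF3", "abyF4", "abyX", "abyV", "abyW", "abyR", "abyT",
    ),
}


@dataclass(frozen=True)
class PlantedGene:
    label: str
    protein: SequenceRecord


def plant_cluster(
    cluster_type: str,
    catalog: ReferenceCatalog,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PlantedGene], GroundTruth]:
    """Ordered gene arrangement satisfying exactly one synteny type.

    Types 1a-4 emit their canonical template; type 5 emits a shuffled
    arrangement rejected until it violates every other type's mandatory
    motifs.  Proteins are the catalog references mutated at
    ``config.mutation_rate``.
    """
    rng = rng if rng is not None else config.rng("plant")
    if cluster_type in CLUSTER_TEMPLATES:
        labels = list(CLUSTER_TEMPLATES[cluster_type])
    elif cluster_type == "5":
        pool = list(CLUSTER_TEMPLATES["1a"])
        for _ in range(200):
            shuffled = list(rng.permutation(pool))
            satisfied = bgc_classify.mandatory_motifs_satisfied(shuffled)
            if not any(satisfied.values()):
                labels = shuffled
                break
        else:  # pragma: no cover - rejection virtually always succeeds
            raise RuntimeError("could not sample a type-5 arrangement")
    else:
        raise ValueError(f"unknown cluster type {cluster_type!r}")

    arrangement: list[PlantedGene] = []
    for i, label in enumerate(labels):
        ref = catalog.entries[label].reference_protein.residues
        seq = mutate_protein(ref, config.mutation_rate, rng, config.indel_rate)
        arrangement.append(
            PlantedGene(label=label, protein=SequenceRecord(f"planted_{i}_{label}", "", seq))
        )
    truth = GroundTruth(planted_labels=labels, cluster_type=cluster_type)
    return arrangement, truth


INTERGENIC_RANGE = (50, 500)


def generate_genome(
    config: GeneratorConfig,
    planted: Sequence[PlantedGene] | None = None,
    genome_id: str = "synthetic",
    truth: GroundTruth | None = None,
) -> tuple[Genome, GroundTruth]:
    """A background genome with an optional planted cluster.

    ``background_gene_count`` random genes are laid on one contig with
    50-500 bp intergenic gaps; the planted arrangement (if any) is
    inserted contiguously at a seeded position.  ``config.truncation``
    splits the planted gene at that arrangement index across a contig
    break, truncating its protein, which is how partial (assembly-broken)
    clusters are emulated.
    """
    rng = config.rng("genome")
    truth = truth or GroundTruth()
    lo, hi = config.catalog_protein_lengths
    n_bg = config.background_gene_count
    insert_at = int(rng.integers(0, n_bg + 1)) if planted is not None else None

    entries: list[tuple[str | None, SequenceRecord]] = []  # (planted label or None, protein)
    for i in range(n_bg):
        length = int(rng.integers(lo, hi + 1))
        entries.append((None, SequenceRecord(f"{genome_id}_bg{i}", "", random_protein(rng, length))))
    planted_strand = "+" if planted is None or rng.random() < 0.5 else "-"
    if planted is not None:
        planted_entries = [
            (pg.label, SequenceRecord(f"{genome_id}_{pg.protein.id}", "", pg.protein.residues))
            for pg in planted
        ]
        if planted_strand == "-":
            # reading in strand direction must give the template order
            planted_entries = list(reversed(planted_entries))
        entries = entries[:insert_at] + planted_entries + entries[insert_at:]

    genes: list[Gene] = []
    proteins: dict[str, SequenceRecord] = {}
    planted_ids: list[str] = []
    pos = int(rng.integers(*INTERGENIC_RANGE))
    for i, (label, protein) in enumerate(entries):
        length_nt = 3 * len(protein) + 3
        is_planted = label is not None
        strand = planted_strand if is_planted else ("+" if rng.random() < 0.5 else "-")
        gene = Gene(
            gene_id=f"{genome_id}_g{i}",
            contig_id="c1",
            start=pos,
            end=pos + length_nt,
            strand=strand,
            protein_id=protein.id,
        )
        genes.append(gene)
        proteins[protein.id] = protein
        if is_planted:
            planted_ids.append(gene.gene_id)
            if label in ANCHOR_LABELS:
                truth.anchor_gene_id = gene.gene_id
        pos = gene.end + int(rng.integers(*INTERGENIC_RANGE))
    contig_len = pos

    contigs = {"c1": contig_len}
    if planted is not None and config.truncation is not None:
        genes, proteins, contigs = _truncate_at(
            genes, proteins, contig_len, planted_ids, config.truncation, genome_id
        )
        truth.completeness_suffix = "partial"

    if planted is not None:
        span_genes = [g for g in genes if g.gene_id in set(planted_ids)]
        truth.planted_gene_ids = [g.gene_id for g in span_genes]
        by_contig: dict[str, list[Gene]] = {}
        for g in span_genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        anchor_contig = next(
            (c for c, gs in by_contig.items() if any(g.gene_id == truth.anchor_gene_id for g in gs)),
            None,
        )
        if anchor_contig is not None:
            gs = by_contig[anchor_contig]
            truth.contig_id = anchor_contig
            truth.planted_span = (min(g.start for g in gs), max(g.end for g in gs))
            # a cluster running into a contig end is partial by the edge rule
            if truth.planted_span[0] <= 1000 or contigs[anchor_contig] - truth.planted_span[1] <= 1000:
                truth.completeness_suffix = "partial"

    genome = Genome(genome_id=genome_id, contigs=contigs, genes=genes, proteins=dict(proteins))
    genome.validate()
    return genome, truth


def _truncate_at(
    genes: list[Gene],
    proteins: dict[str, SequenceRecord],
    contig_len: int,
    planted_ids: list[str],
    trunc_index: int,
    genome_id: str,
) -> tuple[list[Gene], dict[str, SequenceRecord], dict[str, int]]:
    """Split the contig at the midpoint of one planted gene."""
    if not (0 <= trunc_index < len(planted_ids)):
        raise ValueError(f"truncation index {trunc_index} outside the planted arrangement")
    victim_id = planted_ids[trunc_index]
    victim = next(g for g in genes if g.gene_id == victim_id)
    break_at = (victim.start + victim.end) // 2
    prot = proteins[victim.protein_id]
    half = max(1, len(prot) // 2)
    left_prot = SequenceRecord(prot.id + "_L", "", prot.residues[:half])
    right_prot = SequenceRecord(prot.id + "_R", "", prot.residues[half:])

    new_genes: list[Gene] = []
    new_proteins = dict(proteins)
    for g in genes:
        if g.gene_id == victim_id:
            new_genes.append(
                Gene(
                    gene_id=g.gene_id + "_L",
                    contig_id="c1",
                    start=g.start,
                    end=break_at,
                    strand=g.strand,
                    protein_id=left_prot.id,
                    partial_flags=PartialFlags(right_truncated=True),
                )
            )
            new_genes.append(
                Gene(
                    gene_id=g.gene_id + "_R",
                    contig_id="c2",
                    start=0,
                    end=g.end - break_at,
                    strand=g.strand,
                    protein_id=right_prot.id,
                    partial_flags=PartialFlags(left_truncated=True),
                )
            )
            new_proteins.pop(g.protein_id, None)
            new_proteins[left_prot.id] = left_prot
            new_proteins[right_prot.id] = right_prot
        elif g.start >= break_at:
            new_genes.append(
                Gene(
                    gene_id=g.gene_id,
                    contig_id="c2",
                    start=g.start - break_at,
                    end=g.end - break_at,
                    strand=g.strand,
                    protein_id=g.protein_id,
                    partial_flags=g.partial_flags,
                )
            )
        else:
            new_genes.append(g)
    # keep the split visible in the planted id list
    idx = planted_ids.index(victim_id)
    planted_ids[idx : idx + 1] = [victim_id + "_L", victim_id + "_R"]
    contigs = {"c1": break_at, "c2": contig_len - break_at}
    return new_genes, new_proteins, contigs


def perturb_labels(
    labels: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    protect_anchor: bool = True,
) -> list[str]:
    """Per-gene label noise: with probability ``rate`` a gene's label is
    dropped to 'unknown' or relabeled to a uniformly random other catalog
    label (50/50).  Anchor (Diels-Alderase) labels are never touched when
    ``protect_anchor``: the anchor's identity comes from the screening
    hit, not from catalog labeling.
    """
    vocabulary = [l for l in CATALOG_INVENTORY if l not in ANCHOR_LABELS]
    out = list(labels)
    for i, label in enumerate(out):
        if protect_anchor and label in ANCHOR_LABELS:
            continue
        if rng.random() < rate:
            if rng.random() < 0.5:
                out[i] = "unknown"
            else:
                out[i] = str(rng.choice([v for v in vocabulary if v != label]))
    return out


def candidate_from_labels(
    labels: Sequence[str],
    genome_id: str = "synthetic",
    contig_id: str = "c1",
    contig_length: int | None = None,
    edge_flags: tuple[bool, bool] = (False, False),
    truncated_gene_index: int | None = None,
    gene_spacing: int = 1_000,
) -> ClusterCandidate:
    """Label-level candidate builder (synthetic coordinates).

    Used to exercise the rule engines directly when sequence-level
    delimitation is not the thing under study.
    """
    labels = list(labels)
    genes: list[LabeledGene] = []
    anchor_index = None
    for i, label in enumerate(labels):
        flags = PartialFlags(right_truncated=(i == truncated_gene_index))
        gene = Gene(
            gene_id=f"{genome_id}_g{i}",
            contig_id=contig_id,
            start=i * gene_spacing,
            end=i * gene_spacing + 900,
            strand="+",
            protein_id=f"{genome_id}_p{i}",
            partial_flags=flags,
        )
        ident = 0.0 if label == "unknown" else 1.0
        genes.append(LabeledGene(gene, label, ident, ident))
        if label in ANCHOR_LABELS and anchor_index is None:
            anchor_index = i
    if anchor_index is None:
        raise ValueError("label list contains no Diels-Alderase anchor label")
    span = (genes[0].gene.start, genes[-1].gene.end)
    if contig_length is None:
        contig_length = span[1] + 20_000
    return ClusterCandidate(
        genome_id=genome_id,
        contig_id=contig_id,
        span=span,
        genes=genes,
        anchor_index=anchor_index,
        pks_block=find_pks_block(labels),
        edge_flags=edge_flags,
        orientation="catalog_forward",
        contig_length=contig_length,
    )


# ---------------------------------------------------------------------------
# cohorts


def _split_path(path: str) -> tuple[str, ...]:
    return tuple(path.split("/"))


def _beta(rng: np.random.Generator, mean: float, concentration: float = 20.0) -> float:
    mean = min(max(mean, 0.01), 0.99)
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


BASELINE_ABUNDANCE = {"Bacteria": 0.70, "Actinobacteria": 0.08}
BASELINE_LOG10_DEPTH = (9.4, 0.30)  # mean, sd of log10 assembled bp


def generate_cohort(
    config: GeneratorConfig,
    n_positive: int = 50,
    n_negative: int = 300,
) -> tuple[list[HabitatRecord], GroundTruth]:
    """Synthetic metagenome cohort with habitat labels and abundances.

    Positives draw habitats from ``config.habitat_weights`` and get the
    configured additive effects on taxon abundance (clipped to [0, 1])
    and on log10 depth; negatives draw habitats from the full-pool mix
    with baseline distributions.
    """
    rng = config.rng("cohort")
    truth = GroundTruth()
    records: list[HabitatRecord] = []
    effects = dict(config.effect_sizes)

    def draw(sample_id: str, weights: Mapping[str, float], positive: bool) -> HabitatRecord:
        paths = list(weights)
        probs = np.array([weights[p] for p in paths])
        path = str(rng.choice(paths, p=probs / probs.sum()))
        abundance = {}
        for taxon, base in BASELINE_ABUNDANCE.items():
            mean = base + (effects.get(taxon, 0.0) if positive else 0.0)
            abundance[taxon] = _beta(rng, mean)
        mu, sd = BASELINE_LOG10_DEPTH
        if positive:
            mu = mu + effects.get("log10_depth_bp", 0.0)
        depth = float(10.0 ** rng.normal(mu, sd))
        truth.habitat_by_sample[sample_id] = path
        return HabitatRecord(
            sample_id=sample_id,
            ontology_path=_split_path(path),
            depth_bp=depth,
            abundance=abundance,
            anchor_positive=positive,
        )

    for i in range(n_positive):
        records.append(draw(f"pos{i}", config.habitat_weights, True))
    for i in range(n_negative):
        records.append(draw(f"neg{i}", POOL_HABITAT_WEIGHTS, False))
    return records, truth


# ---------------------------------------------------------------------------
# HGT scenarios

GENUS_NAMES = ("Streptomyces", "Frankia", "Micromonospora", "Pantoea")


def generate_hgt_scenario(
    config: GeneratorConfig,
    n_taxa: int = 12,
    donor: str | None = None,
    recipient: str | None = None,
    transfer: bool = True,
) -> tuple[dendropy.Tree, dict[str, SequenceRecord], dict[str, str], GroundTruth]:
    """Species tree + gene sequences, optionally with one transfer.

    Taxa are split across four genera forming monophyletic clades; gene
    sequences evolve along the species tree by per-branch substitution.
    With ``transfer`` the recipient's gene instead evolves from the
    donor genus' stem ancestor, so the gene tree places the recipient
    next to the donor clade while the species tree keeps it with its
    genus.  Ground truth records the transferred taxon.
    """
    if n_taxa < 8:
        raise ValueError("need at least 8 taxa for 4 genera of 2")
    rng = config.rng("hgt")
    n_genera = len(GENUS_NAMES)
    sizes = [n_taxa // n_genera + (1 if i < n_taxa % n_genera else 0) for i in range(n_genera)]
    genus_of: dict[str, str] = {}
    taxa_labels: list[str] = []
    for genus, size in zip(GENUS_NAMES, sizes):
        for k in range(size):
            label = f"{genus}_sp{k + 1}"
            taxa_labels.append(label)
            genus_of[label] = genus

    taxon_ns = dendropy.TaxonNamespace(taxa_labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    def join_random(nodes: list[dendropy.Node], lo: float, hi: float) -> dendropy.Node:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            for child in (nodes[i], nodes[j]):
                child.edge.length = float(rng.uniform(lo, hi))
                parent.add_child(child)
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        return nodes[0]

    genus_roots: dict[str, dendropy.Node] = {}
    for genus, size in zip(GENUS_NAMES, sizes):
        leaves = [
            dendropy.Node(taxon=taxon_ns.get_taxon(f"{genus}_sp{k + 1}")) for k in range(size)
        ]
        genus_roots[genus] = join_random(leaves, 0.02, 0.06)
    backbone = join_random(list(genus_roots.values()), 0.06, 0.12)
    tree.seed_node = backbone
    tree.is_rooted = True

    # evolve sequences root -> leaves; remember each node's sequence
    root_seq = random_protein(rng, config.hgt_gene_length)
    node_seq: dict[int, str] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = node_seq[id(node.parent_node)]
        node_seq[id(node)] = mutate_protein(parent_seq, float(node.edge.length or 0.0), rng)

    if recipient is None:
        recipient = f"{GENUS_NAMES[3]}_sp1"  # Pantoea by default
    if donor is None:
        donor = f"{GENUS_NAMES[0]}_sp1"  # a Streptomyces
    if genus_of[recipient] == genus_of[donor]:
        raise ValueError("donor and recipient must belong to different genera")

    truth = GroundTruth()
    gene_seqs: dict[str, SequenceRecord] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        gene_seqs[label] = SequenceRecord(label, "", node_seq[id(leaf)])
    if transfer:
        donor_stem = genus_roots[genus_of[donor]]
        transferred = mutate_protein(node_seq[id(donor_stem)], 0.03, rng)
        gene_seqs[recipient] = SequenceRecord(recipient, "", transferred)
        truth.transferred_taxon = recipient
        truth.donor_taxon = donor
    return tree, gene_seqs, genus_of, truth


def gene_tree_from_sequences(
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
) -> dendropy.Tree:
    """p-distance NJ gene tree (progressive alignment if lengths differ)."""
    from .phylo import Alignment, align_progressive, neighbor_joining, pdistance

    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        aln = Alignment([s.id for s in seqs], [s.residues for s in seqs])
    else:
        aln = align_progressive(seqs)
    return neighbor_joining(pdistance(aln))


# ---------------------------------------------------------------------------
# genome-mining bookkeeping cohort

#: per-category genome counts of the reference mining inventory: 66
#: anchor-positive genomes of which 5 carry a complete abyssomicin BGC,
#: 12 a partial one, 23 a potential abyssomicin BGC, 11 a potential BGC of
#: unclear product, 4 no BGC at all and 11 sit on uninformative contigs.
BOOKKEEPING_COUNTS: dict[str, int] = {
    "abyssomicin_total": 5,
    "abyssomicin_partial": 12,
    "potential_abyssomicin": 23,
    "potential_bgc": 11,
    "not_a_bgc": 4,
    "not_enough_data": 11,
}


def generate_bookkeeping_cohort(
    config: GeneratorConfig,
    counts: Mapping[str, int] | None = None,
) -> list[tuple[str, ClusterCandidate]]:
    """Label-level candidates mirroring the mining inventory bookkeeping.

    Each genome contributes one candidate whose *construction* (planted
    labels, edge/truncation flags, contig size) should produce the
    intended category when classified; the classifier is never told the
    intended category.  Cluster types cycle over the seven synteny
    templates.
    """
    rng = config.rng("default")
    counts = dict(counts or BOOKKEEPING_COUNTS)
    types = ["1a", "1b", "2a", "2b", "3", "4", "5"]
    out: list[tuple[str, ClusterCandidate]] = []
    g = 0

    def next_type() -> str:
        return types[len(out) % len(types)]

    for _ in range(counts.get("abyssomicin_total", 0)):
        labels = list(CLUSTER_TEMPLATES.get(next_type()) or CLUSTER_TEMPLATES["1a"])
        out.append((f"g{g}", candidate_from_labels(labels, genome_id=f"g{g}")))
        g += 1
    for i in range(counts.get("abyssomicin_partial", 0)):
        labels = list(CLUSTER_TEMPLATES.get(next_type()) or CLUSTER_TEMPLATES["1a"])
        if i % 2 == 0:
            cand = candidate_from_labels(labels, genome_id=f"g{g}", edge_flags=(False, True))
        else:
            cand = candidate_from_labels(
                labels, genome_id=f"g{g}", truncated_gene_index=int(rng.integers(0, len(labels)))
            )
        out.append((f"g{g}", cand))
        g += 1
    for _ in range(counts.get("potential_abyssomicin", 0)):
        # biosynthetic core intact but most tailoring labels lost: the
        # label recall stays below the abyssomicin threshold
        labels = [
            "abyU", "abyA1", "abyA2", "abyA3", "abyB1", "abyB2",
            "unknown", "abyC", "abyF1",
        ]
        out.append((f"g{g}", candidate_from_labels(labels, genome_id=f"g{g}")))
        g += 1
    for _ in range(counts.get("potential_bgc", 0)):
        # clustered catalog labels around the anchor, but no PKS/tetronate core
        labels = ["abyU", "abyV", "abyW", "abyX", "abyE", "abyT", "abyD"]
        out.append((f"g{g}", candidate_from_labels(labels, genome_id=f"g{g}")))
        g += 1
    for _ in range(counts.get("not_a_bgc", 0)):
        labels = ["abyU", "unknown", "unknown", "unknown", "abyR"]
        out.append((f"g{g}", candidate_from_labels(labels, genome_id=f"g{g}")))
        g += 1
    for _ in range(counts.get("not_enough_data", 0)):
        out.append(
            (
                f"g{g}",
                candidate_from_labels(["abyU"], genome_id=f"g{g}", contig_length=5_000),
            )
        )
        g += 1
    return out
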