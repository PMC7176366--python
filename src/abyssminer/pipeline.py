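"""End-to-end orchestration: mine -> classify -> report.

`mine_genomes` is the functional core (in-memory genomes in, report
out); `run_mine` wraps it with file I/O.  Reports are deterministic for
a fixed config and seed, and every summary count is recomputable from
the per-genome rows (checked on construction).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .bgc_classify import (
    ABYSSOMICIN_FAMILY,
    CompletenessRules,
    SyntenyRules,
    classify_completeness,
    classify_syntype,
    flag_mobile_elements,
)
from .catalog import (
    ClusterCandidate,
    ReferenceCatalog,
    delimit_cluster,
    label_genes,
    load_catalog,
    merge_overlapping,
)
from .homology import ScoringScheme, default_scheme, find_anchor_hits, hits_table
from .seq_io import Genome, read_fasta, read_features, attach_proteins
from .stats_habitat import (
    HabitatRecord,
    compare_cohorts,
    read_metadata_tsv,
    tally_distribution,
)

logger = logging.getLogger("abyssminer")

#: genome-level category priority when a genome holds several candidates
CATEGORY_PRIORITY = (
    "abyssomicin_total",
    "abyssomicin_partial",
    "potential_abyssomicin_total",
    "potential_abyssomicin_partial",
    "potential_bgc_total",
    "potential_bgc_partial",
    "other_tetronate",
    "not_a_bgc",
    "not_enough_data",
)

ANCHOR_NEGATIVE = "anchor_negative"


@dataclass
class RunConfig:
    proteome_dir: str | None = None
    features_dir: str | None = None
    catalog_entries: str | None = None
    catalog_fasta: str | None = None
    anchors_fasta: str | None = None
    metadata_tsv: str | None = None
    species_tree: str | None = None
    evalue_max: float = 1e-6
    max_gap_genes: int = 4
    flank_probe: int = 30
    mobile_window_bp: int = 10_000
    seed: int = 0
    out_dir: str = "abyssminer_out"

    def provenance(self) -> dict:
        payload = asdict(self)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"config": payload, "config_hash": digest, "seed": self.seed, "version": __version__}


@dataclass
class RunReport:
    genome_rows: list[dict]
    candidate_rows: list[dict]
    summary: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.verify_consistency()

    def verify_consistency(self) -> None:
        """Every summary count must be recomputable from the rows."""
        histogram = self.summary["category_histogram"]
        if sum(histogram.values()) != len(self.genome_rows):
            raise AssertionError("category histogram does not sum to genome count")
        recomputed = summarize([row["category"] for row in self.genome_rows])
        for key in ("n_genomes", "n_positive_genomes", "category_histogram", "percent_positive_with_bgc"):
            if recomputed[key] != self.summary[key]:
                raise AssertionError(f"summary field {key!r} inconsistent with rows")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.genome_rows).to_csv(out / "report.tsv", sep="\t", index=False)
        pd.DataFrame(self.candidate_rows).to_csv(out / "candidates.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {"summary": self.summary, "provenance": self.provenance}, fh, indent=2, default=str
            )


def summarize(genome_categories: Sequence[str]) -> dict:
    """Summary block from per-genome categories.

    The headline fraction is the share of anchor-positive genomes whose
    best candidate is an abyssomicin or potential-abyssomicin BGC,
    reported as a percentage with one decimal.
    """
    histogram: dict[str, int] = {}
    for cat in genome_categories:
        histogram[cat] = histogram.get(cat, 0) + 1
    positives = [c for c in genome_categories if c != ANCHOR_NEGATIVE]
    with_bgc = [c for c in positives if c in ABYSSOMICIN_FAMILY]
    percent = round(100.0 * len(with_bgc) / len(positives), 1) if positives else 0.0
    return {
        "n_genomes": len(genome_categories),
        "n_positive_genomes": len(positives),
        "n_abyssomicin_or_potential": len(with_bgc),
        "category_histogram": dict(sorted(histogram.items())),
        "percent_positive_with_bgc": percent,
    }


def _flank_labeled(genome, candidate: ClusterCandidate, catalog, scheme, window_bp: int):
    genes = genome.genes_on(candidate.contig_id)
    lo = candidate.span[0] - window_bp
    hi = candidate.span[1] + window_bp
    idx = [i for i, g in enumerate(genes) if g.end > lo and g.start < hi]
    if not idx:
        return list(candidate.genes)
    labeled = label_genes(genome, candidate.contig_id, (idx[0], idx[-1] + 1), catalog, scheme)
    return labeled


def mine_genome(
    genome: Genome,
    catalog: ReferenceCatalog,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-6,
    max_gap_genes: int = 4,
    flank_probe: int = 30,
    mobile_window_bp: int = 10_000,
    completeness_rules: CompletenessRules | None = None,
    synteny_rules: SyntenyRules | None = None,
) -> tuple[str, list[dict], list]:
    """Mine one genome; returns (genome category, candidate rows, hits)."""
    scheme = scheme or default_scheme()
    searchable = [genome.proteins[g.protein_id] for g in genome.genes if genome.is_searchable(g)]
    hits = find_anchor_hits(
        searchable, catalog.anchors(), scheme, evalue_max=evalue_max, genome_id=genome.genome_id
    )
    if not hits:
        return ANCHOR_NEGATIVE, [], []
    candidates = [
        delimit_cluster(genome, h, catalog, scheme, max_gap_genes, flank_probe) for h in hits
    ]
    candidates = merge_overlapping(candidates)
    rows: list[dict] = []
    categories: list[str] = []
    for cand in candidates:
        call = classify_completeness(cand, catalog, completeness_rules)
        categories.append(call.category)
        row = {
            "genome_id": genome.genome_id,
            "contig_id": cand.contig_id,
            "span_start": cand.span[0],
            "span_end": cand.span[1],
            "anchor": cand.anchor_hit.anchor_query if cand.anchor_hit else "",
            "n_genes": len(cand.genes),
            "category": call.category,
            "evidence": ";".join(call.evidence),
            "cluster_type": "",
            "motif_score": "",
            "mobile_flag": "",
        }
        if call.category in ABYSSOMICIN_FAMILY:
            syn = classify_syntype(cand, synteny_rules)
            row["cluster_type"] = syn.cluster_type
            row["motif_score"] = round(syn.score, 3)
        flank = _flank_labeled(genome, cand, catalog, scheme, mobile_window_bp)
        row["mobile_flag"] = flag_mobile_elements(genome, cand, flank, mobile_window_bp).location
        rows.append(row)
    best = min(categories, key=lambda c: CATEGORY_PRIORITY.index(c))
    return best, rows, hits


def mine_genomes(
    genomes: Iterable[Genome],
    catalog: ReferenceCatalog | None = None,
    scheme: ScoringScheme | None = None,
    config: RunConfig | None = None,
    completeness_rules: CompletenessRules | None = None,
    synteny_rules: SyntenyRules | None = None,
) -> RunReport:
    """Run the full mining chain over an in-memory genome collection."""
    config = config or RunConfig()
    catalog = catalog or load_catalog()
    scheme = scheme or default_scheme()
    genome_rows: list[dict] = []
    candidate_rows: list[dict] = []
    all_hits = []
    for genome in genomes:
        try:
            genome.validate()
        except Exception as exc:  # skipped, logged, never silently dropped
            logger.warning("skipping genome %s: %s", genome.genome_id, exc)
            continue
        logger.info("mining %s (%d genes)", genome.genome_id, len(genome.genes))
        category, rows, hits = mine_genome(
            genome,
            catalog,
            scheme,
            evalue_max=config.evalue_max,
            max_gap_genes=config.max_gap_genes,
            flank_probe=config.flank_probe,
            mobile_window_bp=config.mobile_window_bp,
            completeness_rules=completeness_rules,
            synteny_rules=synteny_rules,
        )
        genome_rows.append(
            {
                "genome_id": genome.genome_id,
                "n_anchor_hits": len(hits),
                "category": category,
                "cluster_types": ";".join(sorted({r["cluster_type"] for r in rows if r["cluster_type"]})),
                "mobile_flags": ";".join(sorted({r["mobile_flag"] for r in rows if r["mobile_flag"]})),
            }
        )
        candidate_rows.extend(rows)
        all_hits.extend(hits)
    summary = summarize([row["category"] for row in genome_rows])
    summary["n_anchor_hits"] = len(all_hits)
    report = RunReport(
        genome_rows=genome_rows,
        candidate_rows=candidate_rows,
        summary=summary,
        provenance=config.provenance(),
    )
    report.hits = all_hits  # type: ignore[attr-defined]
    return report


def load_genomes(proteome_dir: str | Path, features_dir: str | Path) -> list[Genome]:
    """Pair feature tables with proteome FASTAs by file stem."""
    proteome_dir, features_dir = Path(proteome_dir), Path(features_dir)
    genomes = []
    for feat in sorted(list(features_dir.glob("*.tsv")) + list(features_dir.glob("*.gff*"))):
        dialect = "tsv" if feat.suffix == ".tsv" else "gff3"
        genome = read_features(feat, dialect=dialect, genome_id=feat.stem)
        fasta = next(
            (p for ext in (".faa", ".fasta", ".fa") if (p := proteome_dir / f"{feat.stem}{ext}").exists()),
            None,
        )
        if fasta is None:
            logger.warning("skipping genome %s: no proteome FASTA found", feat.stem)
            continue
        attach_proteins(genome, read_fasta(fasta, alphabet="protein"))
        genomes.append(genome)
    return genomes


def run_mine(config: RunConfig) -> RunReport:
    """File-level entry point: read inputs per config, mine, write report."""
    if not config.proteome_dir or not config.features_dir:
        raise ValueError("run_mine needs proteome_dir and features_dir")
    catalog = (
        load_catalog(config.catalog_entries, config.catalog_fasta)
        if config.catalog_entries
        else load_catalog()
    )
    genomes = load_genomes(config.proteome_dir, config.features_dir)
    report = mine_genomes(genomes, catalog, config=config)
    report.write(config.out_dir)
    hits = getattr(report, "hits", [])
    hits_table(hits).to_csv(Path(config.out_dir) / "anchor_hits.tsv", sep="\t", index=False)
    return report


def run_stats(
    records: Sequence[HabitatRecord] | None = None,
    config: RunConfig | None = None,
    positives_n: int = 50,
    negatives_per_stratum: int = 50,
) -> dict:
    """Habitat tallies plus the positive-vs-negative cohort comparisons."""
    config = config or RunConfig()
    if records is None:
        if not config.metadata_tsv:
            raise ValueError("run_stats needs records or config.metadata_tsv")
        records = read_metadata_tsv(config.metadata_tsv)
    tally = tally_distribution(records, level=2, predicate=lambda r: r.anchor_positive)
    comparison = compare_cohorts(
        records,
        positives_n=positives_n,
        negatives_per_stratum=negatives_per_stratum,
        seed=config.seed,
    )
    return {
        "positive_habitat_tally": {
            cat: {"count": n, "fraction": round(frac, 4)} for cat, (n, frac) in tally.items()
        },
        "cohort_comparison": comparison.to_dict(),
        "provenance": config.provenance(),
    }


def run_phylo(
    hit_proteins: Sequence,
    species_tree,
    genus_of: Mapping[str, str],
    out_dir: str | Path | None = None,
):
    """Gene tree + incongruence screen for the anchor-hit proteins.

    Needs at least 3 hit proteins; fewer is a skip (logged), mirroring
    how a tree on <3 leaves carries no information.
    """
    from . import phylo
    from .synthetic_data import gene_tree_from_sequences

    if len(hit_proteins) < 3:
        logger.warning("phylo stage skipped: %d < 3 anchor proteins", len(hit_proteins))
        return None
    tree = gene_tree_from_sequences(list(hit_proteins))
    rf = phylo.robinson_foulds(tree, species_tree)
    screen = phylo.flag_hgt_candidates(tree, species_tree, genus_of)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phylo.write_newick(tree, out / "gene_tree.nwk")
        phylo.flags_table(screen).to_csv(out / "hgt_flags.tsv", sep="\t", index=False)
    return {"gene_tree": tree, "rf_distance": rf, "screen": screen}
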