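"""Reference gene catalog, neighborhood labeling and BGC delimitation.

The catalog carries one labeled reference protein per known abyssomicin
cluster gene (aby/abs/abm inventories) plus mobile-element references
(transposase, integrase).  Genes around an anchor hit are labeled by best
catalog alignment, and the candidate cluster is grown outward from the
anchor with a gap-bounded extension rule that replaces the interactive
antiSMASH + manual-curation step of the original workflow: extension
stops once ``max_gap_genes`` consecutive genes fail to label, and the
candidate is trimmed so its first and last genes are catalog-labeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import homology
from .homology import AnchorHit, ScoringScheme, default_scheme
from .seq_io import Gene, Genome, SequenceRecord, read_fasta

UNKNOWN = "unknown"

ROLE_CLASSES = ("PKS", "tetronate", "diels_alderase", "regulator", "transport", "tailoring", "other")

PKS_LABELS = ("abyB1", "abyB2", "abyB3")
TETRONATE_LABELS = ("abyA1", "abyA2", "abyA3", "abyA4", "abyA5")
ANCHOR_LABELS = ("abyU", "absU", "abmU")
ABC_TRANSPORT_LABELS = ("abyF1", "abyF2", "abyF3", "abyF4")

#: label -> (role_class, source_cluster, mobile_element)
CATALOG_INVENTORY: dict[str, tuple[str, str, bool]] = {
    # aby cluster (Micromonospora maris AB-18-032)
    "abyU": ("diels_alderase", "aby", False),
    "abyA1": ("tetronate", "aby", False),
    "abyA2": ("tetronate", "aby", False),
    "abyA3": ("tetronate", "aby", False),
    "abyA4": ("tetronate", "aby", False),
    "abyA5": ("tetronate", "aby", False),
    "abyB1": ("PKS", "aby", False),
    "abyB2": ("PKS", "aby", False),
    "abyB3": ("PKS", "aby", False),
    "abyC": ("regulator", "aby", False),
    "abyD": ("transport", "aby", False),
    "abyE": ("tailoring", "aby", False),
    "abyF1": ("transport", "aby", False),
    "abyF2": ("transport", "aby", False),
    "abyF3": ("transport", "aby", False),
    "abyF4": ("transport", "aby", False),
    "abyH": ("regulator", "aby", False),
    "abyI": ("regulator", "aby", False),
    "abyK": ("other", "aby", False),
    "abyM": ("other", "aby", False),
    "abyN": ("other", "aby", False),
    "abyR": ("regulator", "aby", False),
    "abyT": ("tailoring", "aby", False),
    "abyV": ("tailoring", "aby", False),
    "abyW": ("tailoring", "aby", False),
    "abyX": ("tailoring", "aby", False),
    "abyZ": ("tailoring", "aby", False),
    # abs-specific genes (Streptomyces sp. LC-6-2)
    "absU": ("diels_alderase", "abs", False),
    "absC1": ("regulator", "abs", False),
    "absC2": ("regulator", "abs", False),
    "absG1": ("tailoring", "abs", False),
    "absG2": ("tailoring", "abs", False),
    "absI": ("tailoring", "abs", False),
    "absJ": ("tailoring", "abs", False),
    # abm-specific genes (Streptomyces koyangensis SCSIO 5802)
    "abmU": ("diels_alderase", "abm", False),
    "abmK": ("tailoring", "abm", False),
    "abmL": ("tailoring", "abm", False),
    "abmM": ("tailoring", "abm", False),
    "abmN": ("tailoring", "abm", False),
    "abmE2": ("tailoring", "abm", False),
    "abmJ": ("tailoring", "abm", False),
    "abmG": ("tailoring", "abm", False),
    # mobile elements flagged for genomic-island proximity analysis
    "transposase": ("other", "none", True),
    "integrase": ("other", "none", True),
}


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogEntry:
    label: str
    role_class: str
    source_cluster: str
    reference_protein: SequenceRecord
    mobile_element: bool = False

    def __post_init__(self) -> None:
        if self.role_class not in ROLE_CLASSES:
            raise CatalogError(f"{self.label}: unknown role class {self.role_class!r}")


@dataclass
class ReferenceCatalog:
    """Labeled reference proteins plus the homolog-calling thresholds."""

    entries: dict[str, CatalogEntry]
    min_identity: float = 0.30
    min_coverage: float = 0.50

    def __post_init__(self) -> None:
        for required in ("PKS", "tetronate", "diels_alderase"):
            if not any(e.role_class == required for e in self.entries.values()):
                raise CatalogError(f"catalog has no entry with role class {required!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return list(self.entries)

    def role_of(self, label: str) -> str | None:
        entry = self.entries.get(label)
        return entry.role_class if entry else None

    def source_labels(self, source_cluster: str) -> list[str]:
        return [
            e.label
            for e in self.entries.values()
            if e.source_cluster == source_cluster and not e.mobile_element
        ]

    def mobile_labels(self) -> list[str]:
        return [e.label for e in self.entries.values() if e.mobile_element]

    def anchors(self) -> list[SequenceRecord]:
        """Diels-Alderase reference proteins in anchor preference order."""
        order = {label: i for i, label in enumerate(("abyU", "absU", "abmU"))}
        anchors = [e for e in self.entries.values() if e.role_class == "diels_alderase"]
        anchors.sort(key=lambda e: order.get(e.label, len(order)))
        return [
            SequenceRecord(_anchor_query_name(e.label), "", e.reference_protein.residues)
            for e in anchors
        ]


def _anchor_query_name(label: str) -> str:
    # catalog labels are gene-style (abyU); anchor queries protein-style (AbyU)
    return label[:2].capitalize() + label[2:] if label.lower().startswith("ab") else label


def default_catalog_paths() -> tuple[Path, Path]:
    """Paths of the shipped (synthetic-sequence) catalog fixture."""
    data = resources.files("abyssminer") / "data"
    return Path(str(data / "catalog_entries.tsv")), Path(
        str(data / "catalog_proteins.synthetic.faa")
    )


def load_catalog(
    entries_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> ReferenceCatalog:
    """Load a catalog from its TSV + FASTA file pair.

    With no arguments the shipped default fixture is loaded.  Its
    reference sequences are synthetic placeholders (the published
    reference proteins live in supplementary material that is not
    redistributable); users mining real data should supply their own
    FASTA keyed by the same labels.
    """
    if entries_path is None or fasta_path is None:
        entries_path, fasta_path = default_catalog_paths()
    table = pd.read_csv(entries_path, sep="\t", dtype=str)
    required = {"label", "role_class", "source_cluster", "mobile_element"}
    if not required.issubset(table.columns):
        raise CatalogError(f"{entries_path}: catalog columns must include {sorted(required)}")
    proteins = {r.id: r for r in read_fasta(fasta_path, alphabet="protein")}
    entries: dict[str, CatalogEntry] = {}
    for row in table.itertuples(index=False):
        label = str(row.label)
        if label in entries:
            raise CatalogError(f"duplicate catalog label {label!r}")
        if label not in proteins:
            raise CatalogError(f"catalog label {label!r} has no reference protein in FASTA")
        entries[label] = CatalogEntry(
            label=label,
            role_class=str(row.role_class),
            source_cluster=str(row.source_cluster),
            reference_protein=proteins[label],
            mobile_element=str(row.mobile_element).lower() in ("1", "true", "yes"),
        )
    thresholds: dict[str, float] = {}
    for col, key in (("min_identity", "min_identity"), ("min_coverage", "min_coverage")):
        if col in table.columns:
            values = table[col].dropna().unique()
            if len(values):
                thresholds[key] = float(values[0])
    return ReferenceCatalog(entries=entries, **thresholds)


def write_catalog(catalog: ReferenceCatalog, entries_path: str | Path, fasta_path: str | Path) -> None:
    rows = [
        {
            "label": e.label,
            "role_class": e.role_class,
            "source_cluster": e.source_cluster,
            "mobile_element": int(e.mobile_element),
            "min_identity": catalog.min_identity,
            "min_coverage": catalog.min_coverage,
        }
        for e in catalog.entries.values()
    ]
    pd.DataFrame(rows).to_csv(entries_path, sep="\t", index=False)
    from .seq_io import write_fasta

    write_fasta(
        [replace(e.reference_protein, id=e.label) for e in catalog.entries.values()],
        fasta_path,
    )


@dataclass(frozen=True)
class LabeledGene:
    """One gene with its best catalog call (or 'unknown')."""

    gene: Gene
    label: str
    identity: float
    coverage: float


def label_gene(
    protein: SequenceRecord | None,
    catalog: ReferenceCatalog,
    scheme: ScoringScheme,
) -> tuple[str, float, float]:
    """Best catalog label for one protein, or 'unknown'.

    The catalog reference is the alignment query, so coverage means
    coverage *of the reference*: a homolog must align over at least
    ``min_coverage`` of the reference and at ``min_identity`` within the
    aligned region.  Ties go to higher bit score, then lexicographically
    smaller label.
    """
    if protein is None:
        return UNKNOWN, 0.0, 0.0
    target = homology.encode_protein(protein.residues)
    best: tuple[int, str] | None = None
    for label in sorted(catalog.entries):
        entry = catalog.entries[label]
        q = homology.encode_protein(entry.reference_protein.residues)
        raw = int(
            homology._kernels.sw_score(q, target, scheme.matrix, scheme.gap_open, scheme.gap_extend)
        )
        if best is None or raw > best[0]:
            best = (raw, label)
    assert best is not None
    entry = catalog.entries[best[1]]
    res = homology.align_local(entry.reference_protein, protein, scheme)
    if res.identity_fraction >= catalog.min_identity and res.query_coverage >= catalog.min_coverage:
        return best[1], res.identity_fraction, res.query_coverage
    return UNKNOWN, res.identity_fraction, res.query_coverage


def label_genes(
    genome: Genome,
    contig_id: str,
    window: tuple[int, int],
    catalog: ReferenceCatalog,
    scheme: ScoringScheme | None = None,
) -> list[LabeledGene]:
    """Label genes ``window`` (index range, half-open) of one contig.

    Unsearchable genes (no linked protein) are labeled 'unknown' and
    never dropped.  Labeling is idempotent: it depends only on sequences
    and catalog thresholds.
    """
    scheme = scheme or default_scheme()
    genes = genome.genes_on(contig_id)
    lo, hi = window
    if not (0 <= lo <= hi <= len(genes)):
        raise ValueError(f"window {window} outside gene list of {contig_id!r} (n={len(genes)})")
    out: list[LabeledGene] = []
    for gene in genes[lo:hi]:
        label, ident, cov = label_gene(genome.protein_of(gene), catalog, scheme)
        out.append(LabeledGene(gene, label, ident, cov))
    return out


@dataclass
class ClusterCandidate:
    """A delimited, label-annotated gene neighborhood around an anchor.

    ``genes`` is ordered by start coordinate and *reversed* when
    ``orientation == "catalog_reverse"``, so downstream motif logic always
    reads the cluster in catalog orientation.
    """

    genome_id: str
    contig_id: str
    span: tuple[int, int]
    genes: list[LabeledGene]
    anchor_index: int
    pks_block: tuple[int, int] | None
    edge_flags: tuple[bool, bool]  # (left_contig_edge, right_contig_edge)
    orientation: str  # catalog_forward | catalog_reverse
    contig_length: int
    anchor_hit: AnchorHit | None = None

    @property
    def labels(self) -> list[str]:
        return [lg.label for lg in self.genes]

    @property
    def anchor_gene(self) -> LabeledGene:
        return self.genes[self.anchor_index]

    def labeled_count(self) -> int:
        return sum(1 for lg in self.genes if lg.label != UNKNOWN)

    def to_json(self) -> str:
        return json.dumps(
            {
                "genome_id": self.genome_id,
                "contig_id": self.contig_id,
                "span": list(self.span),
                "orientation": self.orientation,
                "anchor_index": self.anchor_index,
                "edge_flags": list(self.edge_flags),
                "genes": [
                    {
                        "gene_id": lg.gene.gene_id,
                        "label": lg.label,
                        "identity": round(lg.identity, 4),
                        "coverage": round(lg.coverage, 4),
                    }
                    for lg in self.genes
                ],
            },
            indent=2,
        )


def find_pks_block(labels: Sequence[str]) -> tuple[int, int] | None:
    """Best contiguous run of PKS labels, half-open.

    The longest run wins; equal-length runs are ranked by how PKS-dense
    their +/-3-gene neighborhood is (the real PKS operon region clusters
    its genes even when one is mislabeled), then by position.
    """
    pks = set(PKS_LABELS)
    runs: list[tuple[int, int]] = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] in pks:
            j = i
            while j < n and labels[j] in pks:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return None
    max_len = max(j - i for i, j in runs)

    def density(run: tuple[int, int]) -> int:
        lo = max(0, run[0] - 3)
        hi = min(n, run[1] + 3)
        return sum(1 for k in range(lo, hi) if labels[k] in pks)

    best = [r for r in runs if r[1] - r[0] == max_len]
    best.sort(key=lambda r: (-density(r), r[0]))
    return best[0]


EDGE_PROXIMITY_BP = 1000


def delimit_cluster(
    genome: Genome,
    hit: AnchorHit,
    catalog: ReferenceCatalog,
    scheme: ScoringScheme | None = None,
    max_gap_genes: int = 4,
    flank_probe: int = 30,
) -> ClusterCandidate:
    """Delimit the candidate BGC around one anchor hit.

    Up to ``flank_probe`` genes on each side of the anchor are labeled;
    the candidate extends outward while fewer than ``max_gap_genes``
    consecutive genes are 'unknown', then is trimmed so that its first
    and last genes carry catalog labels.  Edge flags are set when the
    trimmed span comes within 1 kb of a contig end.  Orientation is
    catalog_reverse when the PKS block (or, absent one, the anchor gene)
    lies on the minus strand.
    """
    scheme = scheme or default_scheme()
    anchor_gene_idx: int | None = None
    contig_id: str | None = None
    for cid in genome.contigs:
        genes = genome.genes_on(cid)
        for i, g in enumerate(genes):
            if g.protein_id == hit.protein_id or g.gene_id == hit.protein_id:
                anchor_gene_idx, contig_id = i, cid
                break
        if anchor_gene_idx is not None:
            break
    if anchor_gene_idx is None or contig_id is None:
        raise CatalogError(
            f"anchor protein {hit.protein_id!r} has no gene model in genome {genome.genome_id!r}"
        )
    genes = genome.genes_on(contig_id)
    lo = max(0, anchor_gene_idx - flank_probe)
    hi = min(len(genes), anchor_gene_idx + flank_probe + 1)
    labeled = label_genes(genome, contig_id, (lo, hi), catalog, scheme)
    a = anchor_gene_idx - lo  # anchor position within the labeled window

    # force the anchor's label to its screening identity: the anchor is a
    # Diels-Alderase hit by construction even if the catalog call differs
    anchor_lg = labeled[a]
    if catalog.role_of(anchor_lg.label) != "diels_alderase":
        anchor_label = _anchor_label_for_query(hit.anchor_query, catalog)
        labeled[a] = LabeledGene(
            anchor_lg.gene, anchor_label, hit.result.identity_fraction, hit.result.query_coverage
        )

    def extend(direction: int) -> int:
        idx = a
        gap = 0
        last = a
        j = a + direction
        while 0 <= j < len(labeled) and gap < max_gap_genes:
            if labeled[j].label == UNKNOWN:
                gap += 1
            else:
                gap = 0
                last = j
            j += direction
        return last

    left = extend(-1)
    right = extend(+1)
    window = labeled[left : right + 1]
    anchor_in_window = a - left

    first = genes[lo + left]
    last = genes[lo + right]
    span = (first.start, last.end)
    contig_length = genome.contigs[contig_id]
    edge_flags = (
        span[0] <= EDGE_PROXIMITY_BP,
        contig_length - span[1] <= EDGE_PROXIMITY_BP,
    )

    pks = find_pks_block([lg.label for lg in window])
    if pks is not None:
        block_strands = [lg.gene.strand for lg in window[pks[0] : pks[1]]]
        minus = block_strands.count("-") > len(block_strands) / 2
    else:
        minus = window[anchor_in_window].gene.strand == "-"
    orientation = "catalog_reverse" if minus else "catalog_forward"
    if orientation == "catalog_reverse":
        window = list(reversed(window))
        anchor_in_window = len(window) - 1 - anchor_in_window
        pks = find_pks_block([lg.label for lg in window])

    return ClusterCandidate(
        genome_id=genome.genome_id,
        contig_id=contig_id,
        span=span,
        genes=window,
        anchor_index=anchor_in_window,
        pks_block=pks,
        edge_flags=edge_flags,
        orientation=orientation,
        contig_length=contig_length,
        anchor_hit=hit,
    )


def _anchor_label_for_query(anchor_query: str, catalog: ReferenceCatalog) -> str:
    label = anchor_query[0].lower() + anchor_query[1:]
    if label in catalog.entries:
        return label
    for entry in catalog.entries.values():
        if entry.role_class == "diels_alderase":
            return entry.label
    raise CatalogError("catalog has no diels_alderase entry")


def merge_overlapping(candidates: list[ClusterCandidate]) -> list[ClusterCandidate]:
    """Merge candidates whose spans intersect on the same contig.

    Paralogous anchors inside one cluster each seed a candidate; when the
    spans overlap the candidates describe the same neighborhood, so the
    one anchored at the lower-E-value hit is kept.
    """
    by_contig: dict[tuple[str, str], list[ClusterCandidate]] = {}
    for c in candidates:
        by_contig.setdefault((c.genome_id, c.contig_id), []).append(c)
    merged: list[ClusterCandidate] = []
    for group in by_contig.values():
        group.sort(key=lambda c: c.span)
        kept: list[ClusterCandidate] = []
        for cand in group:
            if kept and cand.span[0] < kept[-1].span[1]:
                prev = kept[-1]
                e_prev = prev.anchor_hit.result.evalue if prev.anchor_hit else 0.0
                e_new = cand.anchor_hit.result.evalue if cand.anchor_hit else 0.0
                if e_new < e_prev:
                    kept[-1] = cand
            else:
                kept.append(cand)
        merged.extend(kept)
    return merged
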