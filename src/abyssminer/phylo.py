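"""Distance-based gene trees and gene-tree/species-tree incongruence.

The anchor-hit proteins are aligned with a guide-tree progressive
aligner, pairwise p-distances are computed over gap-free columns, and a
Saitou-Nei neighbor-joining tree is built.  Incongruence with a supplied
species tree is quantified with the Robinson-Foulds bipartition distance
and, per leaf, with a genus-level sister-clade discordance rule that
flags horizontal-transfer candidates: a leaf whose gene-tree sister
clade contains no member of its own genus, while its species-tree sister
clade is monogeneric for that genus, did not inherit the gene
vertically under the simplest reading.

p-distance (no multiple-hit correction) is the default model; it is
transparent and sufficient for topology-level incongruence.  A Poisson
correction is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import _kernels, homology
from .homology import AnchorHit, ScoringScheme, default_scheme
from .seq_io import SequenceRecord

GAP = "-"


class PhyloError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by taxon id, input order preserved."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PhyloError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError(f"alignment rows have unequal lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_fasta_records(self) -> list[SequenceRecord]:
        # gapped FASTA rows; alphabet validation applies only on reading
        return [SequenceRecord(i, "", r) for i, r in zip(self.ids, self.rows)]


def _row_profile(rows: Sequence[str]) -> np.ndarray:
    """(columns, 21) residue-frequency profile; gap mass omitted."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, 21), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                prof[j, homology._RESIDUE_INDEX[c]] += 1.0
    prof /= len(rows)
    return prof


def _apply_ops(rows_a: list[str], rows_b: list[str], ops: np.ndarray) -> list[str]:
    """Merge two row groups along a profile-alignment op path."""
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 1:  # both columns
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == 2:  # column from A, gap in B
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            ia += 1
        else:  # column from B, gap in A
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def align_pair_global(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> tuple[int, str, str]:
    """Affine-gap global alignment of two sequences (score, row_a, row_b)."""
    scheme = scheme or default_scheme()
    qa = homology.encode_protein(a.residues)
    qb = homology.encode_protein(b.residues)
    score, ops = _kernels.nw_align(qa, qb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    rows = _apply_ops([a.residues], [b.residues], ops)
    return int(score), rows[0], rows[1]


def align_progressive(
    sequences: Sequence[SequenceRecord], scheme: ScoringScheme | None = None
) -> Alignment:
    """Guide-tree progressive multiple alignment.

    Pairwise global alignments give an identity-based distance matrix;
    average-linkage clustering of that matrix fixes the merge order, and
    groups are merged by profile-profile alignment under the same
    scoring scheme.  Ungapping any output row recovers its input
    sequence exactly.
    """
    scheme = scheme or default_scheme()
    sequences = list(sequences)
    if not sequences:
        raise PhyloError("no sequences to align")
    if len(sequences) == 1:
        return Alignment([sequences[0].id], [sequences[0].residues])
    if len({s.id for s in sequences}) != len(sequences):
        raise PhyloError("duplicate sequence ids in alignment input")
    n = len(sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ra, rb = align_pair_global(sequences[i], sequences[j], scheme)
            matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
            cols = sum(1 for x, y in zip(ra, rb) if x != GAP and y != GAP)
            ident = matches / cols if cols else 0.0
            dist[i, j] = dist[j, i] = 1.0 - ident
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i].residues]) for i in range(n)
    }
    for step, (a_idx, b_idx, _, _) in enumerate(linkage):
        ids_a, rows_a = clusters.pop(int(a_idx))
        ids_b, rows_b = clusters.pop(int(b_idx))
        pa = _row_profile(rows_a)
        pb = _row_profile(rows_b)
        ops = _kernels.profile_align(pa, pb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
        merged = _apply_ops(rows_a, rows_b, ops)
        clusters[n + step] = (ids_a + ids_b, merged)
    (order, rows), = clusters.values()
    by_input = sorted(range(len(order)), key=lambda k: order[k])
    return Alignment(
        ids=[sequences[order[k]].id for k in by_input],
        rows=[rows[k] for k in by_input],
    )


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise PhyloError("distance matrix shape does not match taxon count")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise PhyloError("distance matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise PhyloError("distances must be non-negative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


def pdistance(alignment: Alignment, poisson_correction: bool = False) -> DistanceMatrix:
    """Pairwise p-distance over columns where neither row is gapped.

    With ``poisson_correction`` the distance is -ln(1 - p).  A pair with
    zero comparable columns is an error naming the pair.
    """
    if len(alignment) < 2:
        raise PhyloError("p-distance needs at least two rows")
    n = len(alignment)
    arr = np.array([list(r) for r in alignment.rows])
    gap = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise PhyloError(
                    f"rows {alignment.ids[i]!r} and {alignment.ids[j]!r} share no "
                    "gap-free columns"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / n_ok
            if poisson_correction:
                if p >= 1.0:
                    raise PhyloError("Poisson correction undefined at p = 1")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=list(alignment.ids), matrix=d)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-matrix pair selection with lexicographically-smallest-taxon-pair
    tie-break; standard branch-length formulas; a negative branch length
    is clamped to zero with the deficit moved to its sister branch.  The
    output reproduces additive input distances exactly (path lengths) and
    is returned rooted at the final join (trifurcating root), with an
    unrooted interpretation for comparisons.
    """
    n = len(D)
    taxa = dendropy.TaxonNamespace(list(D.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n < 2:
        raise PhyloError("neighbor joining needs at least 2 taxa")
    nodes: dict[str, dendropy.Node] = {}
    for tid in D.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(tid))
        nodes[tid] = node
    if n == 2:
        edge = float(D.matrix[0, 1])
        root = tree.seed_node
        for tid, half in zip(D.ids, (edge / 2.0, edge / 2.0)):
            nodes[tid].edge.length = half
            root.add_child(nodes[tid])
        return tree

    active = list(D.ids)
    # smallest-label representative of each active cluster, for tie-breaks
    rep = {tid: tid for tid in D.ids}
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(D.ids):
        for j, b in enumerate(D.ids):
            if i < j:
                dist[(a, b)] = dist[(b, a)] = float(D.matrix[i, j])

    join_count = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best_pair: tuple[str, str] | None = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * dist[(a, b)] - totals[a] - totals[b]
                key = tuple(sorted((rep[a], rep[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best_pair is not None
                    and key < tuple(sorted((rep[best_pair[0]], rep[best_pair[1]])))
                ):
                    best_q = q
                    best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        d_ab = dist[(a, b)]
        la = 0.5 * d_ab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = d_ab - la
        la, lb = _clamp_pair(la, lb)
        new_id = f"__join{join_count}"
        join_count += 1
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[new_id] = parent
        rep[new_id] = min(rep[a], rep[b])
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist[(a, c)] + dist[(b, c)] - d_ab)
            dist[(new_id, c)] = dist[(c, new_id)] = max(0.0, d_new)
        active = [c for c in active if c not in (a, b)] + [new_id]

    # final trifurcation
    x, y, z = active
    lx = 0.5 * (dist[(x, y)] + dist[(x, z)] - dist[(y, z)])
    ly = 0.5 * (dist[(x, y)] + dist[(y, z)] - dist[(x, z)])
    lz = 0.5 * (dist[(x, z)] + dist[(y, z)] - dist[(x, y)])
    root = tree.seed_node
    for tid, length in ((x, lx), (y, ly), (z, lz)):
        nodes[tid].edge.length = max(0.0, length)
        root.add_child(nodes[tid])
    tree.is_rooted = False
    return tree


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sister."""
    if la < 0.0:
        lb += la
        la = 0.0
    if lb < 0.0:
        la += lb
        lb = 0.0
    return max(0.0, la), max(0.0, lb)


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (non-trivial bipartition count).

    Both trees must share an identical leaf set; the error message lists
    the difference otherwise.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise PhyloError(
            f"leaf sets differ: only in first={sorted(l1 - l2)}, only in second={sorted(l2 - l1)}"
        )
    taxa = dendropy.TaxonNamespace(sorted(l1))
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=taxa)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=taxa)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def _sister_leaves(tree: dendropy.Tree, leaf_label: str) -> set[str]:
    """Nearest-neighbor leaf set of one leaf, on the unrooted view.

    At the leaf's attachment node the tree splits into neighboring
    subtrees; the smallest of them is the leaf's local neighborhood
    (its cherry partner or sister clade), independent of where the
    rooted representation happens to place the root.
    """
    leaf = next(
        (l for l in tree.leaf_node_iter() if l.taxon is not None and l.taxon.label == leaf_label),
        None,
    )
    if leaf is None:
        raise PhyloError(f"leaf {leaf_label!r} not in tree")
    parent = leaf.parent_node
    if parent is None:
        return set()
    all_leaves = leaf_labels(tree)
    subtrees: list[set[str]] = []
    for child in parent.child_nodes():
        if child is leaf:
            continue
        subtrees.append(
            {l.taxon.label for l in child.leaf_iter() if l.taxon is not None}
        )
    under_parent = {l.taxon.label for l in parent.leaf_iter() if l.taxon is not None}
    up = all_leaves - under_parent
    if up:
        subtrees.append(up)
    subtrees = [s for s in subtrees if s]
    if not subtrees:
        return set()
    return min(subtrees, key=lambda s: (len(s), tuple(sorted(s))))


@dataclass(frozen=True)
class HgtFlag:
    leaf: str
    genus: str
    gene_sisters: tuple[str, ...]
    species_sisters: tuple[str, ...]


@dataclass
class HgtScreen:
    flags: list[HgtFlag]
    skipped: list[str]  # leaves with unknown genus


def flag_hgt_candidates(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    genus_of: Mapping[str, str],
) -> HgtScreen:
    """Genus-level sister-clade discordance screen.

    A leaf is flagged when its gene-tree sister clade contains no member
    of its genus while its species-tree sister clade is monogeneric for
    that genus.  This mirrors a qualitative transfer argument, not a full
    duplication-transfer-loss reconciliation.
    """
    gene_leaves = leaf_labels(gene_tree)
    species_leaves = leaf_labels(species_tree)
    extra = gene_leaves - species_leaves
    if extra:
        raise PhyloError(f"gene-tree leaves missing from species tree: {sorted(extra)}")
    flags: list[HgtFlag] = []
    skipped: list[str] = []
    for leaf in sorted(gene_leaves):
        genus = genus_of.get(leaf)
        if genus is None:
            skipped.append(leaf)
            continue
        gene_sisters = _sister_leaves(gene_tree, leaf)
        species_sisters = _sister_leaves(species_tree, leaf)
        if not gene_sisters or not species_sisters:
            continue
        gene_genera = {genus_of.get(s) for s in gene_sisters}
        species_genera = {genus_of.get(s) for s in species_sisters}
        if genus not in gene_genera and species_genera == {genus}:
            flags.append(
                HgtFlag(
                    leaf=leaf,
                    genus=genus,
                    gene_sisters=tuple(sorted(gene_sisters)),
                    species_sisters=tuple(sorted(species_sisters)),
                )
            )
    return HgtScreen(flags=flags, skipped=skipped)


def detect_paralogs(hits: Iterable[AnchorHit]) -> dict[str, list[str]]:
    """Genomes with two or more anchor hits -> their hit protein ids."""
    by_genome: dict[str, list[str]] = {}
    for h in hits:
        if h.genome_id is None:
            continue
        by_genome.setdefault(h.genome_id, []).append(h.protein_id)
    return {g: ids for g, ids in by_genome.items() if len(ids) >= 2}


def flags_table(screen: HgtScreen) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "leaf": f.leaf,
                "genus": f.genus,
                "gene_tree_sisters": ",".join(f.gene_sisters),
                "species_tree_sisters": ",".join(f.species_sisters),
            }
            for f in screen.flags
        ],
        columns=["leaf", "genus", "gene_tree_sisters", "species_tree_sisters"],
    )
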