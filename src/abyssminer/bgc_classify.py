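"""Rule engines classifying delimited candidates.

Two verdicts are produced per candidate cluster:

* a *completeness* category combining cluster identity (abyssomicin /
  potential abyssomicin / potential BGC / none) with assembly integrity
  (total vs partial, driven by contig-edge and gene-truncation flags);
* a *synteny type* (1a, 1b, 2a, 2b, 3, 4 or the no-synteny fallback 5)
  from declarative motifs over the orientation-normalized label order.

The published synteny descriptions are prose; the quantifications used
here (how near is "nearby", how many out-of-order labels still count as
"punctual rearrangements") are explicit, config-backed choices collected
in :class:`SyntenyRules`.  Mobile-element proximity uses the +/-10 kb
window of the genomic-island analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .catalog import (
    ABC_TRANSPORT_LABELS,
    ANCHOR_LABELS,
    PKS_LABELS,
    TETRONATE_LABELS,
    UNKNOWN,
    ClusterCandidate,
    LabeledGene,
    ReferenceCatalog,
    find_pks_block,
)
from .seq_io import Genome

COMPLETENESS_CATEGORIES = (
    "abyssomicin_total",
    "abyssomicin_partial",
    "potential_abyssomicin_total",
    "potential_abyssomicin_partial",
    "potential_bgc_total",
    "potential_bgc_partial",
    "not_a_bgc",
    "not_enough_data",
    "other_tetronate",
)

ABYSSOMICIN_FAMILY = (
    "abyssomicin_total",
    "abyssomicin_partial",
    "potential_abyssomicin_total",
    "potential_abyssomicin_partial",
)


@dataclass(frozen=True)
class CompletenessCall:
    category: str
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class SyntenyTypeCall:
    cluster_type: str
    matched_motifs: tuple[str, ...]
    score: float


@dataclass(frozen=True)
class MobileFlag:
    location: str  # inside_bgc | near_bgc | near_anchor | none
    elements: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class CompletenessRules:
    """Tunable thresholds behind the completeness decision procedure."""

    min_genes: int = 5
    min_contig_bp: int = 15_000
    min_labeled_for_bgc: int = 5
    min_tetronate: int = 3
    label_recall: float = 0.80  # abyssomicin vs potential-abyssomicin split


def classify_completeness(
    candidate: ClusterCandidate,
    catalog: ReferenceCatalog,
    rules: CompletenessRules | None = None,
) -> CompletenessCall:
    """Completeness verdict for one labeled candidate; first match wins.

    Decision order: (i) too little data (few genes or a short contig);
    (ii) no biosynthetic signal at all; (iii)/(iv) biosynthetic core
    present (PKS + tetronate operon + anchor), split into abyssomicin vs
    potential-abyssomicin by recall of the source cluster's gene labels;
    (v) a clustered set of catalog labels without the core.  The _partial
    suffix fires whenever any contig-edge or gene-truncation flag is set.
    """
    rules = rules or CompletenessRules()
    evidence: list[str] = []
    labels = candidate.labels
    labeled = [l for l in labels if l != UNKNOWN]
    distinct = set(labeled)

    if len(candidate.genes) < rules.min_genes or candidate.contig_length < rules.min_contig_bp:
        evidence.append("short_candidate_or_contig")
        return CompletenessCall("not_enough_data", tuple(evidence))

    n_pks = len(distinct & set(PKS_LABELS))
    n_tetronate = len(distinct & set(TETRONATE_LABELS))
    if n_pks == 0 and n_tetronate == 0 and len(distinct) < rules.min_labeled_for_bgc:
        return CompletenessCall("not_a_bgc", ())

    partial = any(candidate.edge_flags) or any(
        lg.gene.partial_flags.any() for lg in candidate.genes
    )
    suffix = "partial" if partial else "total"
    if partial:
        evidence.append("edge_or_truncation_flag")

    anchor_label = candidate.anchor_gene.label
    has_anchor = anchor_label in ANCHOR_LABELS or catalog.role_of(anchor_label) == "diels_alderase"
    core = n_pks >= 1 and n_tetronate >= rules.min_tetronate and has_anchor
    if core:
        evidence.append("core_pks_tetronate_anchor")
        source = catalog.entries[anchor_label].source_cluster if anchor_label in catalog.entries else "aby"
        source_labels = set(catalog.source_labels(source)) or set(catalog.source_labels("aby"))
        recall = len(distinct & source_labels) / len(source_labels)
        if recall >= rules.label_recall:
            evidence.append(f"label_recall_{recall:.2f}")
            return CompletenessCall(f"abyssomicin_{suffix}", tuple(evidence))
        evidence.append(f"label_recall_{recall:.2f}_below_threshold")
        return CompletenessCall(f"potential_abyssomicin_{suffix}", tuple(evidence))

    if len(distinct) >= rules.min_labeled_for_bgc:
        evidence.append("clustered_labels_without_core")
        return CompletenessCall(f"potential_bgc_{suffix}", tuple(evidence))
    return CompletenessCall("not_a_bgc", ())


# ---------------------------------------------------------------------------
# synteny typing


#: canonical downstream reference order of the aby cluster (type 1/3 blocks)
REF_C_TO_W = ("abyC", "abyD", "abyE", "abyF1", "abyF2", "abyF3", "abyF4", "abyX", "abyV", "abyW")
#: canonical reference order for type-2 downstream synteny (abyA2 .. abyI)
REF_A2_TO_I = (
    "abyA2",
    "abyC",
    "abyD",
    "abyE",
    "abyF1",
    "abyF2",
    "abyF3",
    "abyF4",
    "abyX",
    "abyV",
    "abyW",
    "abyK",
    "abyH",
    "abyI",
)


@dataclass(frozen=True)
class SyntenyRules:
    """Quantifications of the prose motif descriptions."""

    nearby_genes: int = 5  # "next to/nearby"
    followed_by_genes: int = 2  # "followed by"
    max_out_of_order: int = 2  # "punctual rearrangements"
    min_shared_for_synteny: int = 6  # labels required to claim a conserved block
    max_shared_for_absence: int = 2  # labels tolerated when a block must be absent
    min_operon_side: int = 3  # "entire operon" tolerance on one side
    min_adjacent_run: int = 4  # contiguous operon run for type 3


def _out_of_order(observed: Sequence[str], reference: Sequence[str]) -> tuple[int, int]:
    """(#shared labels, #labels breaking the reference order).

    First occurrences of reference labels are mapped to reference ranks;
    the out-of-order count is shared minus the longest increasing
    subsequence of those ranks.
    """
    rank = {label: i for i, label in enumerate(reference)}
    seq: list[int] = []
    seen: set[str] = set()
    for label in observed:
        if label in rank and label not in seen:
            seen.add(label)
            seq.append(rank[label])
    if not seq:
        return 0, 0
    tails: list[int] = []  # patience LIS
    import bisect

    for r in seq:
        pos = bisect.bisect_left(tails, r)
        if pos == len(tails):
            tails.append(r)
        else:
            tails[pos] = r
    return len(seq), len(seq) - len(tails)


@dataclass(frozen=True)
class _Motif:
    name: str
    mandatory: bool
    check: Callable[["_Layout", SyntenyRules], bool]


class _Layout:
    """Orientation-normalized label layout with up/downstream regions."""

    def __init__(self, labels: Sequence[str]):
        self.labels = list(labels)
        self.pks_block = find_pks_block(self.labels)
        if self.pks_block is not None:
            self.up = self.labels[: self.pks_block[0]]
            self.down = self.labels[self.pks_block[1] :]
        else:
            self.up = list(self.labels)
            self.down = []
        self.pks_positions = [i for i, l in enumerate(self.labels) if l in PKS_LABELS]

    def upstream_count(self, group: Sequence[str]) -> int:
        return len(set(self.up) & set(group))

    def anchor_positions(self, region: Sequence[str]) -> list[int]:
        return [i for i, l in enumerate(region) if l in ANCHOR_LABELS]

    def operon_positions(self, region: Sequence[str]) -> list[int]:
        return [i for i, l in enumerate(region) if l in TETRONATE_LABELS]


def _anchor_near_operon_upstream(lay: _Layout, rules: SyntenyRules) -> bool:
    ops = lay.operon_positions(lay.up)
    anchors = lay.anchor_positions(lay.up)
    return bool(ops and anchors) and min(
        abs(a - o) for a in anchors for o in ops
    ) <= rules.nearby_genes


def _block_in_order(region: Sequence[str], reference: Sequence[str], rules: SyntenyRules) -> bool:
    shared, ooo = _out_of_order(region, reference)
    return shared >= rules.min_shared_for_synteny and ooo <= rules.max_out_of_order


def _block_absent(region: Sequence[str], reference: Sequence[str], rules: SyntenyRules) -> bool:
    shared = len(set(region) & set(reference))
    return shared <= rules.max_shared_for_absence


def _operon_except_a2_up(lay: _Layout, rules: SyntenyRules) -> bool:
    return lay.upstream_count(("abyA1", "abyA3", "abyA4", "abyA5")) >= rules.min_operon_side


def _n_after_operon(lay: _Layout, rules: SyntenyRules) -> bool:
    ops = lay.operon_positions(lay.up)
    if not ops or "abyN" not in lay.up:
        return False
    n_pos = lay.up.index("abyN")
    before = [o for o in ops if o < n_pos]
    return bool(before) and n_pos - max(before) <= rules.followed_by_genes


def _adjacent_operon_run(lay: _Layout, rules: SyntenyRules) -> tuple[int, int, int] | None:
    """Densest near-contiguous run of tetronate labels.

    Successive operon genes may be separated by at most one intervening
    gene (a single insertion or mislabel does not dissolve an operon).
    Returns (start, end_exclusive, member_count) of the best run.
    """
    positions = [i for i, l in enumerate(lay.labels) if l in TETRONATE_LABELS]
    if not positions:
        return None
    best: tuple[int, int, int] | None = None
    start = 0
    for k in range(1, len(positions) + 1):
        if k == len(positions) or positions[k] - positions[k - 1] > 2:
            count = k - start
            run = (positions[start], positions[k - 1] + 1, count)
            if best is None or count > best[2]:
                best = run
            start = k
    return best


def _t_after_run(lay: _Layout, rules: SyntenyRules) -> bool:
    run = _adjacent_operon_run(lay, rules)
    if run is None or run[2] < rules.min_adjacent_run:
        return False
    window = lay.labels[run[1] : run[1] + rules.followed_by_genes]
    return "abyT" in window


def _m_interrupts_abc(lay: _Layout, rules: SyntenyRules) -> bool:
    labels = lay.labels
    abc = set(ABC_TRANSPORT_LABELS)
    for j, label in enumerate(labels):
        if label != "abyM":
            continue
        left = any(l in abc for l in labels[max(0, j - rules.followed_by_genes) : j])
        right = any(l in abc for l in labels[j + 1 : j + 1 + rules.followed_by_genes])
        if left and right:
            return True
    return False


def _anchor_flanked_by_pks(lay: _Layout, rules: SyntenyRules) -> bool:
    """Anchor sits inside the PKS operon: a PKS gene within a few genes
    on *both* sides of the anchor (the inserted-block signature)."""
    window = rules.nearby_genes - 1  # local: strictly inside the operon
    for a in lay.anchor_positions(lay.labels):
        left = any(
            lay.labels[k] in PKS_LABELS for k in range(max(0, a - window), a)
        )
        right = any(
            lay.labels[k] in PKS_LABELS
            for k in range(a + 1, min(len(lay.labels), a + 1 + window))
        )
        if left and right:
            return True
    return False


def _label_flanked_by_pks(lay: _Layout, label: str, rules: SyntenyRules) -> bool:
    window = rules.nearby_genes - 1
    for a, lab in enumerate(lay.labels):
        if lab != label:
            continue
        left = any(lay.labels[k] in PKS_LABELS for k in range(max(0, a - window), a))
        right = any(
            lay.labels[k] in PKS_LABELS
            for k in range(a + 1, min(len(lay.labels), a + 1 + window))
        )
        if left and right:
            return True
    return False


def _zaa_before_anchor(lay: _Layout, rules: SyntenyRules) -> bool:
    anchors = lay.anchor_positions(lay.labels)
    if not anchors:
        return False
    first = min(anchors)
    return len({"abyZ", "abyA3", "abyA2"} & set(lay.labels[:first])) >= 2


def _type_motifs(rules: SyntenyRules) -> dict[str, list[_Motif]]:
    R = rules

    def operon_up(lay: _Layout, r: SyntenyRules) -> bool:
        return lay.upstream_count(TETRONATE_LABELS) >= r.min_operon_side

    return {
        "1a": [
            _Motif("operon_upstream", True, operon_up),
            _Motif("anchor_near_operon", True, _anchor_near_operon_upstream),
            _Motif("c_to_w_downstream", True, lambda l, r: bool(l.down) and _block_in_order(l.down, REF_C_TO_W, r)),
            _Motif("full_operon_upstream", False, lambda l, r: l.upstream_count(TETRONATE_LABELS) == 5),
            _Motif("a2_upstream", False, lambda l, r: "abyA2" in l.up),
            _Motif("no_abyN", False, lambda l, r: "abyN" not in l.labels),
            _Motif("abyC_downstream", False, lambda l, r: "abyC" in l.down),
            _Motif("abyW_downstream", False, lambda l, r: "abyW" in l.down),
            _Motif(
                "anchor_near_KHI",
                False,
                lambda l, r: any(
                    abs(a - i) <= r.nearby_genes
                    for a in l.anchor_positions(l.labels)
                    for i, lab in enumerate(l.labels)
                    if lab in ("abyK", "abyH", "abyI")
                ),
            ),
        ],
        "1b": [
            _Motif("operon_upstream", True, operon_up),
            _Motif("anchor_near_operon", True, _anchor_near_operon_upstream),
            _Motif("c_to_w_upstream", True, lambda l, r: _block_in_order(l.up, REF_C_TO_W, r)),
            _Motif("c_to_w_not_downstream", True, lambda l, r: _block_absent(l.down, REF_C_TO_W, r)),
            _Motif("extra_abyV_downstream", False, lambda l, r: "abyV" in l.down),
            _Motif("full_operon_upstream", False, lambda l, r: l.upstream_count(TETRONATE_LABELS) == 5),
            _Motif("no_abyN", False, lambda l, r: "abyN" not in l.labels),
        ],
        "2a": [
            _Motif("operon_except_a2_upstream", True, _operon_except_a2_up),
            _Motif("a2_to_i_downstream", True, lambda l, r: bool(l.down) and _block_in_order(l.down, REF_A2_TO_I, r)),
            # abyN is the type-2 signature gene but a single mislabel must
            # not veto the call: it discriminates through the score instead
            _Motif("abyN_follows_operon", False, _n_after_operon),
            _Motif("a2_downstream", False, lambda l, r: "abyA2" in l.down),
            _Motif("a2_not_upstream", False, lambda l, r: "abyA2" not in l.up),
            _Motif("anchor_upstream", False, lambda l, r: bool(l.anchor_positions(l.up))),
        ],
        "2b": [
            _Motif("operon_except_a2_upstream", True, _operon_except_a2_up),
            _Motif(
                "a2_to_i_upstream",
                True,
                lambda l, r: _block_in_order(l.up, tuple(x for x in REF_A2_TO_I if x != "abyA2"), r),
            ),
            _Motif(
                "block_not_downstream",
                True,
                lambda l, r: _block_absent(l.down, tuple(x for x in REF_A2_TO_I if x != "abyA2"), r),
            ),
            _Motif("abyN_follows_operon", False, _n_after_operon),
            _Motif("a2_downstream", False, lambda l, r: "abyA2" in l.down),
            _Motif("a2_not_upstream", False, lambda l, r: "abyA2" not in l.up),
        ],
        "3": [
            _Motif(
                "adjacent_operon_run",
                True,
                lambda l, r: (lambda run: run is not None and run[2] >= r.min_adjacent_run)(
                    _adjacent_operon_run(l, r)
                ),
            ),
            _Motif(
                "abyT_after_operon_or_abyM_in_ABC",
                True,
                lambda l, r: _t_after_run(l, r) or _m_interrupts_abc(l, r),
            ),
            _Motif("abyT_after_operon", False, _t_after_run),
            _Motif("abyM_interrupts_ABC", False, _m_interrupts_abc),
            _Motif(
                "full_operon_run",
                False,
                lambda l, r: (lambda run: run is not None and run[2] == 5)(
                    _adjacent_operon_run(l, r)
                ),
            ),
        ],
        "4": [
            _Motif("zaa_upstream_of_pks_operon", True, _zaa_before_anchor),
            _Motif("anchor_inside_pks_operon", True, _anchor_flanked_by_pks),
            _Motif(
                "abyA1_inside_pks_operon",
                False,
                lambda l, r: _label_flanked_by_pks(l, "abyA1", r),
            ),
            _Motif(
                "abyZ_upstream", False, lambda l, r: (lambda a: bool(a) and "abyZ" in l.labels[: min(a)])(l.anchor_positions(l.labels))
            ),
            _Motif(
                "abyA3_upstream", False, lambda l, r: (lambda a: bool(a) and "abyA3" in l.labels[: min(a)])(l.anchor_positions(l.labels))
            ),
            _Motif(
                "abyA2_upstream", False, lambda l, r: (lambda a: bool(a) and "abyA2" in l.labels[: min(a)])(l.anchor_positions(l.labels))
            ),
        ],
    }


CLUSTER_TYPES = ("1a", "1b", "2a", "2b", "3", "4", "5")


def classify_syntype(
    candidate: ClusterCandidate | Sequence[str],
    rules: SyntenyRules | None = None,
) -> SyntenyTypeCall:
    """Synteny type of an abyssomicin(-candidate) cluster.

    Accepts a delimited candidate or a bare orientation-normalized label
    list.  A type is eligible when all its mandatory motifs hold; among
    eligible types the highest motif score (fraction of all the type's
    motifs satisfied) wins, ties to the lower type number.  Type 5 is the
    fallback: no other type's mandatory motifs are all satisfied.
    """
    rules = rules or SyntenyRules()
    labels = candidate.labels if isinstance(candidate, ClusterCandidate) else list(candidate)
    lay = _Layout(labels)
    best: tuple[float, str, tuple[str, ...]] | None = None
    for ctype, motifs in _type_motifs(rules).items():
        results = [(m.name, m.check(lay, rules)) for m in motifs]
        if not all(ok for (name, ok), m in zip(results, motifs) if m.mandatory):
            continue
        matched = tuple(name for name, ok in results if ok)
        score = len(matched) / len(motifs)
        if best is None or score > best[0] + 1e-12:
            best = (score, ctype, matched)
    if best is None:
        return SyntenyTypeCall("5", (), 0.0)
    return SyntenyTypeCall(best[1], best[2], best[0])


def mandatory_motifs_satisfied(labels: Sequence[str], rules: SyntenyRules | None = None) -> dict[str, bool]:
    """Per-type flag: are all mandatory motifs satisfied on this layout?"""
    rules = rules or SyntenyRules()
    lay = _Layout(list(labels))
    out: dict[str, bool] = {}
    for ctype, motifs in _type_motifs(rules).items():
        out[ctype] = all(m.check(lay, rules) for m in motifs if m.mandatory)
    return out


# ---------------------------------------------------------------------------
# mobile-element proximity


def flag_mobile_elements(
    genome: Genome,
    candidate: ClusterCandidate,
    flank_labels: Sequence[LabeledGene],
    window_bp: int = 10_000,
) -> MobileFlag:
    """Mobile-element (transposase/integrase) proximity verdict.

    ``flank_labels`` must cover the labeled neighborhood (candidate genes
    plus flanks).  Priority: inside the candidate span, else within
    ``window_bp`` of the span, else -- for anchor-only candidates --
    within ``window_bp`` of the anchor gene, else none.
    """
    mobile = [
        lg
        for lg in flank_labels
        if lg.label in ("transposase", "integrase") and lg.gene.contig_id == candidate.contig_id
    ]
    if not mobile:
        return MobileFlag("none", ())
    lo, hi = candidate.span
    inside = [lg for lg in mobile if lg.gene.start < hi and lg.gene.end > lo]
    if inside:
        return MobileFlag("inside_bgc", tuple((lg.gene.gene_id, lg.label) for lg in inside))
    near = [
        lg
        for lg in mobile
        if lg.gene.end > lo - window_bp and lg.gene.start < hi + window_bp
    ]
    if near:
        # an anchor-only candidate has no cluster to speak of: proximity to
        # its span is proximity to the Diels-Alderase gene itself
        location = "near_anchor" if len(candidate.genes) == 1 else "near_bgc"
        return MobileFlag(location, tuple((lg.gene.gene_id, lg.label) for lg in near))
    return MobileFlag("none", ())
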