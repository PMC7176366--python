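"""Anchor-enzyme homology screening.

The discovery step of the pipeline: every searchable protein is compared
against the three Diels-Alderase anchor queries (AbyU, AbsU, AbmU) with an
exact affine-gap Smith-Waterman alignment, raw scores are converted to bit
scores with fixed gapped-BLOSUM62 Karlin-Altschul constants, and proteins
whose best anchor alignment clears the E-value screen (< 1e-6 by default)
become anchor hits that seed cluster delimitation downstream.

Exact BLAST parity is deliberately not attempted: the constants
(lambda = 0.267, K = 0.041) are the standard gapped-BLOSUM62 calibration
and the effective search space is the raw product m*n, so thresholds are
interpretable and monotone in the raw score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from . import _kernels
from .seq_io import SequenceRecord

RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_X_INDEX = 20
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}
_RESIDUE_INDEX["X"] = _X_INDEX

#: Anchor preference order used to break bit-score ties between anchors.
ANCHOR_ORDER = ("AbyU", "AbsU", "AbmU")


class AlignmentError(ValueError):
    pass


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense (21, 21) int64 array; X scores 0 vs everything."""
    bl = substitution_matrices.load("BLOSUM62")
    S = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(RESIDUE_ORDER):
        for j, b in enumerate(RESIDUE_ORDER):
            S[i, j] = int(bl[a][b])
    return S


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value calibration.

    Defaults mirror protein-BLAST defaults: BLOSUM62, gap open 11, gap
    extend 1, with the standard gapped calibration lambda = 0.267 and
    K = 0.041.
    """

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError("lambda must be finite and positive")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError("K must be finite and positive")
        if self.matrix.shape != (21, 21) or not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric over the 21-letter alphabet")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def default_scheme() -> ScoringScheme:
    return ScoringScheme()


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as kernel indices (X -> 20)."""
    try:
        return np.array([_RESIDUE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise AlignmentError(f"non-amino-acid residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment, in BLAST-style units."""

    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float
    query_coverage: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


def evalue(bit_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expectation E = m * n * 2**(-bit_score).

    ``m`` is the query length and ``n`` the total residue count of the
    searched collection; no length correction is applied.
    """
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m) * float(n) * math.pow(2.0, -bit_score)


def align_local(
    query: SequenceRecord,
    target: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> AlignmentResult:
    """Exact Smith-Waterman local alignment with affine gaps.

    Deterministic traceback with tie-break diagonal > up > left.  The
    reported E-value uses the single-target search space m * n; screening
    functions recompute it against their full target set.
    """
    scheme = scheme or default_scheme()
    if not query.residues or not target.residues:
        raise AlignmentError("cannot align empty sequences")
    q = encode_protein(query.residues)
    t = encode_protein(target.residues)
    raw, qs, qe, ts, te, matches, columns = _kernels.sw_align(
        q, t, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    raw = int(raw)
    bit = scheme.bit_score(raw)
    identity = matches / columns if columns else 0.0
    coverage = (qe - qs) / len(q)
    return AlignmentResult(
        raw_score=raw,
        bit_score=bit,
        evalue=evalue(bit, len(q), len(t)),
        identity_fraction=identity,
        query_coverage=coverage,
        query_span=(int(qs), int(qe)),
        target_span=(int(ts), int(te)),
    )


def raw_local_score(
    query: SequenceRecord, target: SequenceRecord, scheme: ScoringScheme | None = None
) -> int:
    """Score-only Smith-Waterman (no traceback); used for bulk screening."""
    scheme = scheme or default_scheme()
    q = encode_protein(query.residues)
    t = encode_protein(target.residues)
    return int(_kernels.sw_score(q, t, scheme.matrix, scheme.gap_open, scheme.gap_extend))


@dataclass(frozen=True)
class AnchorHit:
    """One protein passing the Diels-Alderase anchor screen."""

    genome_id: str | None
    protein_id: str
    anchor_query: str
    result: AlignmentResult


def _anchor_rank(anchor_id: str) -> int:
    try:
        return ANCHOR_ORDER.index(anchor_id)
    except ValueError:
        return len(ANCHOR_ORDER)


def find_anchor_hits(
    proteins: Iterable[SequenceRecord],
    anchors: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-6,
    genome_id: str | None = None,
) -> list[AnchorHit]:
    """Screen a protein collection against the anchor queries.

    Each protein reports at most one hit: its best-scoring anchor
    (ties broken by the fixed anchor order AbyU, AbsU, AbmU), kept only
    when the E-value over the whole searched set (n = summed length of
    the protein collection) is below ``evalue_max``.  A genome with
    several passing proteins yields several hits (paralogs are carried
    forward independently).
    """
    scheme = scheme or default_scheme()
    if not anchors:
        raise ValueError("anchor set must be non-empty")
    proteins = list(proteins)
    if not proteins:
        return []
    n_total = sum(len(p) for p in proteins)
    anchor_codes = [(a, encode_protein(a.residues)) for a in anchors]
    hits: list[AnchorHit] = []
    for protein in proteins:
        t = encode_protein(protein.residues)
        best: tuple[int, int, SequenceRecord] | None = None
        for anchor, q in anchor_codes:
            raw = int(_kernels.sw_score(q, t, scheme.matrix, scheme.gap_open, scheme.gap_extend))
            key = (-raw, _anchor_rank(anchor.id))
            if best is None or key < best[:2]:
                best = (key[0], key[1], anchor)
        assert best is not None
        anchor = best[2]
        res = align_local(anchor, protein, scheme)
        e = evalue(res.bit_score, len(anchor), n_total)
        if e < evalue_max:
            hits.append(
                AnchorHit(
                    genome_id=genome_id,
                    protein_id=protein.id,
                    anchor_query=anchor.id,
                    result=AlignmentResult(
                        raw_score=res.raw_score,
                        bit_score=res.bit_score,
                        evalue=e,
                        identity_fraction=res.identity_fraction,
                        query_coverage=res.query_coverage,
                        query_span=res.query_span,
                        target_span=res.target_span,
                    ),
                )
            )
    return hits


def hits_table(hits: Iterable[AnchorHit]) -> pd.DataFrame:
    """Anchor hits as the TSV-ready table written by the pipeline."""
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "protein_id": h.protein_id,
                "anchor": h.anchor_query,
                "bit_score": round(h.result.bit_score, 2),
                "evalue": h.result.evalue,
                "identity": round(h.result.identity_fraction, 4),
                "coverage": round(h.result.query_coverage, 4),
            }
            for h in hits
        ],
        columns=["genome_id", "protein_id", "anchor", "bit_score", "evalue", "identity", "coverage"],
    )
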