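"""Sequence and gene-model containers shared by every mining stage.

The in-memory model mirrors what anchor-directed cluster mining actually
needs: per-genome ordered, stranded gene models on contigs, a protein per
gene where the annotation provides one, and contig *lengths* only (whole
nucleotide contigs are never stored).  All internal coordinates are 0-based
half-open; conversion from GFF3's 1-based inclusive convention happens at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_ALPHABETS = {"protein": PROTEIN_ALPHABET, "nucleotide": NUCLEOTIDE_ALPHABET}

#: Columns of the documented TSV feature dialect (0-based half-open coords).
TSV_FEATURE_COLUMNS = ("gene_id", "contig_id", "start", "end", "strand", "protein_id")
_TSV_FLAG_COLUMNS = ("left_truncated", "right_truncated", "internal_stop")


class SeqIOError(ValueError):
    """Malformed sequence or feature input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record with empty id")
        if not self.residues:
            raise SeqIOError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PartialFlags:
    """Assembly-integrity flags attached to a gene model.

    These are annotation-driven (truncation at a contig break, internal
    stop from a frameshift); nothing here inspects nucleotide sequence.
    """

    left_truncated: bool = False
    right_truncated: bool = False
    internal_stop: bool = False

    def any(self) -> bool:
        return self.left_truncated or self.right_truncated or self.internal_stop


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    partial_flags: PartialFlags = field(default_factory=PartialFlags)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Gene models + linked proteins for one genome (or genome bin).

    Metagenome protein collections without gene models are handled
    upstream as bare ``SequenceRecord`` sets and never become Genomes.
    """

    genome_id: str
    contigs: dict[str, int] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)
    proteins: dict[str, SequenceRecord] = field(default_factory=dict)
    taxonomy: tuple[str, str] = ("", "")
    habitat: str | None = None

    def validate(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise SeqIOError(f"duplicate gene id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            if gene.contig_id not in self.contigs:
                raise SeqIOError(
                    f"gene {gene.gene_id!r} references unknown contig {gene.contig_id!r}"
                )
            if gene.end > self.contigs[gene.contig_id]:
                raise SeqIOError(
                    f"gene {gene.gene_id!r} extends past the end of {gene.contig_id!r}"
                )

    def genes_on(self, contig_id: str) -> list[Gene]:
        """Genes of one contig sorted by start (ties broken by gene_id)."""
        return sorted(
            (g for g in self.genes if g.contig_id == contig_id),
            key=lambda g: (g.start, g.gene_id),
        )

    def protein_of(self, gene: Gene) -> SequenceRecord | None:
        if gene.protein_id is None:
            return None
        return self.proteins.get(gene.protein_id)

    def is_searchable(self, gene: Gene) -> bool:
        """A gene is searchable when its protein sequence resolved."""
        return self.protein_of(gene) is not None

    def unsearchable_genes(self) -> list[Gene]:
        return [g for g in self.genes if not self.is_searchable(g)]


def _validate_residues(record_id: str, residues: str, alphabet: str, path: Path) -> str:
    allowed = _ALPHABETS[alphabet]
    upper = residues.upper()
    bad = next((c for c in upper if c not in allowed), None)
    if bad is not None:
        line_no = _line_of_char(path, record_id, bad)
        raise SeqIOError(
            f"{path}: illegal {alphabet} character {bad!r} in record "
            f"{record_id!r} (line {line_no})"
        )
    return upper


def _line_of_char(path: Path, record_id: str, char: str) -> int:
    """Locate the offending residue line for an error message."""
    in_record = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and char in line.upper():
                return i
    return -1


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-FASTA file.

    Parameters
    ----------
    path:
        FASTA file; an empty file yields an empty list.
    alphabet:
        ``"protein"`` (IUPAC amino acids plus X) or ``"nucleotide"`` (ACGTN);
        case-insensitive, residues are upper-cased on read.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _validate_residues(rec.id, str(rec.seq), alphabet, path)
        records.append(SequenceRecord(rec.id, rec.description, residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=_strip_id(r.description, r.id))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _strip_id(description: str, rec_id: str) -> str:
    # Biopython joins "id description"; avoid doubling the id on round-trip.
    if description == rec_id:
        return ""
    if description.startswith(rec_id + " "):
        return description[len(rec_id) + 1 :]
    return description


_TRUTHY = {"1", "true", "yes"}


def _parse_gff3_attributes(field9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field9.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _flags_from_attrs(attrs: Mapping[str, str]) -> PartialFlags:
    return PartialFlags(
        left_truncated=attrs.get("left_truncated", "").lower() in _TRUTHY,
        right_truncated=attrs.get("right_truncated", "").lower() in _TRUTHY,
        internal_stop=attrs.get("internal_stop", "").lower() in _TRUTHY,
    )


def _read_gff3(path: Path, genome_id: str) -> Genome:
    contigs: dict[str, int] = {}
    pragma_contigs: set[str] = set()
    genes: list[Gene] = []
    n_anon = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contigs[parts[1]] = int(parts[3])
                    pragma_contigs.add(parts[1])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqIOError(f"{path}:{line_no}: expected 9 tab-separated columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in ("CDS", "gene"):
                continue
            start_1, end_1 = int(start_s), int(end_s)
            if end_1 < start_1:
                raise SeqIOError(f"{path}:{line_no}: end < start ({end_1} < {start_1})")
            if strand not in ("+", "-"):
                raise SeqIOError(f"{path}:{line_no}: unknown strand symbol {strand!r}")
            attrs = _parse_gff3_attributes(attr_s)
            gene_id = attrs.get("ID")
            if gene_id is None:
                n_anon += 1
                gene_id = f"{seqid}_feature{n_anon}"
            genes.append(
                Gene(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=start_1 - 1,  # GFF3 is 1-based inclusive
                    end=end_1,
                    strand=strand,
                    protein_id=attrs.get("protein_id", attrs.get("ID")),
                    partial_flags=_flags_from_attrs(attrs),
                )
            )
    for gene in genes:
        if gene.contig_id not in pragma_contigs:
            contigs[gene.contig_id] = max(contigs.get(gene.contig_id, 0), gene.end)
    genome = Genome(genome_id=genome_id, contigs=contigs, genes=genes)
    genome.validate()
    return genome


def _read_feature_tsv(path: Path, genome_id: str) -> Genome:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SeqIOError(f"{path}: missing feature columns {missing}")
    genes: list[Gene] = []
    for row in table.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise SeqIOError(f"{path}: gene {row.gene_id!r}: end < start")
        if row.strand not in ("+", "-"):
            raise SeqIOError(f"{path}: gene {row.gene_id!r}: unknown strand {row.strand!r}")
        flag_values = {
            name: str(getattr(row, name, "")).lower() in _TRUTHY
            for name in _TSV_FLAG_COLUMNS
        }
        protein_id = None if pd.isna(row.protein_id) else str(row.protein_id)
        genes.append(
            Gene(
                gene_id=str(row.gene_id),
                contig_id=str(row.contig_id),
                start=start,
                end=end,
                strand=str(row.strand),
                protein_id=protein_id,
                partial_flags=PartialFlags(**flag_values),
            )
        )
    contigs: dict[str, int] = {}
    for gene in genes:
        contigs[gene.contig_id] = max(contigs.get(gene.contig_id, 0), gene.end)
    genome = Genome(genome_id=genome_id, contigs=contigs, genes=genes)
    genome.validate()
    return genome


def read_features(path: str | Path, dialect: str = "gff3", genome_id: str | None = None) -> Genome:
    """Read gene models into a :class:`Genome` (genes + contig lengths only).

    GFF3 rows of type CDS or gene become genes; coordinates are converted
    to 0-based half-open.  Contig lengths come from ``##sequence-region``
    pragmas where present, otherwise ``max(end)`` per contig.  The TSV
    dialect is already 0-based half-open and is taken verbatim.
    """
    path = Path(path)
    genome_id = genome_id if genome_id is not None else path.stem
    if dialect == "gff3":
        return _read_gff3(path, genome_id)
    if dialect == "tsv":
        return _read_feature_tsv(path, genome_id)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def write_features_tsv(genome: Genome, path: str | Path) -> None:
    rows = []
    for g in genome.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "protein_id": "" if g.protein_id is None else g.protein_id,
                "left_truncated": int(g.partial_flags.left_truncated),
                "right_truncated": int(g.partial_flags.right_truncated),
                "internal_stop": int(g.partial_flags.internal_stop),
            }
        )
    pd.DataFrame(rows, columns=TSV_FEATURE_COLUMNS + _TSV_FLAG_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def attach_proteins(genome: Genome, proteins: Iterable[SequenceRecord]) -> Genome:
    """Link protein sequences to a genome's gene models by protein_id.

    Genes whose protein is absent from the supplied set stay in the genome
    but are unsearchable (``Genome.is_searchable``); missing links are
    flags, never errors.
    """
    pool = {p.id: p for p in proteins}
    linked = {
        g.protein_id: pool[g.protein_id]
        for g in genome.genes
        if g.protein_id is not None and g.protein_id in pool
    }
    genome.proteins = {**genome.proteins, **linked}
    return genome


def gff3_lines(genome: Genome) -> list[str]:
    """Serialize gene models back to GFF3 (coordinate round-trip exact)."""
    lines = [f"##gff-version 3"]
    for contig_id, length in genome.contigs.items():
        lines.append(f"##sequence-region {contig_id} 1 {length}")
    for g in genome.genes:
        attrs = [f"ID={g.gene_id}"]
        if g.protein_id is not None and g.protein_id != g.gene_id:
            attrs.append(f"protein_id={g.protein_id}")
        for name in _TSV_FLAG_COLUMNS:
            if getattr(g.partial_flags, name):
                attrs.append(f"{name}=1")
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "abyssminer",
                    "CDS",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    return lines
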