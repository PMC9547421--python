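"""Standard-format readers/writers and chromosome bookkeeping.

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts at
the boundary and user-facing reports print 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

HOMOEOLOGOUS_GROUPS = ("1", "2", "3", "4", "5", "6", "7", "Un")
_CHROM_RE = re.compile(r"^([1-7])([ABD])$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence record (protein or nucleotide, uppercased)."""

    id: str
    sequence: str
    source_note: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with 0-based half-open coordinates."""

    gene_id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.chromosome:
            raise FormatError(f"gene {self.gene_id}: empty chromosome label")


def read_fasta(path: str | Path, alphabet: frozenset[str] = PROTEIN_ALPHABET) -> list[ProteinRecord]:
    """Read a FASTA file into validated, uppercased records.

    Raises :class:`FormatError` on an empty file, duplicate ids, or
    characters outside *alphabet* (naming the offending position).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id} has an empty sequence")
        for i, ch in enumerate(seq):
            if ch not in alphabet:
                raise FormatError(
                    f"record {rec.id}: invalid character {ch!r} at position {i}"
                )
        records.append(ProteinRecord(rec.id, seq, source_note=rec.description))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only features of type ``gene`` are returned; coordinates are converted
    from GFF3 1-based inclusive to 0-based half-open.  A gene without an
    ``ID`` attribute, or with start > end, is an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids or not ids[0]:
            raise FormatError(f"gene feature at {feat.seqid}:{feat.start} lacks an ID")
        if feat.start > feat.end:
            raise FormatError(f"gene {ids[0]}: start > end in GFF3")
        genes.append(
            GeneModel(
                gene_id=ids[0],
                chromosome=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
        )
    return genes


def homoeologous_group(chromosome: str) -> str:
    """Map a wheat chromosome label (e.g. ``3B``) to its group ``1``–``7``.

    Labels that do not parse as group-number + A/B/D subgenome letter are
    assigned to ``Un`` (unanchored), with a logged warning for labels that
    are not literally "Un".
    """
    m = _CHROM_RE.match(chromosome)
    if m:
        return m.group(1)
    if chromosome != "Un":
        logger.warning("unparseable chromosome label %r assigned to Un", chromosome)
    return "Un"


def chromosome_distribution(
    genes: Sequence[GeneModel], grouping: str = "by_homoeologous_group"
) -> dict[str, int]:
    """Ordered gene counts per chromosome or per homoeologous group.

    Under ``by_homoeologous_group`` the table always carries keys 1..7 then
    Un; counts sum to ``len(genes)``.
    """
    if grouping == "by_homoeologous_group":
        counts = {g: 0 for g in HOMOEOLOGOUS_GROUPS}
        for gene in genes:
            counts[homoeologous_group(gene.chromosome)] += 1
        return counts
    if grouping == "by_chromosome":
        counts = {}
        for gene in sorted(genes, key=lambda g: g.chromosome):
            counts[gene.chromosome] = counts.get(gene.chromosome, 0) + 1
        return counts
    raise ValueError(f"unknown grouping {grouping!r}")


def read_genome_fasta(path: str | Path) -> Mapping[str, str]:
    """Read a genome/contig FASTA into a name -> uppercase sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate contig id: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs
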