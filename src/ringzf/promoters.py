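"""Promoter extraction and IUPAC cis-regulatory element censusing.

Promoter windows are the 1.5 kb immediately upstream of the annotated gene
start (strand-aware, clipped at contig edges with a flag).  Motifs are
IUPAC nucleotide patterns scanned on both strands at every position; all
overlapping occurrences are reported, and a palindromic motif yields one
hit per strand at the same locus.  ``N`` in a sequence matches nothing.

The default motif table carries PLACE/PlantCARE-style patterns for the
elements commonly censused in plant promoter surveys (ABRE, DRE, MBS, LTR,
G-box, ARE, Sp1, TC-rich, WUN-motif, RY-element, TGA-element).  It is
curated, editable input - not an authoritative reproduction of any
database entry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domains import census_percentage
from .io import GeneModel, ProteinRecord

IUPAC_CODES: dict = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MOTIF_CATEGORIES = ("stress", "hormone", "development", "light", "other")


@dataclass(frozen=True)
class Motif:
    """A named IUPAC pattern with a functional category."""

    name: str
    category: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        for ch in self.pattern:
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"motif {self.name}: invalid IUPAC code {ch!r}"
                )
        if self.category not in MOTIF_CATEGORIES:
            raise ValueError(f"motif {self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class MotifHit:
    """One occurrence: 0-based start on the forward coordinate system."""

    gene: str
    motif: str
    start: int
    strand: str


@dataclass(frozen=True)
class PromoterRecord:
    """An extracted upstream window (already strand-oriented 5'->3')."""

    gene_id: str
    sequence: str
    truncated: bool
    requested_length: int


_DEFAULT_MOTIFS = [
    ("ABRE", "hormone", "ACGTG"),
    ("TGA-element", "hormone", "AACGAC"),
    ("DRE", "stress", "RCCGAC"),
    ("MBS", "stress", "CAACTG"),
    ("LTR", "stress", "CCGAAA"),
    ("ARE", "stress", "AAACCA"),
    ("TC-rich", "stress", "ATTTTCTTCA"),
    ("WUN-motif", "stress", "AAATTTCCT"),
    ("RY-element", "development", "CATGCATG"),
    ("G-box", "light", "CACGTG"),
    ("Sp1", "light", "GGGCGG"),
]


def default_motif_table() -> list:
    return [Motif(n, c, p) for n, c, p in _DEFAULT_MOTIFS]


def load_motif_table(path: str | Path) -> list:
    """Load motifs from JSON: ``[{"name":..., "category":..., "pattern":...}]``.

    Pattern validation (IUPAC codes, duplicate names) happens here, at
    table-load time.
    """
    with open(path) as fh:
        raw = json.load(fh)
    motifs = [Motif(e["name"], e["category"], e["pattern"].upper()) for e in raw]
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in table")
    return motifs


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    # overlapping occurrences via lookahead; N in the *sequence* can never
    # match because classes are built over ACGT only
    body = "".join(
        IUPAC_CODES[c] if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in pattern
    )
    return re.compile("(?=" + body + ")")


def scan_motifs(promoter: ProteinRecord, table: Sequence[Motif]) -> list:
    """All occurrences of every motif on both strands of one promoter.

    Minus-strand occurrences are found by scanning the forward sequence
    with the reverse-complemented pattern; their ``start`` is the leftmost
    forward-strand coordinate of the occurrence.
    """
    seq = promoter.sequence.upper()
    hits: list = []
    for motif in table:
        for m in _iupac_regex(motif.pattern).finditer(seq):
            hits.append(MotifHit(promoter.id, motif.name, m.start(), "+"))
        for m in _iupac_regex(reverse_complement(motif.pattern)).finditer(seq):
            hits.append(MotifHit(promoter.id, motif.name, m.start(), "-"))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def extract_upstream(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    length: int = 1500,
) -> list:
    """Strand-aware upstream windows of *length* bp before each gene start.

    Plus strand: ``[start - length, start)``; minus strand: ``[end,
    end + length)`` reverse-complemented.  Windows are clipped at contig
    edges and flagged ``truncated``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    out = []
    for gene in genes:
        if gene.chromosome not in genome:
            raise KeyError(
                f"gene {gene.gene_id}: chromosome {gene.chromosome!r} absent "
                "from genome"
            )
        contig = genome[gene.chromosome]
        if gene.strand == "+":
            lo = max(0, gene.start - length)
            window = contig[lo : gene.start]
            truncated = gene.start - length < 0
        else:
            hi = min(len(contig), gene.end + length)
            window = _rc(contig[gene.end : hi])
            truncated = gene.end + length > len(contig)
        out.append(
            PromoterRecord(gene.gene_id, window, truncated, length)
        )
    return out


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class PromoterCensus:
    """Family-level element census.

    ``per_motif`` columns: motif, category, genes_with_hit, pct_genes
    (half-up, one decimal), occurrences.  Percentages use the number of
    genes surveyed as denominator; presence is per gene regardless of
    strand or multiplicity.
    """

    per_motif: pd.DataFrame
    category_totals: dict
    n_genes: int
    n_types_present: int
    n_occurrences: int


def element_census(
    hits: Iterable[MotifHit], n_genes: int, table: Sequence[Motif]
) -> PromoterCensus:
    """Presence and occurrence census over all genes' hits."""
    hits = list(hits)
    genes_with: dict = {m.name: set() for m in table}
    occurrences: dict = {m.name: 0 for m in table}
    for h in hits:
        if h.motif in genes_with:
            genes_with[h.motif].add(h.gene)
            occurrences[h.motif] += 1
    rows = []
    category_totals: dict = {}
    for m in table:
        count = len(genes_with[m.name])
        rows.append(
            {
                "motif": m.name,
                "category": m.category,
                "genes_with_hit": count,
                "pct_genes": census_percentage(count, n_genes) if n_genes else 0.0,
                "occurrences": occurrences[m.name],
            }
        )
        category_totals[m.category] = (
            category_totals.get(m.category, 0) + occurrences[m.name]
        )
    frame = pd.DataFrame(rows)
    return PromoterCensus(
        per_motif=frame,
        category_totals=category_totals,
        n_genes=n_genes,
        n_types_present=int((frame["occurrences"] > 0).sum()),
        n_occurrences=int(frame["occurrences"].sum()),
    )
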