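"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators are pure functions of their arguments (including ``seed``), so
reruns are byte-identical.  Planted domains are embedded in a ligand-free
filler alphabet (no C, H, M, R, D or W) so the planted spans are provably
the only rule matches; promoter backgrounds are drawn from {A, T} so that
no default motif can be spelled outside planted loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import promoters as _promoters
from .domains import LigandRule, default_rule_table
from .io import ProteinRecord
from .molevol import (
    GENETIC_CODE,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    CodingPair,
)

# Residues that can never satisfy a ligand slot of any default rule and are
# common enough to be plausible filler.
FILLER_ALPHABET = "AGLSTVPEQN"

# Wheat developmental-stage and stress-treatment panels used as default
# column labels (seedling/root/stem/leaf/spike/grain stages; drought, heat
# and combined stress at 1 h and 6 h, plus an untreated control).
DEFAULT_STAGES = (
    "SR", "RTLS", "RMS", "S1S", "STNS", "SATS", "SL", "LTTS", "L2DAAs",
    "SPTNS", "SPMS", "SPAS", "G2DAAs", "G14DAAs", "G30DAAs",
)
DEFAULT_TREATMENTS = ("D1h", "D6h", "H1h", "H6h", "DH1h", "DH6h")
DEFAULT_CONTROL = "CK"

DEFAULT_LEVELS = {
    "high_tpm": 50.0,
    "low_tpm": 0.2,
    "induced_tpm": 40.0,
    "basal_tpm": 5.0,
}

# Planted domains (and domains within one protein) are separated by at
# least this much filler: larger than any rule spacer (max 48), so no
# ligand assignment can bridge two planted domains or a domain and flank.
MIN_DOMAIN_GAP = 60


@dataclass(frozen=True)
class PlantedDomain:
    protein_id: str
    subtype: str
    span: tuple
    ligand_positions: tuple


@dataclass(frozen=True)
class PlantedSubstitutions:
    pair_id: str
    n_syn: int
    n_nonsyn: int


@dataclass(frozen=True)
class PlantedMotif:
    gene: str
    motif: str
    start: int
    strand: str


@dataclass
class TruthTable:
    """Everything the generators planted, keyed to emitted records."""

    planted_domains: list = field(default_factory=list)
    planted_substitutions: list = field(default_factory=list)
    planted_motifs: list = field(default_factory=list)
    planted_groups: dict = field(default_factory=dict)
    planted_fold_changes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Proteins with planted RING domains

def _rule_for_subtype(subtype: str, rule_table) -> LigandRule:
    name = "RING-HC" if subtype in ("RING-HCa", "RING-HCb") else subtype
    for rule in rule_table:
        if rule.name == name and not rule.accessory:
            return rule
    for rule in rule_table:
        if rule.name == name:
            return rule
    raise ValueError(f"unknown subtype {subtype!r}")

# HCa/HCb side constraints on the X(4-48) spacer (index 5) under the
# default split criterion (HCa iff >= 8).
_HC_SIDE_RANGES = {"RING-HCa": (8, 48), "RING-HCb": (4, 7)}


def _sample_spacers(subtype: str, rule: LigandRule, spacers, rng) -> tuple:
    ranges = [slot.spacer for slot in rule.slots[:-1]]
    if subtype in _HC_SIDE_RANGES:
        ranges[5] = _HC_SIDE_RANGES[subtype]
    if spacers == "sample":
        return tuple(int(rng.integers(lo, hi + 1)) for lo, hi in ranges)
    spacers = tuple(int(s) for s in spacers)
    if len(spacers) != len(ranges):
        raise ValueError(f"expected {len(ranges)} spacers, got {len(spacers)}")
    for s, (lo, hi) in zip(spacers, ranges):
        if not lo <= s <= hi:
            raise ValueError(f"spacer {s} outside rule range [{lo}, {hi}]")
    return spacers


def _filler(n: int, rng) -> str:
    return "".join(rng.choice(list(FILLER_ALPHABET), size=n)) if n else ""


def _build_domain(subtype: str, rule: LigandRule, spacers: tuple, rng) -> tuple:
    """Return (domain string, relative ligand positions)."""
    parts = []
    positions = []
    pos = 0
    for i, slot in enumerate(rule.slots):
        res = sorted(slot.allowed)[int(rng.integers(len(slot.allowed)))]
        parts.append(res)
        positions.append(pos)
        pos += 1
        if i < len(rule.slots) - 1:
            parts.append(_filler(spacers[i], rng))
            pos += spacers[i]
    return "".join(parts), tuple(positions)


def make_ring_protein(
    subtype: str,
    spacers="sample",
    flank_lengths: tuple = (15, 15),
    seed: int = 0,
    rule_table=None,
    protein_id: str = "RZF0001",
):
    """One protein carrying exactly one planted domain of *subtype*.

    ``spacers`` is either ``"sample"`` or an explicit 7-tuple (8-tuple for
    IBR) within the rule's ranges.  Flanks and spacer filler are drawn from
    the ligand-free alphabet, so the planted span is the only rule match.
    """
    rng = np.random.default_rng(seed)
    table = rule_table if rule_table is not None else default_rule_table()
    rule = _rule_for_subtype(subtype, table)
    spc = _sample_spacers(subtype, rule, spacers, rng)
    domain, rel_pos = _build_domain(subtype, rule, spc, rng)
    left = _filler(flank_lengths[0], rng)
    right = _filler(flank_lengths[1], rng)
    seq = left + domain + right
    positions = tuple(p + len(left) for p in rel_pos)
    truth = PlantedDomain(
        protein_id=protein_id,
        subtype=subtype,
        span=(positions[0], positions[-1] + 1),
        ligand_positions=positions,
    )
    return ProteinRecord(protein_id, seq), truth


def make_multi_domain_protein(
    subtypes, seed: int = 0, rule_table=None, protein_id: str = "RZFMD01",
):
    """One protein with several planted domains, separated by >= 60 filler."""
    rng = np.random.default_rng(seed)
    table = rule_table if rule_table is not None else default_rule_table()
    parts = [_filler(15, rng)]
    pos = 15
    truths = []
    for subtype in subtypes:
        rule = _rule_for_subtype(subtype, table)
        spc = _sample_spacers(subtype, rule, "sample", rng)
        domain, rel = _build_domain(subtype, rule, spc, rng)
        parts.append(domain)
        positions = tuple(p + pos for p in rel)
        truths.append(
            PlantedDomain(protein_id, subtype,
                          (positions[0], positions[-1] + 1), positions)
        )
        pos += len(domain)
        gap = MIN_DOMAIN_GAP + int(rng.integers(0, 20))
        parts.append(_filler(gap, rng))
        pos += gap
    return ProteinRecord(protein_id, "".join(parts)), truths


def _make_decoy(rng, protein_id: str) -> ProteinRecord:
    """A protein with no rule match: ligand-free filler plus at most seven
    ligand-capable residues spaced too far apart for any spacer range."""
    length = int(rng.integers(100, 400))
    seq = list(_filler(length, rng))
    n_lig = int(rng.integers(0, 8))
    pos = int(rng.integers(0, 50))
    placed = 0
    while placed < n_lig and pos < length:
        seq[pos] = "C" if rng.integers(2) else "H"
        placed += 1
        pos += MIN_DOMAIN_GAP + int(rng.integers(0, 30))
    return ProteinRecord(protein_id, "".join(seq))


def make_protein_set(counts_per_subtype: dict, n_decoys: int = 0, seed: int = 0):
    """A FASTA-ready collection with planted subtype counts plus decoys.

    Returns ``(records, truth_table)``.  With zero noise the classifier
    must recover the truth table exactly.
    """
    if any(c < 0 for c in counts_per_subtype.values()) or n_decoys < 0:
        raise ValueError("counts must be nonnegative")
    root = np.random.default_rng(seed)
    records: list = []
    truth = TruthTable()
    idx = 0
    for subtype in sorted(counts_per_subtype):
        for _ in range(counts_per_subtype[subtype]):
            idx += 1
            sub_seed = int(root.integers(0, 2**31 - 1))
            rec, t = make_ring_protein(
                subtype, seed=sub_seed, protein_id=f"RZF{idx:04d}"
            )
            records.append(rec)
            truth.planted_domains.append(t)
    for d in range(n_decoys):
        records.append(_make_decoy(root, f"DEC{d + 1:04d}"))
    return records, truth


# ---------------------------------------------------------------------------
# Codon pairs with controlled divergence

def _neighbors(codon: str):
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1 :]


def _synonymous_neighbors(codon: str):
    return [c for _, c in _neighbors(codon)
            if c not in STOP_CODONS and GENETIC_CODE[c] == GENETIC_CODE[codon]]


def _nonsynonymous_neighbors(codon: str):
    return [c for _, c in _neighbors(codon)
            if c not in STOP_CODONS and GENETIC_CODE[c] != GENETIC_CODE[codon]]


def make_codon_pair(
    n_codons: int, n_syn: int, n_nonsyn: int, seed: int = 0,
    id_a: str = "seqA", id_b: str = "seqB", max_retries: int = 100,
):
    """A codon-aligned pair differing by exactly ``n_syn`` synonymous and
    ``n_nonsyn`` nonsynonymous single-nucleotide changes, one per codon."""
    if n_syn + n_nonsyn > n_codons:
        raise ValueError("n_syn + n_nonsyn must not exceed n_codons")
    rng = np.random.default_rng(seed)
    codons_a = [SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                for _ in range(n_codons)]
    edit_idx = rng.permutation(n_codons)[: n_syn + n_nonsyn]
    codons_b = list(codons_a)
    for j, i in enumerate(edit_idx):
        want_syn = j < n_syn
        for attempt in range(max_retries):
            options = (_synonymous_neighbors(codons_a[i]) if want_syn
                       else _nonsynonymous_neighbors(codons_a[i]))
            if options:
                codons_b[i] = options[int(rng.integers(len(options)))]
                break
            codons_a[i] = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
        else:
            raise RuntimeError("could not draw an editable codon")
    pair = CodingPair(id_a, id_b, "".join(codons_a), "".join(codons_b))
    return pair, PlantedSubstitutions(f"{id_a}|{id_b}", n_syn, n_nonsyn)


# ---------------------------------------------------------------------------
# Promoters with planted motifs

_IUPAC = _promoters.IUPAC_CODES


def _instantiate(pattern: str, rng) -> str:
    return "".join(
        sorted(_IUPAC[c])[int(rng.integers(len(_IUPAC[c])))] for c in pattern
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_promoter(
    length: int, plant, seed: int = 0, motif_table=None,
    gene_id: str = "gene1", max_attempts: int = 40,
):
    """A promoter of {A,T} background with planted motif occurrences.

    ``plant`` is a list of ``(motif_name, 0-based start, strand)``.  The
    generator verifies that every scanner hit of the active motif table
    falls inside a planted span, resampling the background a bounded number
    of times otherwise.
    """
    table = motif_table if motif_table is not None else _promoters.default_motif_table()
    by_name = {m.name: m for m in table}
    spans = []
    for name, start, strand in plant:
        if name not in by_name:
            raise ValueError(f"motif {name!r} not in the active table")
        w = len(by_name[name].pattern)
        if start < 0 or start + w > length:
            raise ValueError(f"planted {name} at {start} does not fit in {length}")
        spans.append((start, start + w))
    spans_sorted = sorted(spans)
    for (a, b), (c, _) in zip(spans_sorted, spans_sorted[1:]):
        if c < b:
            raise ValueError("planted occurrences overlap")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seq = list("".join(rng.choice(["A", "T"], size=length)))
        for (name, start, strand), (a, b) in zip(plant, spans):
            inst = _instantiate(by_name[name].pattern, rng)
            if strand == "-":
                inst = _revcomp(inst)
            seq[a:b] = inst
        seq_str = "".join(seq)
        hits = _promoters.scan_motifs(
            ProteinRecord(gene_id, seq_str), table
        )
        stray = [
            h for h in hits
            if not any(a <= h.start and h.start + len(by_name[h.motif].pattern) <= b
                       for a, b in spans)
        ]
        if not stray:
            truths = [PlantedMotif(gene_id, n, s, st) for n, s, st in plant]
            return ProteinRecord(gene_id, seq_str), truths
    raise RuntimeError(
        "could not draw a clean background; use a longer sequence or a "
        "smaller motif table"
    )


# ---------------------------------------------------------------------------
# Expression matrices and qPCR tables

def make_expression_matrix(
    n_per_group: dict,
    stages=DEFAULT_STAGES,
    treatments=DEFAULT_TREATMENTS,
    control: str = DEFAULT_CONTROL,
    levels: dict | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """TPM matrix with planted expression groups.

    Group1/Group2: constitutively high/low across developmental stages.
    Group3/Group4: induced/repressed under stress treatments relative to
    the control column.  Multiplicative lognormal noise with the given CV.
    Returns ``(frame, roles, truth_groups)`` where ``roles`` maps
    ``{"stages": [...], "treatments": [...], "control": name}``.
    """
    lv = dict(DEFAULT_LEVELS)
    if levels:
        lv.update(levels)
    if any(v < 0 for v in lv.values()):
        raise ValueError("expression levels must be nonnegative")
    rng = np.random.default_rng(seed)
    cols = list(stages) + [control] + list(treatments)
    base = {
        "Group1": {c: lv["high_tpm"] for c in cols},
        "Group2": {c: lv["low_tpm"] for c in cols},
        "Group3": {**{c: lv["basal_tpm"] for c in cols},
                   **{c: lv["induced_tpm"] for c in treatments}},
        "Group4": {**{c: lv["basal_tpm"] for c in cols},
                   control: lv["induced_tpm"]},
        "ungrouped": {c: 3.0 for c in cols},
    }
    rows, index, truth = [], [], {}
    gidx = 0
    for group in sorted(n_per_group):
        if group not in base:
            raise ValueError(f"unknown group {group!r}")
        for _ in range(n_per_group[group]):
            gidx += 1
            gid = f"G{gidx:04d}"
            index.append(gid)
            truth[gid] = group
            rows.append([base[group][c] for c in cols])
    frame = pd.DataFrame(rows, index=index, columns=cols, dtype=float)
    if noise_cv > 0 and len(frame):
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=frame.shape)
        frame = frame * noise
    roles = {"stages": list(stages), "treatments": list(treatments),
             "control": control}
    return frame, roles, truth


def make_qpcr_table(
    genes, conditions, true_fold: dict,
    ct_reference: float = 20.0, seed: int = 0,
    ct_target_control: float = 26.0, noise_sd: float = 0.0,
    control: str = "control",
):
    """CT table realizing known fold changes under the ddCt model.

    ``true_fold[(gene, condition)]`` > 0; the target CT under a condition is
    the control CT minus log2(fold), so a fold of 2 lowers CT by one cycle.
    Returns ``(frame, truth)`` with rows (gene, condition, ct_target,
    ct_reference) including a control row per gene.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for gene in genes:
        rows.append((gene, control, ct_target_control, ct_reference))
        for cond in conditions:
            fold = true_fold.get((gene, cond), 1.0)
            if fold <= 0:
                raise ValueError(f"nonpositive fold for {(gene, cond)}")
            ct = ct_target_control - math.log2(fold)
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            rows.append((gene, cond, ct, ct_reference))
            truth[(gene, cond)] = fold
    frame = pd.DataFrame(
        rows, columns=["gene", "condition", "ct_target", "ct_reference"]
    )
    return frame, truth
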