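"""Eight-ligand-slot rule engine for RING zinc-finger domain detection.

A RING domain coordinates two zinc ions through eight ordered metal-ligand
residues (mostly Cys/His).  Each subtype is encoded as a :class:`LigandRule`:
eight slots, each with an allowed residue set and an inclusive spacer range
to the next ligand.  The default table covers the canonical RING-H2
(C3H2C3) and RING-HC (C3HC4) consensus

    C-X2-C-X(9-39)-C-X(1-3)-H-X(2-3)-[C/H]-X2-C-X(4-48)-C-X2-C,

the Asp-modified RING-D, the wheat RING-M consensus

    M-X2-R-X14-C-X1-H-X2-C-X2-C-X10-C-X2-C,

and the nine-ligand IBR (C6HC) accessory domain
C-X4-C-X(14-30)-C-X(1-4)-C-X4-C-X2-C-X4-H-X4-C.

Matching semantics: candidate ligand assignments are anchored at every
possible first-ligand position; among assignments sharing a first-ligand
position the one with the lexicographically smallest spacer vector is kept.
Overlapping hits with different first-ligand positions are all reported.
``X`` in a sequence never satisfies a ligand slot.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .io import ProteinRecord

__all__ = [
    "LigandSlot",
    "LigandRule",
    "RingDomainHit",
    "SubtypeCensus",
    "HcSplitCriterion",
    "default_rule_table",
    "load_rule_table",
    "scan_rule",
    "scan_all",
    "split_hc",
    "classify_proteome",
    "census_percentage",
]


@dataclass(frozen=True)
class LigandSlot:
    """One metal-ligand position: allowed residues and the spacer range
    (inclusive) to the next ligand; the last slot has ``spacer=None``."""

    allowed: frozenset
    spacer: tuple | None = None

    def __post_init__(self):
        if not self.allowed:
            raise ValueError("ligand slot with empty allowed set")
        if self.spacer is not None:
            lo, hi = self.spacer
            if lo < 0 or lo > hi:
                raise ValueError(f"bad spacer range {self.spacer}")


@dataclass(frozen=True)
class LigandRule:
    """A subtype consensus: an ordered run of ligand slots.

    Core RING rules have exactly 8 slots; accessory rules (IBR) have 9.
    Lower ``priority`` is tried first when labels compete.
    """

    name: str
    priority: int
    slots: tuple
    accessory: bool = False

    def __post_init__(self):
        n = 9 if self.accessory else 8
        if len(self.slots) != n:
            raise ValueError(
                f"rule {self.name}: expected {n} slots, got {len(self.slots)}"
            )
        if self.slots[-1].spacer is not None:
            raise ValueError(f"rule {self.name}: last slot must have no spacer")
        if any(s.spacer is None for s in self.slots[:-1]):
            raise ValueError(f"rule {self.name}: interior slot missing spacer")

    @property
    def regex(self) -> re.Pattern:
        """Anchored pattern with lazy spacer quantifiers.

        Lazy quantifiers make the regex engine's first match the assignment
        with the lexicographically smallest spacer vector.
        """
        parts = []
        for slot in self.slots:
            parts.append("(" + "[" + "".join(sorted(slot.allowed)) + "])")
            if slot.spacer is not None:
                lo, hi = slot.spacer
                parts.append(".{%d,%d}?" % (lo, hi))
        return re.compile("".join(parts))


@dataclass(frozen=True)
class RingDomainHit:
    """One located domain: ligand positions, residues, spacers, subtype."""

    protein_id: str
    span: tuple  # 0-based half-open [first ligand, last ligand + 1)
    ligand_positions: tuple
    ligand_residues: tuple
    spacers: tuple
    subtype: str
    rule_name: str
    accessory: bool = False

    def satisfies(self, rule: LigandRule) -> bool:
        """Check every ligand/spacer constraint of *rule* (label soundness)."""
        if len(self.ligand_positions) != len(rule.slots):
            return False
        for res, slot in zip(self.ligand_residues, rule.slots):
            if res not in slot.allowed:
                return False
        for gap, slot in zip(self.spacers, rule.slots):
            lo, hi = slot.spacer
            if not lo <= gap <= hi:
                return False
        pos = self.ligand_positions
        return all(b > a for a, b in zip(pos, pos[1:]))


# ---------------------------------------------------------------------------
# Rule tables

_GENERIC_SPACERS = ((2, 2), (9, 39), (1, 3), (2, 3), (2, 2), (4, 48), (2, 2), None)
_RING_M_SPACERS = ((2, 2), (14, 14), (1, 1), (2, 2), (2, 2), (10, 10), (2, 2), None)
_IBR_SPACERS = ((4, 4), (14, 30), (1, 4), (4, 4), (2, 2), (4, 4), (4, 4), (4, 4), None)


def _rule(name, priority, ligands, spacers, accessory=False):
    slots = tuple(
        LigandSlot(frozenset(lig), sp) for lig, sp in zip(ligands, spacers)
    )
    return LigandRule(name, priority, slots, accessory)


def default_rule_table() -> list:
    """The default subtype rules in priority order.

    RING-M is tried first (its fixed spacing is the most specific), then the
    Asp-modified RING-D, then canonical RING-H2 and RING-HC.  The RING-D Asp
    position (ligand 5) is a configurable convention, not asserted biology.
    The accessory IBR rule never competes with core rules.
    """
    return [
        _rule("RING-M", 0, ["M", "R", "C", "H", "C", "C", "C", "C"], _RING_M_SPACERS),
        _rule("RING-D", 1, ["C", "C", "C", "H", "D", "C", "C", "C"], _GENERIC_SPACERS),
        _rule("RING-H2", 2, ["C", "C", "C", "H", "H", "C", "C", "C"], _GENERIC_SPACERS),
        _rule("RING-HC", 3, ["C", "C", "C", "H", "C", "C", "C", "C"], _GENERIC_SPACERS),
        _rule("IBR", 10, ["C", "C", "C", "C", "C", "C", "C", "H", "C"],
              _IBR_SPACERS, accessory=True),
    ]


def load_rule_table(path: str | Path) -> list:
    """Load a rule table from JSON.

    Format: ``[{"name":..., "priority":..., "accessory":bool,
    "slots":[{"allowed":"C", "spacer":[2,2]}, ..., {"allowed":"C"}]}]``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    rules = []
    names, prios = set(), set()
    for entry in raw:
        if entry["name"] in names:
            raise ValueError(f"duplicate rule name {entry['name']}")
        if entry["priority"] in prios:
            raise ValueError(f"duplicate rule priority {entry['priority']}")
        names.add(entry["name"])
        prios.add(entry["priority"])
        slots = tuple(
            LigandSlot(
                frozenset(s["allowed"]),
                tuple(s["spacer"]) if "spacer" in s and s["spacer"] is not None else None,
            )
            for s in entry["slots"]
        )
        rules.append(
            LigandRule(entry["name"], entry["priority"], slots,
                       bool(entry.get("accessory", False)))
        )
    return sorted(rules, key=lambda r: r.priority)


def dump_rule_table(rules: Iterable[LigandRule], path: str | Path) -> None:
    out = []
    for r in rules:
        out.append(
            {
                "name": r.name,
                "priority": r.priority,
                "accessory": r.accessory,
                "slots": [
                    {"allowed": "".join(sorted(s.allowed)),
                     **({"spacer": list(s.spacer)} if s.spacer else {})}
                    for s in r.slots
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# Scanning

def scan_rule(seq: str, rule: LigandRule, protein_id: str = "") -> list:
    """Find every hit of *rule* in *seq*, one per feasible first-ligand
    position, using the smallest-spacer-vector tie-break."""
    hits = []
    pattern = rule.regex
    first_allowed = rule.slots[0].allowed
    for start, ch in enumerate(seq):
        if ch not in first_allowed:
            continue
        m = pattern.match(seq, start)
        if m is None:
            continue
        positions = tuple(m.start(g) for g in range(1, len(rule.slots) + 1))
        residues = tuple(seq[p] for p in positions)
        spacers = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
        hit = RingDomainHit(
            protein_id=protein_id,
            span=(positions[0], positions[-1] + 1),
            ligand_positions=positions,
            ligand_residues=residues,
            spacers=spacers,
            subtype=rule.name,
            rule_name=rule.name,
            accessory=rule.accessory,
        )
        assert hit.satisfies(rule), "internal error: hit violates its own rule"
        hits.append(hit)
    return hits


def scan_all(seq: str, rule_table: Sequence[LigandRule] | None = None,
             protein_id: str = "") -> list:
    """Apply every rule in priority order.

    When two *core* rules hit at the same first-ligand position only the
    higher-priority (lower number) label survives.  Accessory hits (IBR)
    are reported independently and never suppress core hits.
    """
    if rule_table is None:
        rule_table = default_rule_table()
    if not rule_table:
        raise ValueError("empty rule table")
    core_by_start: dict = {}
    accessory_hits = []
    for rule in sorted(rule_table, key=lambda r: r.priority):
        for hit in scan_rule(seq, rule, protein_id):
            if rule.accessory:
                accessory_hits.append(hit)
            else:
                core_by_start.setdefault(hit.ligand_positions[0], hit)
    out = list(core_by_start.values()) + accessory_hits
    out.sort(key=lambda h: (h.ligand_positions[0], h.accessory))
    return out


@dataclass(frozen=True)
class HcSplitCriterion:
    """Configurable RING-HCa/HCb discriminator.

    The HCa/HCb split is not defined by any published consensus; by default
    the spacer in the X(4-48) region (index 5) decides: HCa iff >= threshold.
    """

    spacer_index: int = 5
    threshold: int = 8

    def __post_init__(self):
        if not 0 <= self.spacer_index <= 6:
            raise ValueError("spacer_index must be in [0, 6]")


def split_hc(hit: RingDomainHit, criterion: HcSplitCriterion | None = None) -> str:
    """Assign a RING-HC hit to RING-HCa or RING-HCb."""
    if hit.subtype != "RING-HC":
        raise ValueError(f"split_hc applied to {hit.subtype} hit")
    crit = criterion or HcSplitCriterion()
    return "RING-HCa" if hit.spacers[crit.spacer_index] >= crit.threshold else "RING-HCb"


@dataclass
class SubtypeCensus:
    """Subtype counts with one-decimal half-up percentages."""

    counts: dict
    total: int
    denominator_note: str = "classified proteins"

    @property
    def percentages(self) -> dict:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {
            k: census_percentage(v, self.total) for k, v in self.counts.items()
        }


@dataclass(frozen=True)
class ProteomeAssignment:
    """Per-protein classification result."""

    protein_id: str
    subtype: str  # RING-H2 / RING-HCa / RING-HCb / RING-D / RING-M / unclassified
    representative: RingDomainHit | None
    n_core_domains: int
    accessory_domains: tuple = ()


def classify_proteome(
    records: Sequence[ProteinRecord],
    rule_table: Sequence[LigandRule] | None = None,
    hc_criterion: HcSplitCriterion | None = None,
):
    """Classify every protein by one representative core domain.

    The representative is the highest-priority, then leftmost, core hit
    (one domain per protein, as family censuses conventionally count).
    Returns ``(assignments, census, multi_domain_report)`` where the report
    lists proteins carrying two or more core domains.
    """
    if rule_table is None:
        rule_table = default_rule_table()
    prio = {r.name: r.priority for r in rule_table}
    assignments = []
    counts: dict = {}
    multi = {}
    for rec in records:
        hits = scan_all(rec.sequence, rule_table, rec.id)
        core = [h for h in hits if not h.accessory]
        acc = tuple(h for h in hits if h.accessory)
        if not core:
            assignments.append(ProteomeAssignment(rec.id, "unclassified", None, 0, acc))
            continue
        rep = min(core, key=lambda h: (prio[h.rule_name], h.ligand_positions[0]))
        label = rep.subtype
        if label == "RING-HC":
            label = split_hc(rep, hc_criterion)
        assignments.append(ProteomeAssignment(rec.id, label, rep, len(core), acc))
        counts[label] = counts.get(label, 0) + 1
        if len(core) >= 2:
            multi[rec.id] = len(core)
    census = SubtypeCensus(counts=counts, total=sum(counts.values()))
    return assignments, census, multi


def census_percentage(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, e.g. (59, 75) -> 78.7."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
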