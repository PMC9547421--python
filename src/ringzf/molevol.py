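"""Nei-Gojobori (1986) Ka/Ks estimation and divergence-time conversion.

Synonymous/nonsynonymous site and difference counting with pathway
averaging over multi-hit codons, Jukes-Cantor distance correction, and the
molecular-clock conversion T = Ks / (2 lambda) with a default substitution
rate of 6.5e-9 per synonymous site per year, reported in Mya.

Only the standard genetic code (translation table 1) is supported; mutation
paths passing through stop codons are excluded with renormalization over
the remaining valid paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations, product

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions / site / year

_table = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict = dict(_table.forward_table)
for _stop in _table.stop_codons:
    GENETIC_CODE[_stop] = "*"
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


class CodingPairError(ValueError):
    """Raised on malformed coding-sequence pairs."""


@dataclass(frozen=True)
class CodingPair:
    """Two codon-aligned, gap-free coding sequences of equal length."""

    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self):
        a, b = self.cds_a, self.cds_b
        if len(a) != len(b):
            raise CodingPairError("sequences differ in length")
        if len(a) % 3 != 0:
            raise CodingPairError("length not divisible by 3")
        if len(a) == 0:
            raise CodingPairError("empty sequences")
        for name, s in ((self.id_a, a), (self.id_b, b)):
            bad = set(s) - set(NUCLEOTIDES)
            if bad:
                raise CodingPairError(f"{name}: invalid characters {sorted(bad)}")
            for i in range(0, len(s), 3):
                if s[i : i + 3] in STOP_CODONS:
                    raise CodingPairError(
                        f"{name}: internal stop codon at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3

    def codons(self):
        a, b = self.cds_a, self.cds_b
        for i in range(0, len(a), 3):
            yield a[i : i + 3], b[i : i + 3]


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts, corrected distances and divergence time.

    ``omega`` and ``t_mya`` are ``None`` when undefined (Ks saturated or
    zero); ``dropped_codons`` counts codons whose every mutation path runs
    through a stop codon (excluded from the tallies).
    """

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float | None
    Ks: float | None
    omega: float | None
    t_mya: float | None
    dropped_codons: int = 0
    method: str = "NG86+JC69"


def _synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction (of 3) of single-nucleotide changes at *pos* that are
    synonymous; changes creating stop codons never count as synonymous."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
            syn += 1
    return syn / 3.0


def count_sites(cds: str) -> tuple:
    """NG86 synonymous/nonsynonymous site counts (S, N) for one sequence.

    S + N equals the nucleotide length exactly.
    """
    if len(cds) % 3 != 0 or not cds:
        raise CodingPairError("length not divisible by 3")
    S = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise CodingPairError(f"stop codon in frame at codon {i // 3}")
        S += sum(_synonymous_fraction(codon, p) for p in range(3))
    return S, len(cds) - S


def _classify_step(c_from: str, c_to: str) -> tuple:
    """(syn, nonsyn) tally of one single-nucleotide codon change."""
    if GENETIC_CODE[c_from] == GENETIC_CODE[c_to]:
        return 1, 0
    return 0, 1


def codon_pair_differences(codon_a: str, codon_b: str) -> tuple:
    """Pathway-averaged (Sd, Nd) between two codons.

    All orderings of the differing positions are walked as single-step
    mutation paths; paths entering a stop codon are discarded and the
    average is renormalized over valid paths.  Returns ``None`` when every
    path is invalid (caller drops the codon).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = codon_a
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            ds, dn = _classify_step(cur, nxt)
            s += ds
            n += dn
            cur = nxt
        if ok:
            total_s += s
            total_n += n
            n_valid += 1
    if n_valid == 0:
        return None
    return total_s / n_valid, total_n / n_valid


def count_differences(pair: CodingPair) -> tuple:
    """Pathway-averaged (Sd, Nd) over all codons of a pair.

    Codons whose every mutation path hits a stop are excluded and logged.
    """
    Sd = Nd = 0.0
    dropped = 0
    for idx, (ca, cb) in enumerate(pair.codons()):
        res = codon_pair_differences(ca, cb)
        if res is None:
            dropped += 1
            logger.warning(
                "codon %d (%s->%s): all mutation paths pass through stops; "
                "codon excluded", idx, ca, cb,
            )
            continue
        Sd += res[0]
        Nd += res[1]
    return Sd, Nd, dropped


def jukes_cantor(p: float) -> float | None:
    """JC69-corrected distance; ``None`` when saturated (p >= 3/4)."""
    import math

    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kaks(pair: CodingPair, lambda_rate: float = DEFAULT_LAMBDA) -> KaKsResult:
    """Full NG86 Ka/Ks estimate with JC correction for one coding pair."""
    S_a, N_a = count_sites(pair.cds_a)
    S_b, N_b = count_sites(pair.cds_b)
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    Sd, Nd, dropped = count_differences(pair)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    omega = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
    t = divergence_time(Ks, lambda_rate) if Ks is not None else None
    return KaKsResult(
        id_a=pair.id_a, id_b=pair.id_b, S=S, N=N, Sd=Sd, Nd=Nd,
        ps=ps, pn=pn, Ka=Ka, Ks=Ks, omega=omega, t_mya=t,
        dropped_codons=dropped,
    )


def divergence_time(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Divergence time in Mya: T = Ks / (2 lambda x 1e6).

    With the default rate, Ks = 0.013 gives exactly 1.0 Mya.
    """
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    return ks / (2.0 * lambda_rate * 1e6)


def selection_call(result: KaKsResult, tol: float = 1e-9) -> str:
    """Classify omega: purifying (<1), neutral (=1), positive (>1)."""
    if result.omega is None:
        return "undefined"
    if abs(result.omega - 1.0) <= tol:
        return "neutral"
    return "purifying" if result.omega < 1.0 else "positive"
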