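"""Physicochemical protein characterization from sequence alone.

Molecular weight (average masses), theoretical pI, GRAVY, aliphatic index,
instability index and atomic composition - the standard report columns of
a gene-family survey.  Definitions are the conventional ones: Kyte and
Doolittle hydropathy for GRAVY, Ikai's coefficients for the aliphatic
index, the Guruprasad DIWV dipeptide weights for instability, and an
EMBOSS-style pKa set with Henderson-Hasselbalch charge for pI.  Residue
hydropathy, DIWV and average-mass tables come from Biopython's data
modules; the atomic formula table and pKa set are defined here.

``X`` (unknown residue) is rejected in strict mode (the default), naming
the offending position.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import IUPACData
from Bio.SeqUtils.ProtParamData import DIWV, kd

WATER_MASS = 18.0153  # average mass of H2O, Daltons

#: average residue masses = free amino-acid masses minus one water
RESIDUE_MASSES: dict = {
    aa: IUPACData.protein_weights[aa] - WATER_MASS
    for aa in IUPACData.protein_weights
}

#: atomic composition (C, H, N, O, S) of the free amino acids
AMINO_ACID_FORMULAS: dict = {
    "A": (3, 7, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "C": (3, 7, 1, 2, 1),
    "E": (5, 9, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "F": (9, 11, 1, 2, 0),
    "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
}

#: EMBOSS-style pKa values (termini and ionizable side chains)
PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

#: Ikai aliphatic-index side-chain coefficients for Val and Ile/Leu
ALIPHATIC_COEFFS = (2.9, 3.9)

INSTABILITY_THRESHOLD = 40.0  # unstable iff strictly greater


class SequenceError(ValueError):
    """Raised on sequences this module cannot characterize."""


def _check(seq: str, min_len: int = 1, allow_x: bool = False) -> None:
    if len(seq) < min_len:
        raise SequenceError(f"sequence shorter than {min_len} residues")
    for i, ch in enumerate(seq):
        if ch == "X":
            if not allow_x:
                raise SequenceError(f"unknown residue X at position {i}")
            continue
        if ch not in AMINO_ACID_FORMULAS:
            raise SequenceError(f"invalid residue {ch!r} at position {i}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    _check(seq)
    return sum(RESIDUE_MASSES[ch] for ch in seq) + WATER_MASS


def gravy(seq: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle mean)."""
    _check(seq)
    return sum(kd[ch] for ch in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai's aliphatic index from Ala/Val/Ile/Leu mole percents."""
    _check(seq)
    n = len(seq)
    x_ala = 100.0 * seq.count("A") / n
    x_val = 100.0 * seq.count("V") / n
    x_il = 100.0 * (seq.count("I") + seq.count("L")) / n
    a, b = ALIPHATIC_COEFFS
    return x_ala + a * x_val + b * x_il


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights.

    Values strictly above 40 classify the protein as unstable.
    """
    _check(seq, min_len=2)
    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 * total / len(seq)


def is_unstable(seq: str) -> bool:
    return instability_index(seq) > INSTABILITY_THRESHOLD


def net_charge(seq: str, ph: float) -> float:
    """Net charge at *ph* by Henderson-Hasselbalch over termini and the
    ionizable side chains D, E, C, Y, H, K, R."""
    _check(seq)
    pos = 1.0 / (1.0 + 10 ** (ph - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (PKA["Cterm"] - ph))
    for ch in seq:
        if ch in ("H", "K", "R"):
            pos += 1.0 / (1.0 + 10 ** (ph - PKA[ch]))
        elif ch in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (PKA[ch] - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    _check(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def atomic_composition(seq: str) -> dict:
    """Atom counts C, H, N, O, S: residue formula sums minus (L-1) waters."""
    _check(seq)
    totals = [0, 0, 0, 0, 0]
    for ch in seq:
        for i, v in enumerate(AMINO_ACID_FORMULAS[ch]):
            totals[i] += v
    n_water = len(seq) - 1
    totals[1] -= 2 * n_water  # H2
    totals[3] -= 1 * n_water  # O
    return dict(zip("CHNOS", totals))


@dataclass(frozen=True)
class ProteinProperties:
    """The full per-protein characterization row."""

    protein_id: str
    length: int
    mw: float
    pi: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    unstable: bool
    atoms: dict


def characterize(protein_id: str, seq: str) -> ProteinProperties:
    """All properties for one sequence (strict mode, X rejected)."""
    return ProteinProperties(
        protein_id=protein_id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        instability_index=instability_index(seq),
        unstable=is_unstable(seq),
        atoms=atomic_composition(seq),
    )
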