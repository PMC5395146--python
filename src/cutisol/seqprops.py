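"""Per-protein sequence properties: isoelectric point, composition, motifs.

The isoelectric point follows the Bjellqvist pK set as deployed by the
ExPASy Compute pI tool: residue-specific N-terminal pKs, a single
C-terminal pK, and side-chain pKs for D, E, C, Y (acidic) and H, K, R
(basic).  The pI is the pH at which the Henderson-Hasselbalch net charge
vanishes, located by bisection on [0, 14] to a charge residual below 1e-4
(the charge is strictly decreasing in pH, so bisection always converges).

Motif counts cover the elastic-repeat tetramer AAP[A/V/L] and the GYR and
YLP tripeptides proposed as protein-protein interaction motifs;
overlapping occurrences are all counted.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .sequence_io import ProteinRecord

# Bjellqvist pK values as used by the ExPASy Compute pI/Mw tool.
CTERM_PK = 3.55
#: C-terminal D/E carry their own pK in the Bjellqvist set.
CTERM_PK_BY_RESIDUE = {"D": 4.55, "E": 4.75}
NTERM_PK_DEFAULT = 7.5
NTERM_PK = {
    "A": 7.59,
    "M": 7.0,
    "S": 6.93,
    "P": 8.36,
    "T": 6.82,
    "V": 7.44,
    "E": 7.7,
}
SIDECHAIN_ACIDIC = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
SIDECHAIN_BASIC = {"H": 5.98, "K": 10.0, "R": 12.0}

#: Recognized motifs (regex with overlap handled via lookahead).
MOTIFS = {
    "AAP_AVL": "AAP[AVL]",
    "GYR": "GYR",
    "YLP": "YLP",
}

#: Residue classes whose percentages the property table reports.
PCT_RESIDUES = ("H", "Y", "Q", "K")


def net_charge(sequence: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge of the sequence at the given pH."""
    counts = Counter(sequence)
    nterm_pk = NTERM_PK.get(sequence[0], NTERM_PK_DEFAULT)
    positive = 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    for res, pk in SIDECHAIN_BASIC.items():
        positive += counts[res] / (1.0 + 10 ** (pH - pk))
    cterm_pk = CTERM_PK_BY_RESIDUE.get(sequence[-1], CTERM_PK)
    negative = 1.0 / (1.0 + 10 ** (cterm_pk - pH))
    for res, pk in SIDECHAIN_ACIDIC.items():
        negative += counts[res] / (1.0 + 10 ** (pk - pH))
    return positive - negative


def isoelectric_point(
    sequence: str, tolerance: float = 1e-4, max_iter: int = 200
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    if not sequence:
        raise ValueError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        charge = net_charge(sequence, mid)
        if abs(charge) < tolerance:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return mid


def composition(sequence: str) -> tuple[dict[str, float], Counter]:
    """(residue -> percentage of length, raw counts).

    Percentages are over every residue letter present (including X), so
    they sum to 100.
    """
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = Counter(sequence)
    length = len(sequence)
    return {res: 100.0 * n / length for res, n in counts.items()}, counts


def motif_count(sequence: str, motif: str) -> int:
    """Number of motif occurrences; overlapping occurrences all count."""
    return len(motif_positions(sequence, motif))


def motif_positions(sequence: str, motif: str) -> list[int]:
    """1-based start positions of each (possibly overlapping) occurrence."""
    try:
        pattern = MOTIFS[motif]
    except KeyError:
        raise ValueError(
            f"unknown motif {motif!r}; known: {sorted(MOTIFS)}"
        )
    return [m.start() + 1 for m in re.finditer(f"(?={pattern})", sequence)]


@dataclass(frozen=True)
class SequenceProperties:
    protein_id: str
    length: int
    pI: float
    pct: Mapping[str, float]
    motif_counts: Mapping[str, int]
    analyzed_sequence: str  # "full" | "mature"


def sequence_properties(
    protein: ProteinRecord, mature: bool = False
) -> SequenceProperties:
    """Length, pI, H/Y/Q/K percentages and motif counts for one protein.

    With ``mature`` the annotated signal peptide is removed first; proteins
    without an annotation fall back to the full sequence.
    """
    seq = protein.mature_sequence if mature else protein.sequence
    pct, _ = composition(seq)
    return SequenceProperties(
        protein_id=protein.id,
        length=len(seq),
        pI=isoelectric_point(seq),
        pct={res: pct.get(res, 0.0) for res in PCT_RESIDUES},
        motif_counts={m: motif_count(seq, m) for m in MOTIFS},
        analyzed_sequence="mature" if mature else "full",
    )


def properties_table(
    proteins: Sequence[ProteinRecord], mature: bool = False
) -> pd.DataFrame:
    """Property table keyed by protein id (one row per protein)."""
    rows = []
    for protein in proteins:
        props = sequence_properties(protein, mature=mature)
        row: dict[str, object] = {
            "protein": props.protein_id,
            "length": props.length,
            "pI": props.pI,
            "analyzed_sequence": props.analyzed_sequence,
        }
        for res in PCT_RESIDUES:
            row[f"pct_{res}"] = props.pct[res]
        for m in MOTIFS:
            row[f"n_{m}"] = props.motif_counts[m]
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein")
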