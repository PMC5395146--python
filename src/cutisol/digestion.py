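"""In-silico tryptic digestion and peptide mass bookkeeping.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline (the default rule of common search engines).  Peptides are
reported with 1-based inclusive coordinates and their missed-cleavage
count; searches here allow up to two missed cleavages.

Masses are monoisotopic, built from the pyteomics residue-mass table.
Fixed carbamidomethylation of cysteine and the variable oxidation /
deamidation modifications are handled as additive deltas; no fragment-ion
or search-scoring computation is done.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

from pyteomics import mass as _pmass

from .sequence_io import ProteinRecord

WATER_MONO = 18.0105646863
#: Fixed modification: carbamidomethylation of cysteine.
CARBAMIDOMETHYL = 57.02146
#: Variable modification: oxidation of methionine.
OXIDATION_M = 15.99491
#: Variable modification: deamidation of asparagine or glutamine.
DEAMIDATION_NQ = 0.98402

#: Residues whose side chains accept the variable modifications above.
_VARIABLE_TARGETS = {"M": OXIDATION_M, "N": DEAMIDATION_NQ, "Q": DEAMIDATION_NQ}


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A tryptic peptide with 1-based inclusive coordinates."""

    peptide: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_boundaries(sequence: str) -> list[int]:
    """0-based indices at which the sequence is cut (between i-1 and i)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str, max_missed: int = 2
) -> list[TheoreticalPeptide]:
    """All tryptic peptides with 0..``max_missed`` missed cleavages.

    The zero-missed peptides, concatenated in order, reconstruct the input
    exactly.  Output is ordered by start position, then length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + cleavage_boundaries(sequence) + [len(sequence)]
    peptides: list[TheoreticalPeptide] = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + missed + 1
            if j >= len(bounds):
                break
            peptides.append(
                TheoreticalPeptide(
                    peptide=sequence[bounds[i]:bounds[j]],
                    start=bounds[i] + 1,
                    end=bounds[j],
                    missed_cleavages=missed,
                )
            )
    return peptides


def nterm_peptide_length(protein: ProteinRecord, use_mature: bool = False) -> int:
    """Length of the zero-missed tryptic peptide starting at residue 1.

    With ``use_mature`` the signal peptide is removed first (it must be
    annotated), so the value refers to the secreted protein's N-terminus.
    """
    if use_mature and protein.signal_peptide_end is None:
        raise ValueError(
            f"protein {protein.id}: mature N-terminal peptide requested but "
            "signal_peptide_end is not annotated"
        )
    seq = protein.mature_sequence if use_mature else protein.sequence
    first = tryptic_digest(seq, max_missed=0)[0]
    return len(first.peptide)


def peptide_monoisotopic_mass(
    peptide: str,
    fixed_carbamidomethyl_c: bool = True,
    variable_mods: Sequence[tuple[int, float]] = (),
) -> float:
    """Monoisotopic peptide mass in Da.

    ``variable_mods`` is a list of (1-based residue position, mass delta)
    pairs that are added verbatim; the fixed cysteine modification is
    applied to every C when the flag is set.
    """
    if not peptide:
        raise ValueError("empty peptide")
    total = WATER_MONO
    for res in peptide:
        try:
            total += _pmass.std_aa_mass[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} in peptide {peptide}")
    if fixed_carbamidomethyl_c:
        total += CARBAMIDOMETHYL * peptide.count("C")
    for pos, delta in variable_mods:
        if not (1 <= pos <= len(peptide)):
            raise ValueError(
                f"modification position {pos} outside peptide of length "
                f"{len(peptide)}"
            )
        total += delta
    return total


def enumerate_modified_masses(
    peptide: str,
    fixed_carbamidomethyl_c: bool = True,
    max_var_sites: int = 3,
) -> Iterator[tuple[tuple[tuple[int, float], ...], float]]:
    """All variable-modification states up to ``max_var_sites`` sites.

    Yields ``(mods, mass)`` pairs, starting from the unmodified form.
    Oxidation applies to M, deamidation to N/Q; combinatorics are capped
    because masses here are bookkeeping, not search scoring.
    """
    sites = [
        (i + 1, _VARIABLE_TARGETS[res])
        for i, res in enumerate(peptide)
        if res in _VARIABLE_TARGETS
    ]
    for k in range(min(max_var_sites, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            yield combo, peptide_monoisotopic_mass(
                peptide, fixed_carbamidomethyl_c, combo
            )
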