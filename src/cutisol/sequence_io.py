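"""File I/O and shared domain types for serial-extraction proteomics.

This module defines the in-memory model used by every downstream stage
(:class:`ProteinRecord`, :class:`PeptideObservation`, :class:`EvidenceTable`,
:class:`FractionScheme`) and the external file contracts: FASTA for protein
sequences, tab-delimited tables with a header row for protein metadata and
peptide evidence.  It also builds reversed-sequence decoy databases.

Conventions
-----------
* All residue positions and intervals are 1-based and inclusive.
* Multiple protein ids in a table cell are separated by ``;``.
* Isoleucine and leucine are *not* collapsed anywhere: peptide-to-protein
  assignment arrives already resolved in the ``protein_ids`` column and is
  only re-validated here by exact substring matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Recognized cuticular-protein families.  ``other`` covers anything else
#: (including non-CPs that slip into an evidence table).
FAMILIES = frozenset(
    {
        "CPR",
        "CPAP1",
        "CPAP3",
        "CPF",
        "CPFL",
        "CPLCA",
        "CPLCG",
        "CPLCP",
        "CPLCW",
        "CPLCX",
        "TWDL",
        "CPCFC",
        "other",
    }
)

#: R&R Consensus subgroups of the CPR family.
CPR_GROUPS = frozenset({"RR1", "RR2", "RR3", "unassigned", "not_applicable"})

DOMAIN_KINDS = frozenset({"pf00379", "pf01607", "other"})


class FormatError(ValueError):
    """A file or record violates one of the input contracts."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A chitin-binding (or other) domain interval, 1-based inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise FormatError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"invalid domain interval {self.start}-{self.end} (1-based, inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """One cuticular protein with sequence and annotation.

    ``signal_peptide_end`` is the 1-based index of the *last* signal-peptide
    residue; the mature sequence starts at the following residue.
    """

    id: str
    sequence: str
    accession: str | None = None
    family: str = "other"
    cpr_group: str = "not_applicable"
    signal_peptide_end: int | None = None
    domains: tuple[DomainAnnotation, ...] = ()
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein id must be non-empty")
        if not self.sequence:
            raise FormatError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id}: invalid residue letters {sorted(bad)}"
            )
        if self.family not in FAMILIES:
            raise FormatError(f"protein {self.id}: unknown family {self.family!r}")
        if self.cpr_group not in CPR_GROUPS:
            raise FormatError(
                f"protein {self.id}: unknown CPR group {self.cpr_group!r}"
            )
        if self.cpr_group != "not_applicable" and self.family != "CPR":
            raise FormatError(
                f"protein {self.id}: cpr_group {self.cpr_group} requires family CPR"
            )
        if self.signal_peptide_end is not None and not (
            1 <= self.signal_peptide_end < len(self.sequence)
        ):
            raise FormatError(
                f"protein {self.id}: signal_peptide_end {self.signal_peptide_end} "
                f"outside [1, {len(self.sequence) - 1}]"
            )
        for dom in self.domains:
            if dom.end > len(self.sequence):
                raise FormatError(
                    f"protein {self.id}: domain {dom.kind} {dom.start}-{dom.end} "
                    f"extends beyond sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mature_sequence(self) -> str:
        """Sequence after the annotated signal peptide (full if unannotated)."""
        if self.signal_peptide_end is None:
            return self.sequence
        return self.sequence[self.signal_peptide_end:]


@dataclass(frozen=True)
class Fraction:
    id: str
    category: str  # "extract" | "final_pellet"


@dataclass(frozen=True)
class FractionScheme:
    """The ordered serial-extraction fractions.

    Exactly one fraction is the final pellet.  ``excluded`` fractions remain
    representable in evidence tables but are ignored by classification and
    coverage by default (the tetraborate pre-wash is discarded upstream).
    """

    fractions: tuple[Fraction, ...]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fractions]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate fraction ids in scheme")
        fps = [f.id for f in self.fractions if f.category == "final_pellet"]
        if len(fps) != 1:
            raise FormatError("scheme must have exactly one final_pellet fraction")
        unknown = self.excluded - set(ids)
        if unknown:
            raise FormatError(f"excluded fractions not in scheme: {sorted(unknown)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.fractions)

    @property
    def final_pellet_id(self) -> str:
        return next(f.id for f in self.fractions if f.category == "final_pellet")

    @property
    def extract_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.fractions if f.category == "extract")

    @property
    def active_ids(self) -> tuple[str, ...]:
        """Fraction ids that participate in classification/coverage."""
        return tuple(i for i in self.ids if i not in self.excluded)

    def index(self, fraction_id: str) -> int:
        return self.ids.index(fraction_id)

    def __contains__(self, fraction_id: object) -> bool:
        return fraction_id in self.ids


def default_scheme() -> FractionScheme:
    """PBS -> EDTA -> 2/4/8 M urea -> boiling SDS -> final pellet.

    The potassium-tetraborate pre-wash (``KTB``) is present but excluded:
    it removes non-cuticular material before the serial extraction proper.
    """
    return FractionScheme(
        fractions=(
            Fraction("KTB", "extract"),
            Fraction("PBS", "extract"),
            Fraction("EDTA", "extract"),
            Fraction("urea2M", "extract"),
            Fraction("urea4M", "extract"),
            Fraction("urea8M", "extract"),
            Fraction("SDS", "extract"),
            Fraction("FP", "final_pellet"),
        ),
        excluded=frozenset({"KTB"}),
    )


@dataclass(frozen=True)
class PeptideObservation:
    """One detected peptide in one (fraction, replicate, gel slice) context."""

    peptide: str
    protein_ids: frozenset[str]
    fraction: str
    replicate: int
    gel_slice: str = "whole"
    spectral_count: int = 1
    modifications: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError("empty peptide")
        if not self.protein_ids:
            raise FormatError(f"peptide {self.peptide}: no protein ids")
        if self.replicate < 1:
            raise FormatError(f"peptide {self.peptide}: replicate must be >= 1")
        if self.spectral_count < 0:
            raise FormatError(f"peptide {self.peptide}: negative spectral count")


@dataclass
class EvidenceTable:
    """Validated peptide evidence plus ingest-time exclusions."""

    observations: list[PeptideObservation]
    scheme: FractionScheme
    n_replicates: int = 3
    excluded: list[PeptideObservation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unknown_protein_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.fraction not in self.scheme:
                raise FormatError(
                    f"observation fraction {obs.fraction!r} not in scheme; "
                    f"permitted: {list(self.scheme.ids)}"
                )
            if obs.replicate > self.n_replicates:
                raise FormatError(
                    f"replicate {obs.replicate} exceeds replicate count "
                    f"{self.n_replicates}"
                )

    def protein_ids(self) -> set[str]:
        out: set[str] = set()
        for obs in self.observations:
            out |= obs.protein_ids
        return out

    def for_protein(self, protein_id: str) -> list[PeptideObservation]:
        return [o for o in self.observations if protein_id in o.protein_ids]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into sequence-only records.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Empty files, duplicate ids and non-residue characters
    are fatal, naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise FormatError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, sequence=str(entry.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def make_decoy(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Reversed-sequence decoys, one per input, ids prefixed ``DECOY_``."""
    return [
        ProteinRecord(id=f"DECOY_{p.id}", sequence=p.sequence[::-1])
        for p in proteins
    ]


# ---------------------------------------------------------------------------
# Metadata table
# ---------------------------------------------------------------------------

_META_COLUMNS = ("id", "family", "cpr_group", "cluster_id",
                 "signal_peptide_end", "domains")


def _parse_domains(cell: str, pid: str) -> tuple[DomainAnnotation, ...]:
    if _is_blank(cell):
        return ()
    out = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            kind, span = token.split(":")
            start_s, end_s = span.split("-")
            out.append(DomainAnnotation(kind.strip(), int(start_s), int(end_s)))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"protein {pid}: bad domain token {token!r}: {exc}")
    return tuple(out)


def _is_blank(cell: object) -> bool:
    return cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() in ("", "-")


def read_metadata(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> tuple[list[ProteinRecord], list[str]]:
    """Merge a metadata TSV into FASTA-derived records.

    Returns the merged records plus the list of metadata ids that did not
    resolve against the FASTA.  Proteins absent from the metadata keep the
    defaults (family ``other``).  Domain intervals beyond the sequence are
    fatal, naming the protein.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path}: missing columns {missing}")
    by_id = {p.id: p for p in proteins}
    unknown: list[str] = []
    merged = dict(by_id)
    for row in df.itertuples(index=False):
        pid = str(row.id)
        base = by_id.get(pid)
        if base is None:
            unknown.append(pid)
            continue
        merged[pid] = dataclasses.replace(
            base,
            family=str(row.family) if not _is_blank(row.family) else "other",
            cpr_group=(
                str(row.cpr_group) if not _is_blank(row.cpr_group)
                else "not_applicable"
            ),
            cluster_id=None if _is_blank(row.cluster_id) else str(row.cluster_id),
            signal_peptide_end=(
                None if _is_blank(row.signal_peptide_end)
                else int(float(row.signal_peptide_end))
            ),
            domains=_parse_domains(row.domains, pid),
        )
    return [merged[p.id] for p in proteins], unknown


def write_metadata(records: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "family": rec.family,
                "cpr_group": rec.cpr_group,
                "cluster_id": rec.cluster_id or "-",
                "signal_peptide_end": (
                    "-" if rec.signal_peptide_end is None
                    else rec.signal_peptide_end
                ),
                "domains": ";".join(
                    f"{d.kind}:{d.start}-{d.end}" for d in rec.domains
                ) or "-",
            }
        )
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Evidence table
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = ("peptide", "protein_ids", "fraction", "replicate",
                     "gel_slice", "spectral_count")


def _parse_mods(cell: object) -> tuple[tuple[int, float], ...]:
    if _is_blank(cell):
        return ()
    out = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        pos_s, delta_s = token.split(":")
        out.append((int(pos_s), float(delta_s)))
    return tuple(out)


def read_evidence(
    path: str | Path,
    scheme: FractionScheme | None = None,
    proteins: Sequence[ProteinRecord] | None = None,
    n_replicates: int = 3,
) -> EvidenceTable:
    """Read and validate a peptide-evidence TSV.

    An unknown fraction id is fatal (the error lists the permitted ids).
    When ``proteins`` is supplied, every claimed protein is checked to
    contain the peptide as an exact substring; non-matching ids are pruned
    with a warning and observations left with no valid protein are moved to
    ``EvidenceTable.excluded``.
    """
    scheme = scheme or default_scheme()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"evidence {path}: missing columns {missing}")
    seq_by_id = {p.id: p.sequence for p in proteins} if proteins is not None else None
    observations: list[PeptideObservation] = []
    excluded: list[PeptideObservation] = []
    warn: list[str] = []
    unknown_ids: set[str] = set()
    for row in df.itertuples(index=False):
        fraction = str(row.fraction)
        if fraction not in scheme:
            raise FormatError(
                f"evidence {path}: unknown fraction {fraction!r}; "
                f"permitted: {list(scheme.ids)}"
            )
        peptide = str(row.peptide).upper()
        ids = frozenset(
            t.strip() for t in str(row.protein_ids).split(";") if t.strip()
        )
        obs = PeptideObservation(
            peptide=peptide,
            protein_ids=ids,
            fraction=fraction,
            replicate=int(row.replicate),
            gel_slice=str(row.gel_slice),
            spectral_count=int(row.spectral_count),
            modifications=_parse_mods(getattr(row, "modifications", None)),
        )
        if seq_by_id is not None:
            unknown_ids |= {i for i in ids if i not in seq_by_id}
            matching = frozenset(
                i for i in ids if i in seq_by_id and peptide in seq_by_id[i]
            )
            dropped = ids - matching
            if dropped:
                warn.append(
                    f"peptide {peptide}: not a substring of {sorted(dropped)}"
                )
            if not matching:
                excluded.append(obs)
                continue
            obs = dataclasses.replace(obs, protein_ids=matching)
        observations.append(obs)
    return EvidenceTable(
        observations=observations,
        scheme=scheme,
        n_replicates=n_replicates,
        excluded=excluded,
        warnings=warn,
        unknown_protein_ids=unknown_ids,
    )


def write_evidence(table: EvidenceTable, path: str | Path) -> None:
    rows = []
    for obs in table.observations:
        rows.append(
            {
                "peptide": obs.peptide,
                "protein_ids": ";".join(sorted(obs.protein_ids)),
                "fraction": obs.fraction,
                "replicate": obs.replicate,
                "gel_slice": obs.gel_slice,
                "spectral_count": obs.spectral_count,
                "modifications": ";".join(
                    f"{pos}:{delta!r}" for pos, delta in obs.modifications
                ) or "-",
            }
        )
    pd.DataFrame(
        rows, columns=list(_EVIDENCE_COLUMNS) + ["modifications"]
    ).to_csv(path, sep="\t", index=False)
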