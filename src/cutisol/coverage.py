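"""Residue-resolution peptide coverage and cross-linking-relevant censuses.

Observed peptides are mapped back onto their proteins; every occurrence of
a peptide contributes, overlapping intervals are merged, and shared
(non-unique) peptides contribute to all member proteins.  On top of the
coverage map this module derives the quantities used to reason about
sclerotization chemistry: whether the N-terminal residue was ever seen in
a peptide, whether chitin-binding domains are spanned, and whether runs of
His/Lys (length >= 2) or Gln (length >= 4) fall inside recovered peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import (
    DomainAnnotation,
    EvidenceTable,
    ProteinRecord,
)

#: Residue classes relevant to cuticle cross-linking chemistry.
CENSUS_RESIDUES = ("H", "K", "Y", "Q")

#: Minimal run length for a residue "cluster", per residue.
CLUSTER_MIN_LENGTH = {"H": 2, "K": 2, "Q": 4}


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Merge 1-based inclusive intervals into disjoint sorted intervals."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return tuple(out)


def find_occurrences(peptide: str, sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences, 1-based inclusive."""
    hits = []
    idx = sequence.find(peptide)
    while idx != -1:
        hits.append((idx + 1, idx + len(peptide)))
        idx = sequence.find(peptide, idx + 1)
    return hits


@dataclass(frozen=True)
class DomainCoverage:
    domain: DomainAnnotation
    overlapped: bool
    fraction_covered: float


@dataclass
class CoverageReport:
    """Recovered/unrecovered map for one protein."""

    protein_id: str
    length: int
    covered: tuple[tuple[int, int], ...]
    coverage_fraction: float
    nterm_recovered: bool
    longest_recovered_peptide: int
    domain_coverage: tuple[DomainCoverage, ...]
    slice_profile: dict[str, frozenset[str]]
    n_peptides: int
    n_unique_peptides: int

    def is_covered(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.covered)

    def covers_interval(self, start: int, end: int) -> bool:
        """True iff [start, end] lies wholly within one covered interval."""
        return any(s <= start and end <= e for s, e in self.covered)


def domain_recovery(
    covered: Sequence[tuple[int, int]], protein: ProteinRecord
) -> tuple[DomainCoverage, ...]:
    """Overlap flag and covered fraction for each annotated domain."""
    out = []
    for dom in protein.domains:
        overlap = 0
        for s, e in covered:
            overlap += max(0, min(e, dom.end) - max(s, dom.start) + 1)
        out.append(
            DomainCoverage(
                domain=dom,
                overlapped=overlap > 0,
                fraction_covered=overlap / dom.length,
            )
        )
    return tuple(out)


def map_coverage(
    evidence: EvidenceTable,
    proteins: Sequence[ProteinRecord],
    restrict_fractions: set[str] | None = None,
    mature: bool = False,
) -> dict[str, CoverageReport]:
    """Residue-resolution coverage for every protein with evidence.

    Fractions excluded by the scheme are ignored unless explicitly named in
    ``restrict_fractions``.  With ``mature`` the analyzed sequence starts
    after the annotated signal peptide, so ``nterm_recovered`` refers to
    the mature protein's alpha-amino terminus; domain coordinates (given on
    the full sequence) are only reported in full-sequence mode.
    """
    fractions = (
        set(restrict_fractions)
        if restrict_fractions is not None
        else set(evidence.scheme.active_ids)
    )
    by_protein: dict[str, list] = {p.id: [] for p in proteins}
    for obs in evidence.observations:
        if obs.fraction not in fractions:
            continue
        for pid in obs.protein_ids:
            if pid in by_protein:
                by_protein[pid].append(obs)
    reports: dict[str, CoverageReport] = {}
    for protein in proteins:
        observations = by_protein[protein.id]
        if not observations:
            continue
        seq = protein.mature_sequence if mature else protein.sequence
        intervals: list[tuple[int, int]] = []
        longest = 0
        peptides = {o.peptide for o in observations}
        unique_peptides = {
            o.peptide for o in observations if o.protein_ids == {protein.id}
        }
        for pep in peptides:
            hits = find_occurrences(pep, seq)
            if hits:
                intervals.extend(hits)
                longest = max(longest, len(pep))
        covered = merge_intervals(intervals)
        n_covered = sum(e - s + 1 for s, e in covered)
        slice_prof: dict[str, set[str]] = {}
        for obs in observations:
            if obs.gel_slice not in ("none", ""):
                slice_prof.setdefault(obs.fraction, set()).add(obs.gel_slice)
        reports[protein.id] = CoverageReport(
            protein_id=protein.id,
            length=len(seq),
            covered=covered,
            coverage_fraction=n_covered / len(seq),
            nterm_recovered=any(s == 1 for s, _ in covered),
            longest_recovered_peptide=longest,
            domain_coverage=(
                domain_recovery(covered, protein) if not mature else ()
            ),
            slice_profile={f: frozenset(v) for f, v in slice_prof.items()},
            n_peptides=len(peptides),
            n_unique_peptides=len(unique_peptides),
        )
    return reports


# ---------------------------------------------------------------------------
# Residue and residue-cluster recovery census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSite:
    protein_id: str
    residue: str
    position: int
    recovered: bool


@dataclass(frozen=True)
class ResidueCluster:
    """A maximal run of identical residues (HH+, KK+, or QQQQ+)."""

    protein_id: str
    residue: str
    start: int
    end: int
    recovered: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ResidueRecoveryCensus:
    sites: list[ResidueSite] = field(default_factory=list)
    clusters: list[ResidueCluster] = field(default_factory=list)

    def cluster_totals(self, residue: str) -> tuple[int, int]:
        """(total clusters, clusters fully inside recovered peptides)."""
        relevant = [c for c in self.clusters if c.residue == residue]
        return len(relevant), sum(c.recovered for c in relevant)

    def site_totals(self, residue: str) -> tuple[int, int]:
        relevant = [s for s in self.sites if s.residue == residue]
        return len(relevant), sum(s.recovered for s in relevant)


def find_runs(sequence: str, residue: str, min_length: int) -> list[tuple[int, int]]:
    """Maximal runs of ``residue`` of at least ``min_length`` (1-based)."""
    runs = []
    i = 0
    n = len(sequence)
    while i < n:
        if sequence[i] == residue:
            j = i
            while j + 1 < n and sequence[j + 1] == residue:
                j += 1
            if j - i + 1 >= min_length:
                runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def residue_census(
    proteins: Sequence[ProteinRecord],
    reports: Mapping[str, CoverageReport],
    mature: bool = False,
) -> ResidueRecoveryCensus:
    """Census of H/K/Y/Q sites and clusters across covered proteins.

    A site is recovered iff it lies in a covered interval; a cluster is
    recovered iff every residue of the run is covered (runs are maximal by
    construction).  Only proteins with a coverage report contribute.
    """
    census = ResidueRecoveryCensus()
    for protein in proteins:
        report = reports.get(protein.id)
        if report is None:
            continue
        seq = protein.mature_sequence if mature else protein.sequence
        for residue in CENSUS_RESIDUES:
            for pos, res in enumerate(seq, start=1):
                if res == residue:
                    census.sites.append(
                        ResidueSite(
                            protein_id=protein.id,
                            residue=residue,
                            position=pos,
                            recovered=report.is_covered(pos),
                        )
                    )
            min_len = CLUSTER_MIN_LENGTH.get(residue)
            if min_len is None:
                continue
            for start, end in find_runs(seq, residue, min_len):
                census.clusters.append(
                    ResidueCluster(
                        protein_id=protein.id,
                        residue=residue,
                        start=start,
                        end=end,
                        recovered=report.covers_interval(start, end),
                    )
                )
    return census


# ---------------------------------------------------------------------------
# Gel-slice profiles
# ---------------------------------------------------------------------------

@dataclass
class SliceProfile:
    protein_id: str
    slices_by_fraction: dict[str, frozenset[str]]
    multi_slice: bool


def slice_profile(evidence: EvidenceTable, protein_id: str) -> SliceProfile:
    """Gel-slice presence per fraction; ``multi_slice`` is true iff some
    fraction has peptides in two or more distinct slices."""
    slices: dict[str, set[str]] = {}
    for obs in evidence.observations:
        if protein_id in obs.protein_ids and obs.gel_slice not in ("none", ""):
            slices.setdefault(obs.fraction, set()).add(obs.gel_slice)
    return SliceProfile(
        protein_id=protein_id,
        slices_by_fraction={f: frozenset(v) for f, v in slices.items()},
        multi_slice=any(len(v) >= 2 for v in slices.values()),
    )


def render_coverage(protein: ProteinRecord, report: CoverageReport) -> str:
    """Plain-text annotated sequence: covered residues uppercase, the rest
    lowercase, 60 residues per line with a 1-based offset column."""
    chars = []
    for pos, res in enumerate(protein.sequence, start=1):
        chars.append(res.upper() if report.is_covered(pos) else res.lower())
    lines = []
    for i in range(0, len(chars), 60):
        lines.append(f"{i + 1:>6}  " + "".join(chars[i:i + 60]))
    return "\n".join(lines)
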