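"""Spectral-count grouping and ranking of final-pellet proteins.

Proteins sharing any observed peptide are merged into protein groups
(transitive closure); groups are ranked by a length-normalized spectral
count share (the NSAF convention: SpC/L renormalized to sum to one), and
the top-quartile summary reports how many of the best-supported groups are
cuticular proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .sequence_io import PeptideObservation


@dataclass(frozen=True)
class ProteinGroup:
    members: tuple[str, ...]  # sorted protein ids
    distinct_peptides: int
    total_spectral_count: int
    representative_length: float  # mean member length
    nsaf: float | None = None


def group_by_shared_peptides(
    observations: Iterable[PeptideObservation],
    lengths: Mapping[str, int],
) -> list[ProteinGroup]:
    """Partition observed proteins into shared-peptide groups.

    The caller restricts ``observations`` to one batch and one fraction
    (typically the final pellet).  Proteins connected through any chain of
    shared peptides end up in one group; proteins with all-unique peptides
    become singletons.
    """
    observations = list(observations)
    graph = nx.Graph()
    peptides_by_protein: dict[str, set[str]] = {}
    counts_by_protein: dict[str, int] = {}
    for obs in observations:
        ids = sorted(obs.protein_ids)
        graph.add_nodes_from(ids)
        for a, b in zip(ids, ids[1:]):
            graph.add_edge(a, b)
        for pid in ids:
            peptides_by_protein.setdefault(pid, set()).add(obs.peptide)
            counts_by_protein[pid] = (
                counts_by_protein.get(pid, 0) + obs.spectral_count
            )
    groups = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        peptides: set[str] = set()
        for pid in members:
            peptides |= peptides_by_protein[pid]
        # spectral counts of shared peptides are attributed once per group
        total = 0
        seen_obs: set[int] = set()
        for i, obs in enumerate(observations):
            if obs.protein_ids & set(members) and i not in seen_obs:
                total += obs.spectral_count
                seen_obs.add(i)
        missing = [m for m in members if m not in lengths]
        if missing:
            raise KeyError(f"no length known for proteins {missing}")
        groups.append(
            ProteinGroup(
                members=members,
                distinct_peptides=len(peptides),
                total_spectral_count=total,
                representative_length=(
                    sum(lengths[m] for m in members) / len(members)
                ),
            )
        )
    return sorted(groups, key=lambda g: g.members)


def normalized_abundance(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Attach NSAF shares: (SpC/L) / sum over groups of (SpC/L)."""
    saf = [g.total_spectral_count / g.representative_length for g in groups]
    total = sum(saf)
    if total == 0:
        raise ValueError("zero total spectral count; cannot normalize")
    return [replace(g, nsaf=s / total) for g, s in zip(groups, saf)]


def rank_groups(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Descending NSAF; ties broken by total SpC, then by first member id."""
    if any(g.nsaf is None for g in groups):
        groups = normalized_abundance(groups)
    return sorted(
        groups,
        key=lambda g: (-g.nsaf, -g.total_spectral_count, g.members[0]),
    )


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero (18.25 -> 18, 31.75 -> 32)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class QuartileSummary:
    groups_recovered: int          # A
    multi_peptide_groups: int      # B
    top_quartile_size: int         # C = nearest-int(0.25 * B)
    cp_groups_in_top: int          # D
    pct_cp: float                  # E = 100 * D / C


def top_quartile_summary(
    groups: Sequence[ProteinGroup], cp_ids: set[str]
) -> QuartileSummary:
    """The final-pellet abundance summary.

    A = groups recovered; B = groups with more than one distinct peptide;
    C = nearest-integer(0.25 B); D = groups among the top C (ranked by
    NSAF) with at least one member in ``cp_ids``; E = 100 D / C.
    """
    a = len(groups)
    multi = [g for g in groups if g.distinct_peptides > 1]
    b = len(multi)
    if b == 0:
        raise ValueError("no protein groups with more than one peptide")
    c = round_half_away(0.25 * b)
    ranked = rank_groups(multi)
    top = ranked[:c]
    d = sum(1 for g in top if any(m in cp_ids for m in g.members))
    return QuartileSummary(
        groups_recovered=a,
        multi_peptide_groups=b,
        top_quartile_size=c,
        cp_groups_in_top=d,
        pct_cp=100.0 * d / c,
    )


def group_table(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    """Rank-ordered TSV-ready table of protein groups."""
    ranked = rank_groups(groups)
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "members": [";".join(g.members) for g in ranked],
            "distinct_peptides": [g.distinct_peptides for g in ranked],
            "total_spectral_count": [g.total_spectral_count for g in ranked],
            "representative_length": [g.representative_length for g in ranked],
            "nsaf": [g.nsaf for g in ranked],
        }
    )
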