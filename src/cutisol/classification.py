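"""Solubility-class assignment from replicate-filtered peptide evidence.

A (protein, fraction) pair is *accepted* when at least one peptide of the
protein was found in that fraction in at least two of the three biological
replicates (configurable).  Accepted fractions then decide the class:

* ``SOLUBLE_ONLY`` — accepted only in extract fractions;
* ``BOTH``         — accepted in extracts and in the final pellet;
* ``FP_ONLY``      — accepted only in the final pellet;
* ``INSUFFICIENT`` — observed, but no fraction passed the replicate rule.

A protein whose minority category has raw observations that fail the
replicate rule keeps its majority class but carries an ``exception`` flag
(the parenthesized entries of the solubility table).  Proteins identified
by three or more distinct peptides are flagged ``multi`` (the ``++``
strength); the rest are ``single``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .sequence_io import EvidenceTable, FractionScheme, ProteinRecord

CLASSES = ("SOLUBLE_ONLY", "BOTH", "FP_ONLY", "INSUFFICIENT")


@dataclass(frozen=True)
class SolubilityCall:
    protein_id: str
    solubility_class: str
    exception: bool
    strength: str  # "single" (+) | "multi" (++)
    accepted_fractions: frozenset[str]
    first_solubilizing_fraction: str | None
    distinct_peptides: int
    has_unique_evidence: bool

    def __post_init__(self) -> None:
        assert self.solubility_class in CLASSES
        assert (self.strength == "multi") == (self.distinct_peptides >= 3)


def replicate_filter(
    evidence: EvidenceTable,
    r_required: int = 2,
    level: str = "protein",
) -> set[tuple[str, str]]:
    """Accepted (protein, fraction) pairs under the replicate rule.

    ``level="protein"`` (default) accepts a pair when *any* peptide
    evidence for the protein appears in >= ``r_required`` distinct
    replicates of that fraction; ``level="peptide"`` requires a single
    peptide sequence to recur across replicates.  Scheme-excluded
    fractions never pass.
    """
    if r_required > evidence.n_replicates:
        raise ValueError(
            f"r_required={r_required} exceeds replicate count "
            f"{evidence.n_replicates}"
        )
    if level not in ("protein", "peptide"):
        raise ValueError(f"unknown replicate-rule level {level!r}")
    active = set(evidence.scheme.active_ids)
    reps: dict[tuple, set[int]] = {}
    for obs in evidence.observations:
        if obs.fraction not in active:
            continue
        for pid in obs.protein_ids:
            if level == "protein":
                key = (pid, obs.fraction)
            else:
                key = (pid, obs.fraction, obs.peptide)
            reps.setdefault(key, set()).add(obs.replicate)
    accepted = set()
    for key, replicates in reps.items():
        if len(replicates) >= r_required:
            accepted.add((key[0], key[1]))
    return accepted


def classify(
    evidence: EvidenceTable,
    r_required: int = 2,
    level: str = "protein",
    accepted: set[tuple[str, str]] | None = None,
) -> dict[str, SolubilityCall]:
    """Assign a solubility class to every protein with evidence.

    ``accepted`` may be supplied to reuse a precomputed replicate filter;
    otherwise it is derived from ``evidence`` with the given parameters.
    """
    scheme = evidence.scheme
    if accepted is None:
        accepted = replicate_filter(evidence, r_required, level)
    active = set(scheme.active_ids)
    fp = scheme.final_pellet_id
    extract_order = [f for f in scheme.extract_ids if f in active]

    raw_fractions: dict[str, set[str]] = {}
    peptides: dict[str, set[str]] = {}
    unique: dict[str, bool] = {}
    for obs in evidence.observations:
        if obs.fraction not in active:
            continue
        for pid in obs.protein_ids:
            raw_fractions.setdefault(pid, set()).add(obs.fraction)
            peptides.setdefault(pid, set()).add(obs.peptide)
            if len(obs.protein_ids) == 1:
                unique[pid] = True

    calls: dict[str, SolubilityCall] = {}
    for pid in sorted(raw_fractions):
        acc = frozenset(f for (p, f) in accepted if p == pid)
        acc_extract = {f for f in acc if f != fp}
        raw = raw_fractions[pid]
        if acc_extract and fp in acc:
            cls = "BOTH"
            exception = False
        elif acc_extract:
            cls = "SOLUBLE_ONLY"
            exception = fp in raw  # raw FP evidence failing the rule
        elif fp in acc:
            cls = "FP_ONLY"
            exception = bool((raw - {fp}))
        else:
            cls = "INSUFFICIENT"
            exception = False
        n_pep = len(peptides[pid])
        calls[pid] = SolubilityCall(
            protein_id=pid,
            solubility_class=cls,
            exception=exception,
            strength="multi" if n_pep >= 3 else "single",
            accepted_fractions=acc,
            first_solubilizing_fraction=next(
                (f for f in extract_order if f in acc), None
            ),
            distinct_peptides=n_pep,
            has_unique_evidence=unique.get(pid, False),
        )
    return calls


# ---------------------------------------------------------------------------
# Counting for contingency tables and the solubility-table output
# ---------------------------------------------------------------------------

def group_label(protein: ProteinRecord) -> str:
    """RR1 / RR2 / other pooling used throughout the statistics layer."""
    if protein.family == "CPR" and protein.cpr_group in ("RR1", "RR2"):
        return protein.cpr_group
    return "other"


@dataclass
class ClassCounts:
    """Contingency-ready class x group counts.

    ``table`` counts one unit per counted entity; sequence clusters whose
    members have only shared peptides are collapsed to a single unit and
    listed in ``collapsed_clusters``.  ``per_protein`` keeps the
    uncollapsed counts for comparison.
    """

    table: pd.DataFrame
    per_protein: pd.DataFrame
    collapsed_clusters: list[str] = field(default_factory=list)


def class_counts(
    calls: Mapping[str, SolubilityCall],
    proteins: Sequence[ProteinRecord],
    groups: tuple[str, ...] = ("RR1", "RR2", "other"),
) -> ClassCounts:
    """Counts per (solubility class x family group).

    ``INSUFFICIENT`` proteins are excluded (they are reported elsewhere but
    never enter association tests).
    """
    by_id = {p.id: p for p in proteins}
    classes = [c for c in CLASSES if c != "INSUFFICIENT"]
    per_protein = pd.DataFrame(0, index=classes, columns=list(groups))
    collapsed = pd.DataFrame(0, index=classes, columns=list(groups))
    seen_cluster_units: set[tuple[str, str]] = set()
    collapsed_clusters: list[str] = []
    for pid, call in calls.items():
        if call.solubility_class == "INSUFFICIENT":
            continue
        protein = by_id.get(pid)
        if protein is None:
            continue
        label = group_label(protein)
        if label not in groups:
            continue
        per_protein.loc[call.solubility_class, label] += 1
        if protein.cluster_id is not None and not call.has_unique_evidence:
            unit = (protein.cluster_id, call.solubility_class)
            if unit in seen_cluster_units:
                continue
            seen_cluster_units.add(unit)
            collapsed_clusters.append(protein.cluster_id)
        collapsed.loc[call.solubility_class, label] += 1
    return ClassCounts(
        table=collapsed,
        per_protein=per_protein,
        collapsed_clusters=sorted(set(collapsed_clusters)),
    )


def classification_table(
    calls: Mapping[str, SolubilityCall],
    proteins: Sequence[ProteinRecord],
    evidence: EvidenceTable,
) -> pd.DataFrame:
    """Solubility-table rows: per-fraction marks, class, strength, exception.

    ``+`` marks an accepted fraction, ``(+)`` a fraction with raw evidence
    that failed the replicate rule, empty no evidence.
    """
    scheme = evidence.scheme
    active = [f for f in scheme.ids if f not in scheme.excluded]
    raw: dict[tuple[str, str], bool] = {}
    for obs in evidence.observations:
        for pid in obs.protein_ids:
            raw[(pid, obs.fraction)] = True
    by_id = {p.id: p for p in proteins}
    rows = []
    for pid in sorted(calls):
        call = calls[pid]
        protein = by_id.get(pid)
        row: dict[str, object] = {
            "protein": pid,
            "family": protein.family if protein else "other",
            "group": group_label(protein) if protein else "other",
        }
        for fraction in active:
            if fraction in call.accepted_fractions:
                row[fraction] = "+"
            elif raw.get((pid, fraction)):
                row[fraction] = "(+)"
            else:
                row[fraction] = ""
        row["class"] = call.solubility_class
        row["strength"] = "++" if call.strength == "multi" else "+"
        row["exception"] = call.exception
        row["distinct_peptides"] = call.distinct_peptides
        row["first_solubilizing_fraction"] = (
            call.first_solubilizing_fraction or ""
        )
        rows.append(row)
    return pd.DataFrame(rows)
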