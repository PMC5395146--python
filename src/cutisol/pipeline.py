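"""End-to-end orchestration: run the full analysis and write report tables.

``run_pipeline`` reads the inputs (FASTA, metadata, evidence), classifies
each protein by solubility, computes sequence properties and coverage,
runs the association-test battery, summarizes by class, and ranks
final-pellet protein groups by normalized spectral counts.  Everything is
deterministic given the config and inputs; a run log records the config
and input hashes so a report bundle can be traced to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classification, coverage, seqprops, spectral, stats
from . import sequence_io
from .classification import SolubilityCall, group_label
from .sequence_io import EvidenceTable, ProteinRecord


@dataclass
class RunConfig:
    fasta: str
    evidence: str
    out_dir: str
    metadata: str | None = None
    mature: bool = False
    r_required: int = 2
    replicate_level: str = "protein"  # "protein" | "peptide"
    n_replicates: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def summarize_by_class(
    calls: Mapping[str, SolubilityCall],
    props: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """Per (class x group) summary: n, mean pI and H/Y/Q percentages.

    Alongside the all-protein means, a drop-most-extreme pI mean is
    reported (the value farthest from the cell median removed, cells of
    three or more only): the printed per-class summaries exclude a single
    outlier the same way, so both numbers are given rather than guessing
    which convention a reader wants.
    """
    by_id = {p.id: p for p in proteins}
    rows = []
    order = ["SOLUBLE_ONLY", "BOTH", "FP_ONLY"]
    groups = ["RR1", "RR2", "other"]
    for cls in order:
        for grp in groups:
            ids = [
                pid
                for pid, call in calls.items()
                if call.solubility_class == cls
                and pid in by_id
                and group_label(by_id[pid]) == grp
                and pid in props.index
            ]
            row: dict[str, object] = {"class": cls, "group": grp, "n": len(ids)}
            if ids:
                sub = props.loc[ids]
                row["mean_pI"] = round(float(sub["pI"].mean()), 2)
                for res in ("H", "Y", "Q"):
                    row[f"mean_pct_{res}"] = round(
                        float(sub[f"pct_{res}"].mean()), 1
                    )
                pis = sub["pI"].to_numpy()
                if len(pis) >= 3:
                    drop = int(np.argmax(np.abs(pis - np.median(pis))))
                    kept = np.delete(pis, drop)
                    row["n_excl_extreme"] = len(kept)
                    row["mean_pI_excl_extreme"] = round(float(kept.mean()), 2)
                else:
                    row["n_excl_extreme"] = len(pis)
                    row["mean_pI_excl_extreme"] = row["mean_pI"]
            rows.append(row)
    return pd.DataFrame(rows)


def run_associations(
    calls: Mapping[str, SolubilityCall],
    props: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """The association-test battery over classification and properties.

    Chi-square tests for family-vs-solubility and elastic-motif presence;
    one-way ANOVAs of each sequence property by solubility class and by
    family group; two-way (group x solubility) ANOVAs with interaction for
    the properties where the crossed design is estimable.  Raw p-values
    are reported side by side without multiplicity adjustment so users can
    correct as they see fit.
    """
    by_id = {p.id: p for p in proteins}
    frame_rows = []
    merged = []
    for pid, call in calls.items():
        if call.solubility_class == "INSUFFICIENT":
            continue
        if pid not in props.index or pid not in by_id:
            continue
        rec = props.loc[pid]
        merged.append(
            {
                "protein": pid,
                "class": call.solubility_class,
                "group": group_label(by_id[pid]),
                "pI": rec["pI"],
                "pct_H": rec["pct_H"],
                "pct_Y": rec["pct_Y"],
                "pct_Q": rec["pct_Q"],
                "length": rec["length"],
                "n_AAP_AVL": rec["n_AAP_AVL"],
            }
        )
    data = pd.DataFrame(merged)
    if data.empty:
        return pd.DataFrame(
            columns=["hypothesis", "test", "statistic", "df", "p"]
        )

    def record(hypothesis: str, result: stats.AssociationResult) -> None:
        frame_rows.append(
            {
                "hypothesis": hypothesis,
                "test": result.kind,
                "statistic": result.statistic,
                "df": "x".join(str(d) for d in result.df),
                "p": result.p_value,
                "warning": result.warning or "",
            }
        )

    def crosstab_test(hypothesis: str, col: str) -> None:
        tab = pd.crosstab(data["class"], data[col])
        tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            record(
                hypothesis,
                stats.chi_square(stats.ContingencyTable.from_dataframe(tab)),
            )

    crosstab_test("family_x_solubility", "group")
    data["has_AAP"] = np.where(data["n_AAP_AVL"] > 0, "yes", "no")
    crosstab_test("aap_presence_x_solubility", "has_AAP")

    for prop in ("pI", "pct_H", "pct_Y", "pct_Q", "length"):
        for factor, name in (("class", "solubility"), ("group", "family")):
            groups = {
                level: sub[prop].to_numpy()
                for level, sub in data.groupby(factor)
            }
            if len(groups) >= 2 and sum(len(v) for v in groups.values()) > len(groups):
                record(f"{prop}_by_{name}", stats.anova_oneway(groups))
        # crossed model needs >1 level of each factor and residual df
        if data["class"].nunique() >= 2 and data["group"].nunique() >= 2:
            try:
                results = stats.anova_twoway(
                    data, prop, "group", "class", interaction=True
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            for term, result in results.items():
                record(f"{prop}__{term}", result)
    aap_by_family = {
        level: sub["n_AAP_AVL"].to_numpy() for level, sub in data.groupby("group")
    }
    if len(aap_by_family) >= 2:
        record("aap_count_by_family", stats.anova_oneway(aap_by_family))
    return pd.DataFrame(frame_rows)


def coverage_table(reports: Mapping[str, coverage.CoverageReport]) -> pd.DataFrame:
    rows = []
    for pid in sorted(reports):
        rep = reports[pid]
        rows.append(
            {
                "protein": pid,
                "length": rep.length,
                "coverage_fraction": round(rep.coverage_fraction, 4),
                "covered_intervals": ";".join(
                    f"{s}-{e}" for s, e in rep.covered
                ),
                "nterm_recovered": rep.nterm_recovered,
                "longest_recovered_peptide": rep.longest_recovered_peptide,
                "n_peptides": rep.n_peptides,
                "n_unique_peptides": rep.n_unique_peptides,
                "domains_overlapped": sum(
                    d.overlapped for d in rep.domain_coverage
                ),
                "n_domains": len(rep.domain_coverage),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report tables in memory keyed by name.  Any stage failure
    propagates with the stage named in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    proteins = stage("sequence_io", lambda: sequence_io.read_fasta(config.fasta))
    if config.metadata:
        def _merge():
            merged, unknown = sequence_io.read_metadata(config.metadata, proteins)
            for pid in unknown:
                warnings.append(f"metadata id {pid} not in FASTA")
            return merged
        proteins = stage("sequence_io", _merge)
    evidence = stage(
        "sequence_io",
        lambda: sequence_io.read_evidence(
            config.evidence,
            proteins=proteins,
            n_replicates=config.n_replicates,
        ),
    )
    warnings.extend(evidence.warnings)
    if evidence.unknown_protein_ids:
        raise RuntimeError(
            f"pipeline stage 'sequence_io' failed: evidence references "
            f"proteins absent from FASTA: "
            f"{sorted(evidence.unknown_protein_ids)[:5]}"
        )

    calls = stage(
        "classification",
        lambda: classification.classify(
            evidence, r_required=config.r_required, level=config.replicate_level
        ),
    )
    props = stage(
        "seqprops",
        lambda: seqprops.properties_table(proteins, mature=config.mature),
    )
    reports = stage(
        "coverage_mapping", lambda: coverage.map_coverage(evidence, proteins)
    )

    tables: dict[str, pd.DataFrame] = {}
    tables["classification"] = classification.classification_table(
        calls, proteins, evidence
    )
    tables["properties"] = props.reset_index()
    tables["class_summary"] = summarize_by_class(calls, props, proteins)
    tables["associations"] = stage(
        "association_stats", lambda: run_associations(calls, props, proteins)
    )
    tables["coverage"] = coverage_table(reports)

    fp = evidence.scheme.final_pellet_id
    fp_obs = [o for o in evidence.observations if o.fraction == fp]
    if fp_obs:
        lengths = {p.id: p.length for p in proteins}
        cp_ids = {p.id for p in proteins if p.family != "other"}
        def _spectral():
            groups = spectral.normalized_abundance(
                spectral.group_by_shared_peptides(fp_obs, lengths)
            )
            summary = spectral.top_quartile_summary(groups, cp_ids)
            tables["spectral_groups"] = spectral.group_table(groups)
            return pd.DataFrame([dataclasses.asdict(summary)])
        tables["spectral_summary"] = stage("spectral_counts", _spectral)

    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    log = {
        "config": dataclasses.asdict(config),
        "inputs": {
            "fasta_sha256": _sha256(config.fasta),
            "evidence_sha256": _sha256(config.evidence),
            **(
                {"metadata_sha256": _sha256(config.metadata)}
                if config.metadata
                else {}
            ),
        },
        "n_proteins": len(proteins),
        "n_observations": len(evidence.observations),
        "n_excluded_observations": len(evidence.excluded),
        "warnings": warnings,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return tables
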