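"""Synthetic proteomes and serial-extraction evidence with planted truth.

The generator emulates the statistical structure of the adult-mosquito
serial-extraction study so that every pipeline stage can be exercised
without external data: three biological replicates; the ordered PBS /
EDTA / 2-4-8 M urea / SDS / final-pellet fraction scheme; planted
solubility classes in the observed proportions (13 soluble-only, 11 both,
48 final-pellet-only) with class-dependent composition gradients (acidic,
histidine-poor soluble proteins; basic, histidine- and tyrosine-rich
final-pellet proteins); elastic AAP[A/V/L] repeats concentrated in the
insoluble classes; HH pairs and QQQQ runs; and RR-2 sequence clusters
whose members share every peptide.

Peptides are sampled from the true tryptic digest (0-2 missed cleavages),
so digestion and coverage logic downstream see realistic input.  All
randomness flows through one seeded generator: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sequence_io
from .digestion import tryptic_digest
from .sequence_io import (
    EvidenceTable,
    FractionScheme,
    PeptideObservation,
    ProteinRecord,
    default_scheme,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional sequence and detection model.

    ``residue_freq`` drives i.i.d. residue sampling (adjusted residue
    sampling keeps composition targets verifiable on the output);
    ``detect`` gives per-fraction peptide detection probabilities applied
    independently per replicate; motif/cluster rates are Poisson means of
    insertions per protein.
    """

    residue_freq: Mapping[str, float]
    detect: Mapping[str, float]
    aap_rate: float = 0.0
    gyr_rate: float = 0.0
    ylp_rate: float = 0.0
    h_cluster_rate: float = 0.0
    q_run_rate: float = 0.0


@dataclass(frozen=True)
class CohortEntry:
    family: str
    cpr_group: str
    planted_class: str
    n: int


@dataclass(frozen=True)
class SyntheticConfig:
    cohort: tuple[CohortEntry, ...]
    profiles: Mapping[str, ClassProfile]
    seed: int
    length_range: tuple[int, int] = (80, 250)
    peptides_per_protein: float = 5.0
    dropout: float = 0.0
    n_replicates: int = 3
    n_clusters: int = 2
    cluster_size: int = 3
    spectral_count_mean: float = 2.0

    def __post_init__(self) -> None:
        for profile in self.profiles.values():
            for p in profile.detect.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("detection probabilities must be in [0,1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0,1]")


def _freqs(pct_h, pct_y, pct_q, pct_acidic, pct_basic) -> dict[str, float]:
    """Residue frequencies hitting the stated composition targets.

    Targets are percentages for H, Y, Q, the acidic pool (D+E, split
    evenly) and the basic pool (K+R, biased toward K so tryptic peptides
    stay short); the remainder is spread over neutral residues in
    cuticle-protein-like proportions (A/G/S/P-rich, C/W-poor).
    """
    freq = {
        "H": pct_h,
        "Y": pct_y,
        "Q": pct_q,
        "D": pct_acidic / 2,
        "E": pct_acidic / 2,
        "K": pct_basic * 0.6,
        "R": pct_basic * 0.4,
    }
    neutral_weights = {
        "A": 3.0, "G": 2.5, "S": 2.0, "P": 2.0, "V": 1.5, "L": 1.5,
        "N": 1.0, "T": 1.0, "F": 0.8, "I": 0.8, "M": 0.3, "W": 0.1,
        "C": 0.1,
    }
    rest = 100.0 - sum(freq.values())
    if rest <= 0:
        raise ValueError("infeasible composition: targets exceed 100%")
    wsum = sum(neutral_weights.values())
    for res, w in neutral_weights.items():
        freq[res] = rest * w / wsum
    return {res: freq.get(res, 0.0) / 100.0 for res in _AA}


def default_config(seed: int, dropout: float = 0.0) -> SyntheticConfig:
    """The study conditions: 72 proteins in the observed class/family mix.

    Composition targets follow the per-class gradients of the solubility
    summary (soluble proteins acidic and histidine-poor, final-pellet
    proteins basic and histidine/tyrosine-rich); detection is certain in
    each class's planted fractions and zero elsewhere, with ``dropout``
    available as an independent per-replicate miss probability.
    """
    profiles = {
        "SOLUBLE_ONLY": ClassProfile(
            residue_freq=_freqs(1.3, 6.5, 7.0, 13.0, 8.0),
            detect={"urea2M": 1.0, "urea4M": 1.0, "urea8M": 1.0},
            aap_rate=0.0, gyr_rate=0.1, ylp_rate=0.1,
            h_cluster_rate=0.1, q_run_rate=0.1,
        ),
        "BOTH": ClassProfile(
            residue_freq=_freqs(3.6, 6.0, 6.5, 8.0, 9.0),
            detect={"urea8M": 1.0, "SDS": 1.0, "FP": 1.0},
            aap_rate=1.0, gyr_rate=0.2, ylp_rate=0.2,
            h_cluster_rate=0.4, q_run_rate=0.2,
        ),
        "FP_ONLY": ClassProfile(
            residue_freq=_freqs(5.0, 8.0, 4.0, 4.5, 11.0),
            detect={"FP": 1.0},
            aap_rate=1.5, gyr_rate=0.3, ylp_rate=0.3,
            h_cluster_rate=0.6, q_run_rate=0.3,
        ),
    }
    cohort = (
        CohortEntry("CPR", "RR1", "SOLUBLE_ONLY", 10),
        CohortEntry("CPR", "RR2", "SOLUBLE_ONLY", 3),
        CohortEntry("CPR", "RR1", "BOTH", 2),
        CohortEntry("CPR", "RR2", "BOTH", 4),
        CohortEntry("CPLCG", "not_applicable", "BOTH", 3),
        CohortEntry("CPAP3", "not_applicable", "BOTH", 1),
        CohortEntry("CPLCX", "not_applicable", "BOTH", 1),
        CohortEntry("CPR", "RR1", "FP_ONLY", 7),
        CohortEntry("CPR", "RR2", "FP_ONLY", 23),
        CohortEntry("CPLCG", "not_applicable", "FP_ONLY", 4),
        CohortEntry("CPLCP", "not_applicable", "FP_ONLY", 3),
        CohortEntry("TWDL", "not_applicable", "FP_ONLY", 2),
        CohortEntry("CPF", "not_applicable", "FP_ONLY", 2),
        CohortEntry("CPFL", "not_applicable", "FP_ONLY", 2),
        CohortEntry("CPLCA", "not_applicable", "FP_ONLY", 2),
        CohortEntry("CPLCX", "not_applicable", "FP_ONLY", 3),
    )
    return SyntheticConfig(cohort=cohort, profiles=profiles, seed=seed,
                           dropout=dropout)


@dataclass
class SyntheticBundle:
    proteins: list[ProteinRecord]
    truth: pd.DataFrame
    evidence: EvidenceTable
    scheme: FractionScheme


def _insert_motif(seq: list[str], motif: str, rng: np.random.Generator,
                  occupied: set[int]) -> None:
    """Overwrite a random non-overlapping window with the motif."""
    span = len(motif)
    if len(seq) <= span + 2:
        return
    for _ in range(10):  # a few placement attempts, then give up
        start = int(rng.integers(1, len(seq) - span))
        window = set(range(start, start + span))
        if not window & occupied:
            seq[start:start + span] = list(motif)
            occupied |= window
            return


def _generate_sequence(length: int, profile: ClassProfile,
                       rng: np.random.Generator) -> str:
    freqs = np.array([profile.residue_freq[a] for a in _AA])
    freqs = freqs / freqs.sum()
    seq = list(rng.choice(list(_AA), size=length, p=freqs))
    occupied: set[int] = set()
    for rate, make in (
        (profile.aap_rate, lambda: "AAP" + rng.choice(list("AVL"))),
        (profile.gyr_rate, lambda: "GYR"),
        (profile.ylp_rate, lambda: "YLP"),
        (profile.h_cluster_rate, lambda: "HH"),
        (profile.q_run_rate, lambda: "QQQQ"),
    ):
        for _ in range(int(rng.poisson(rate))):
            _insert_motif(seq, make(), rng, occupied)
    return "".join(seq)


def generate_proteome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteome + ground truth for the configured cohort.

    The ground-truth table records each protein's planted class, family,
    group, length and (recomputed) motif count, so tests can verify the
    generator against its own output.  RR-2 final-pellet proteins host the
    configured sequence clusters: cluster members get identical sequences
    so that every peptide is shared.
    """
    from .seqprops import motif_count  # local import avoids cycle at import time

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truth_rows = []
    family_counters: dict[str, int] = {}
    for entry in config.cohort:
        profile = config.profiles[entry.planted_class]
        for _ in range(entry.n):
            family_counters[entry.family] = family_counters.get(entry.family, 0) + 1
            pid = f"{entry.family}{family_counters[entry.family]}"
            length = int(rng.integers(config.length_range[0],
                                      config.length_range[1] + 1))
            seq = _generate_sequence(length, profile, rng)
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=seq,
                    family=entry.family,
                    cpr_group=entry.cpr_group,
                )
            )
            truth_rows.append(
                {
                    "protein": pid,
                    "family": entry.family,
                    "cpr_group": entry.cpr_group,
                    "planted_class": entry.planted_class,
                    "length": length,
                }
            )
    # Sequence clusters: identical RR-2 final-pellet sequences sharing all
    # peptides (mirrors paralog clusters with indistinguishable members).
    eligible = [
        i for i, row in enumerate(truth_rows)
        if row["cpr_group"] == "RR2" and row["planted_class"] == "FP_ONLY"
    ]
    needed = config.n_clusters * config.cluster_size
    if needed and len(eligible) >= needed:
        for c in range(config.n_clusters):
            cluster_id = f"CL{c + 1}"
            idxs = eligible[c * config.cluster_size:(c + 1) * config.cluster_size]
            master_seq = records[idxs[0]].sequence
            for i in idxs:
                records[i] = replace(
                    records[i], sequence=master_seq, cluster_id=cluster_id
                )
                truth_rows[i]["length"] = len(master_seq)
    truth = pd.DataFrame(truth_rows)
    truth["n_AAP_AVL"] = [
        motif_count(rec.sequence, "AAP_AVL") for rec in records
    ]
    return records, truth


def _sample_peptides(
    sequence: str, mean_peptides: float, rng: np.random.Generator
) -> list[str]:
    peptides = tryptic_digest(sequence, max_missed=2)
    candidates: list[str] = []
    seen: set[str] = set()
    # 6-55 aa: the detectable window of a typical bottom-up search
    for pep in peptides:
        if 6 <= len(pep.peptide) <= 55 and pep.peptide not in seen:
            seen.add(pep.peptide)
            candidates.append(pep.peptide)
    if not candidates:
        # sparse cleavage sites leave only long peptides; take the longest
        # rather than short promiscuous fragments
        candidates = [max((p.peptide for p in peptides), key=len)]
    k = max(1, int(rng.poisson(mean_peptides)))
    k = min(k, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def _gel_slice(fraction: str, rng: np.random.Generator) -> str:
    if fraction in ("urea8M", "SDS"):
        return str(rng.choice(list("ABCD")))
    if fraction == "FP":
        return "none"
    return "whole"


def generate_evidence(
    proteins: Sequence[ProteinRecord],
    truth: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> EvidenceTable:
    """Evidence table drawn from the planted detection model.

    For each protein a set of tryptic peptides is sampled; each peptide is
    then detected independently per (fraction, replicate) with probability
    ``detect[fraction] * (1 - dropout)``.  Peptides are attributed to every
    protein containing them, so cluster members share observations.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    scheme = default_scheme()
    planted = dict(zip(truth["protein"], truth["planted_class"]))
    sequences = [(p.id, p.sequence) for p in proteins]
    observations: list[PeptideObservation] = []
    emitted_for_cluster: set[str] = set()
    for protein in proteins:
        # one sampled peptide set per cluster (members are identical)
        if protein.cluster_id is not None:
            if protein.cluster_id in emitted_for_cluster:
                continue
            emitted_for_cluster.add(protein.cluster_id)
        profile = config.profiles[planted[protein.id]]
        peptides = _sample_peptides(
            protein.sequence, config.peptides_per_protein, rng
        )
        ids_for = {
            pep: frozenset(pid for pid, seq in sequences if pep in seq)
            for pep in peptides
        }
        for fraction, prob in profile.detect.items():
            p = prob * (1.0 - config.dropout)
            for rep in range(1, config.n_replicates + 1):
                for pep in peptides:
                    if rng.random() < p:
                        observations.append(
                            PeptideObservation(
                                peptide=pep,
                                protein_ids=ids_for[pep],
                                fraction=fraction,
                                replicate=rep,
                                gel_slice=_gel_slice(fraction, rng),
                                spectral_count=1 + int(
                                    rng.poisson(config.spectral_count_mean - 1)
                                ),
                            )
                        )
    return EvidenceTable(
        observations=observations,
        scheme=scheme,
        n_replicates=config.n_replicates,
    )


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Proteome + truth + evidence from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    proteins, truth = generate_proteome(config, rng)
    evidence = generate_evidence(proteins, truth, config, rng)
    return SyntheticBundle(
        proteins=proteins,
        truth=truth,
        evidence=evidence,
        scheme=evidence.scheme,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit the sequence_io file contracts plus the ground-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteome.fasta",
        "metadata": out / "metadata.tsv",
        "evidence": out / "evidence.tsv",
        "truth": out / "truth.tsv",
    }
    sequence_io.write_fasta(bundle.proteins, paths["fasta"])
    sequence_io.write_metadata(bundle.proteins, paths["metadata"])
    sequence_io.write_evidence(bundle.evidence, paths["evidence"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
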