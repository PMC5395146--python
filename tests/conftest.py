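import pytest
from hypothesis import HealthCheck, settings

from cutisol.sequence_io import (
    EvidenceTable,
    PeptideObservation,
    ProteinRecord,
    default_scheme,
)
from cutisol.synth import default_config, generate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def obs(peptide, proteins, fraction, replicate, gel_slice="whole", count=1):
    """Shorthand observation constructor used across test modules."""
    ids = frozenset([proteins] if isinstance(proteins, str) else proteins)
    return PeptideObservation(
        peptide=peptide,
        protein_ids=ids,
        fraction=fraction,
        replicate=replicate,
        gel_slice=gel_slice,
        spectral_count=count,
    )


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def toy_proteins():
    return [
        ProteinRecord(id="P1", sequence="MKAYDKRHHAQQQQAK", family="CPR",
                      cpr_group="RR1"),
        ProteinRecord(id="P2", sequence="AAAKGYRLLKYLPR", family="CPR",
                      cpr_group="RR2"),
        ProteinRecord(id="P3", sequence="MHHHKAAPAWWR", family="TWDL"),
    ]


def evidence_from(observations, scheme=None, n_replicates=3):
    return EvidenceTable(
        observations=list(observations),
        scheme=scheme or default_scheme(),
        n_replicates=n_replicates,
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic bundle under the default study conditions."""
    return generate_bundle(default_config(seed=11))
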