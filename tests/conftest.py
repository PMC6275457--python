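import pytest

from lgtscreen import SimConfig, generate_dataset
from lgtscreen.io import BlastHit, TaxonRecord, TaxonomyMap


def make_hit(query, subject, bitscore, evalue=1e-50, taxon=None):
    return BlastHit(
        query_id=query, subject_id=subject, percent_identity=50.0,
        alignment_length=200, mismatches=100, gap_opens=1,
        q_start=1, q_end=200, s_start=1, s_end=200,
        evalue=evalue, bitscore=bitscore, subject_taxon=taxon,
    )


@pytest.fixture(scope="session")
def taxmap():
    return TaxonomyMap({
        "Arthropoda_sp": TaxonRecord(True, "Arthropoda"),
        "Chordata_sp": TaxonRecord(True, "Chordata"),
        "Actinobacteria_sp": TaxonRecord(False, "Actinobacteria"),
        "Proteobacteria_sp": TaxonRecord(False, "Proteobacteria"),
        "Ascomycota_sp": TaxonRecord(False, "Ascomycota"),
    })


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic genome shared across tests."""
    return generate_dataset(SimConfig(seed=11))
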