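from importlib import resources
from pathlib import Path

import pytest

from somamut.drivers import load_driver_table
from somamut.knowledge import load_knowledge
from somamut.variants import PredictorCall, VariantClass, VariantRecord

DATA_DIR = Path(str(resources.files("somamut").joinpath("data")))

FIXTURE_TABLES = {
    "young-HGSOC": "drivers_young_hgsoc.tsv",
    "elderly-HGSOC": "drivers_elderly_hgsoc.tsv",
    "young-TNBC": "drivers_young_tnbc.tsv",
    "elderly-TNBC": "drivers_elderly_tnbc.tsv",
}


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def kb():
    return load_knowledge(DATA_DIR)


@pytest.fixture(scope="session")
def fixture_profiles(kb):
    """Per-cohort driver profiles from the bundled published driver tables."""
    return {
        group: load_driver_table(DATA_DIR / fname, kb)
        for group, fname in FIXTURE_TABLES.items()
    }


def make_record(
    sample_id="S1",
    gene="GENE1",
    variant_class=VariantClass.MISSENSE,
    votes=(),
    ref="C",
    alt="T",
    context="ACA",
    protein_change="",
    splice_offset=None,
):
    """Convenience builder: ``votes`` lists the pathogenic/benign slots,
    remaining slots are missing."""
    calls = tuple(votes) + (PredictorCall.MISSING,) * (5 - len(votes))
    return VariantRecord(
        sample_id=sample_id,
        gene=gene,
        variant_class=variant_class,
        ref_allele=ref,
        alt_allele=alt,
        trinucleotide_context=context,
        predictor_calls=calls,
        protein_change=protein_change,
        splice_offset=splice_offset,
    )


@pytest.fixture
def record_builder():
    return make_record
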