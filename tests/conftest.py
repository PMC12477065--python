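import pytest

from proteohet import synth, variantdb


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused by read-only tests."""
    cfg = synth.SynthConfig(
        n_patients=6,
        n_genes=40,
        n_snv=30,
        n_inframe_indel=8,
        n_frameshift_indel=8,
        seed=11,
    )
    return synth.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_db(small_cohort):
    records = [
        r
        for s in small_cohort.samples["sample_id"]
        for r in small_cohort.variant_records[s]
    ]
    return variantdb.build_cohort_db(records)


@pytest.fixture
def toy_transcript():
    # MKT GFE ... simple 8-codon CDS
    return variantdb.TranscriptModel("G1", "G1.t1", "ATGAAAACCGGATTTGAAAGATGA")
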