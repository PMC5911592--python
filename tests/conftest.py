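import numpy as np
import pytest

from panelburden.transcripts import Domain, TranscriptModel
from panelburden.reference import fixture_cohort
from panelburden.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def toy_tx() -> TranscriptModel:
    """3-exon plus-strand toy: exons 101-200/301-420/521-640, CDS t31..t330.

    CDS length 300 nt (protein 99 aa); coding spans per exon are
    1-70 / 71-190 / 191-300, so the NMD-escape zone is [136, 300].
    """
    return TranscriptModel(
        gene_symbol="GENE1",
        transcript_id="TX1",
        chrom="chr1",
        strand="+",
        exons=((101, 200), (301, 420), (521, 640)),
        cds_start_genomic=131,
        cds_end_genomic=630,
        domains=(Domain("DOM1", 60, 70),),
    )


@pytest.fixture(scope="session")
def toy_cds() -> str:
    """Coding sequence for the toy transcript; codon 17 is TGG (one
    substitution from a stop), everything else alternates CTG/GAA."""
    codons = ["ATG"]
    for i in range(2, 100):
        codons.append("TGG" if i == 17 else ("CTG" if i % 2 else "GAA"))
    codons.append("TAA")
    seq = "".join(codons)
    assert len(seq) == 300
    return seq


@pytest.fixture(scope="session")
def fixture():
    """The deterministic pseudo-cohort reproducing the published margins."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def sim_cohort():
    """One study-scale simulated cohort shared across tests."""
    return simulate_cohort(default_config(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
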