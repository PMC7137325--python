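import numpy as np
import pytest

from eclip_atlas import family_quant, simulate
from eclip_atlas.core_io import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimConfig(seed=11, n_families=3, pseudogenes_per_family=2,
                              depth=2000, per_base_error_rate=0.0,
                              n_genes=4)


@pytest.fixture(scope="session")
def famdb(small_cfg):
    return simulate.build_family_database(small_cfg)


@pytest.fixture(scope="session")
def genome(small_cfg, famdb):
    return simulate.simulate_genome_annotation(small_cfg, famdb)


@pytest.fixture(scope="session")
def library(small_cfg, famdb, genome):
    return simulate.simulate_eclip_library(small_cfg, famdb, genome)


@pytest.fixture(scope="session")
def scoring_params():
    return family_quant.ScoringParams()


@pytest.fixture()
def coding_model():
    """+-strand two-exon gene: exons [0,100) and [200,300),
    CDS genomic span [20, 280) -> UTR5 20 nt, UTR3 20 nt."""
    return TranscriptModel(
        "gA", "gA-tx1", "chr1", "+",
        [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)],
        cds_span=(20, 280), tpm=5.0)


def random_alignment_record(rng, read_id="r1_ACGT"):
    n_mm = int(rng.integers(0, 5))
    n_gap = int(rng.integers(0, 3))
    length = 50
    return family_quant.AlignmentRecord(
        read_id, 1, "t1", "family_transcript", 0, length, "+",
        mismatches=[(int(rng.integers(0, length)), int(rng.integers(0, 42)))
                    for _ in range(n_mm)],
        gaps=[int(rng.integers(1, 6)) for _ in range(n_gap)])
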