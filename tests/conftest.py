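import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bivalentscope.genomic_core import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
)
from bivalentscope.synthetic_data import (
    SimConfig,
    generate_annotation,
    generate_tracks,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_gene(gene_id="g1", chrom="chr1", start=1000, end=5000, strand="+", exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = (GenomicInterval(chrom, start, end, strand),)
    return GeneModel(gene_id, iv, exons)


@pytest.fixture
def uniform_track():
    """Coverage 2.0 over chr1:[0, 100000)."""
    return SignalTrack.from_intervals(
        [("chr1", 0, 100_000, 2.0)], {"chr1": 100_000}
    )


@pytest.fixture
def empty_track():
    return SignalTrack({}, {"chr1": 100_000})


@pytest.fixture(scope="session")
def small_sim():
    """120-gene synthetic dataset at default noise, shared across tests."""
    config = SimConfig(seed=7, n_genes=120)
    annotation = generate_annotation(config)
    data = generate_tracks(annotation, config)
    return config, annotation, data


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """On-disk bundle for a small synthetic dataset."""
    from bivalentscope.synthetic_data import emit_fixture

    out = tmp_path_factory.mktemp("fixture")
    config = SimConfig(seed=7, n_genes=120)
    manifest = emit_fixture(config, out)
    return config, out, manifest


def random_peakset(rng, n, chrom="chr1", span=10_000, max_len=400, source="x"):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return PeakSet(
        [GenomicInterval(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)],
        source=source,
    )
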