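import numpy as np
import pytest
from hypothesis import settings

from apakit import GenomeSequence, Site, SiteSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
    g = GenomeSequence()
    g["chr1"] = seq
    return g


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="genome.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def bed_file(tmp_path):
    def _write(text, name="sites.bed"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_sites(*triples, contig="chr1"):
    """(start, end, strand) triples -> SiteSet with generated names."""
    return SiteSet(
        [
            Site(contig, s, e, f"s{i}", 0.0, strand)
            for i, (s, e, strand) in enumerate(triples)
        ]
    )
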