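import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quadchip import Genome, GenomicInterval, Peak

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dna(rng: np.random.Generator, length: int, probs=(0.25, 0.25, 0.25, 0.25),
               bases="ACGT") -> str:
    return "".join(np.asarray(list(bases))[rng.choice(len(bases), size=length, p=list(probs))])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Two chromosomes with hand-placed telomeric units and a PG4 motif."""
    chr1 = ("ACGTACGTAC" * 10) + "GGGTTAGGGTTAGGGTTAGGG" + ("TTCAGCATCA" * 10)
    chr2 = "AATTAGGGCC" + ("ATCG" * 20) + "CCCTAACC"
    return Genome({"chr1": chr1, "chr2": chr2})


def make_peak(chrom, start, end, name=""):
    return Peak(GenomicInterval(chrom, start, end), name=name)
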