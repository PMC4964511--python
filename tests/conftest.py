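import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codonbias import CdsRecord, standard_code

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def make_record():
    """Build a CdsRecord whose coding codons are exactly the given list
    (a terminal stop is appended so composition sees only the list)."""

    def _make(codons, gene_id="g", stop="TAA"):
        return CdsRecord(id=gene_id, seq="".join(codons) + stop)

    return _make


@pytest.fixture
def random_count_tables(code):
    """Factory for random per-gene codon count tables (seeded)."""
    from codonbias import CodonCountTable

    def _make(n_tables, seed=0, lam=3.0):
        rng = np.random.default_rng(seed)
        sense = code.sense_codons
        out = []
        for _ in range(n_tables):
            counts = dict(zip(sense, rng.poisson(lam, len(sense))))
            out.append(CodonCountTable(counts))
        return out

    return _make
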