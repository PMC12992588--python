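import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rappmotif.io_formats import ProteinRecord, Proteome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_proteome(sequences, genome_id="g1", clade="CladeA"):
    return Proteome(
        genome_id,
        clade,
        [ProteinRecord(f"{genome_id}_p{i}", genome_id, s) for i, s in enumerate(sequences, 1)],
    )


@pytest.fixture
def tiny_proteome():
    return make_proteome(["ARAPPA", "RAPP"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_proteome(rng, n_proteins, min_len=4, max_len=60, alphabet="ACDEFGHIKLMNPQRSTVWY", genome_id="rand"):
    seqs = []
    letters = list(alphabet)
    for _ in range(n_proteins):
        L = int(rng.integers(min_len, max_len + 1))
        seqs.append("".join(rng.choice(letters, size=L)))
    return make_proteome(seqs, genome_id=genome_id)
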