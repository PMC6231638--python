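import numpy as np
import pytest

from ripdecay.records import TranscriptRecord
from ripdecay.simulate import SimulationConfig, generate_transcripts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_transcripts=20,
        utr_length_range=(100, 300),
        planted_fraction=0.5,
        motif="UUUAA",
        motif_copies=3,
        noise_cv=0.1,
        seed=7,
    )


@pytest.fixture
def small_records(small_config):
    return generate_transcripts(small_config)


@pytest.fixture
def toy_record():
    # 30 nt 5'UTR-less toy: cds 1-9 (incl. stop), 6 nt 3'UTR
    return TranscriptRecord(
        transcript_id="tx1",
        gene_symbol="G1",
        sequence="AUGGCCUAAGUUAAC",
        cds=(1, 9),
    )


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
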