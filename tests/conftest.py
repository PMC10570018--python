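import random

import pytest

from mircds.io import MiRNA, TranscriptModel


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


def make_transcript(
    tx_id: str, seq: str, utr5_len: int, cds_len: int
) -> TranscriptModel:
    """Transcript with regions partitioned [utr5 | cds | utr3] over ``seq``."""
    return TranscriptModel(
        id=tx_id,
        seq=seq,
        utr5=(0, utr5_len),
        cds=(utr5_len, utr5_len + cds_len),
        utr3=(utr5_len + cds_len, len(seq)),
        cds_complete=cds_len % 3 == 0,
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20230731)


@pytest.fixture
def mirna22(rng) -> MiRNA:
    return MiRNA("miR-t22", random_rna(rng, 22))
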