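import numpy as np
import pandas as pd
import pytest

from lncwhiten import SyntheticSpec, generate_dataset
from lncwhiten.model import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study at a fixed seed, shared across tests."""
    return generate_dataset(SyntheticSpec(), seed=11)


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    """The default bundle written to disk in standard formats."""
    out = tmp_path_factory.mktemp("bundle")
    paths = default_bundle.write(out)
    return paths


def random_transcript(rng: np.random.Generator, tid: str, chrom: str = "chr1",
                      max_exons: int = 5) -> TranscriptModel:
    """A structurally valid random transcript for round-trip tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.integers(2) else "-"
    pos = int(rng.integers(0, 10_000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(30, 2_000))
    return TranscriptModel(tid, f"G_{tid}", chrom, strand, tuple(exons))


@pytest.fixture
def tiny_expression():
    """A 4-feature x 4-sample TPM matrix over two stages."""
    from lncwhiten.model import ExpressionMatrix

    values = pd.DataFrame(
        {
            "s1": [10.0, 0.0, 5.0, 1.0],
            "s2": [12.0, 0.05, 4.0, 1.0],
            "s3": [1.0, 0.0, 6.0, 1.0],
            "s4": [2.0, 0.08, 5.5, 1.0],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    metadata = pd.DataFrame(
        {"stage": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]},
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, "TPM", metadata)
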