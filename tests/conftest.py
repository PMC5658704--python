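import io

import numpy as np
import pandas as pd
import pytest

from rslscreen.library import GuideLibrary


def make_fastq(reads: list[tuple[str, str]]) -> io.StringIO:
    """Build an in-memory FASTQ from (read_id, sequence) pairs."""
    chunks = [f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n" for rid, seq in reads]
    return io.StringIO("".join(chunks))


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Three targeting guides over two genes plus one non-targeting control."""
    return GuideLibrary.from_records(
        [
            ("guideA", "ACGTACGTACGTACGTACGT", "GENE1", False),
            ("guideB", "TTTTCCCCGGGGAAAATTTT", "GENE1", False),
            ("guideC", "GGGGGGGGGGCCCCCCCCCC", "GENE2", False),
            ("ctrl1", "ATATATATATATATATATAT", "NonTargeting", True),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170834)


@pytest.fixture
def random_matrix(rng) -> pd.DataFrame:
    """200 random (guide, rsl) rows with integer counts, some zeros."""
    bases = np.array(list("ACGT"))
    rsls = ["".join(r) for r in rng.choice(bases, size=(200, 6))]
    return pd.DataFrame(
        {
            "guide_id": [f"g{i % 20:02d}" for i in range(200)],
            "rsl": rsls,
            "control": rng.integers(0, 50, size=200),
            "treatment": rng.integers(0, 50, size=200),
        }
    ).drop_duplicates(["guide_id", "rsl"]).reset_index(drop=True)
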