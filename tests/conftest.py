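import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mrmrsig.datamodel_io import NEGATIVE, POSITIVE, ExpressionMatrix


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with balanced binary labels."""
    rng = np.random.default_rng(42)
    sample_ids = ["s1", "s2", "s3", "s4"]
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=sample_ids,
        values=rng.normal(size=(3, 4)),
        labels={"s1": POSITIVE, "s2": POSITIVE, "s3": NEGATIVE, "s4": NEGATIVE},
    )


@pytest.fixture
def separable_matrix():
    """Two well-separated Gaussian clouds, 10+10 samples, 4 genes."""
    rng = np.random.default_rng(7)
    n_pos, n_neg = 10, 10
    shift = np.r_[np.full(n_pos, 4.0), np.full(n_neg, -4.0)]
    values = rng.normal(size=(4, n_pos + n_neg)) + shift
    sample_ids = [f"s{i:02d}" for i in range(n_pos + n_neg)]
    labels = {s: (POSITIVE if i < n_pos else NEGATIVE) for i, s in enumerate(sample_ids)}
    return ExpressionMatrix(["g1", "g2", "g3", "g4"], sample_ids, values, labels)


def write_tsv(path, text):
    Path(path).write_text(text)
    return path
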