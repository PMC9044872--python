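import numpy as np
import pandas as pd
import pytest

from srtkit import ExpressionMatrix, TypeProfile


def make_matrix(values, transcript_ids, sample_ids, types, contexts=None):
    """Small-matrix builder used throughout the suite."""
    if contexts is None:
        contexts = ["tissue"] * len(sample_ids)
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=transcript_ids, columns=sample_ids),
        pd.Series(dict(zip(sample_ids, types))),
        pd.Series(dict(zip(sample_ids, contexts))),
    )


def make_profile(values, transcript_ids, type_labels, **kw):
    return TypeProfile(
        pd.DataFrame(np.asarray(values, dtype=float), index=transcript_ids, columns=type_labels),
        **kw,
    )


@pytest.fixture
def tiny_matrix():
    """3 transcripts x 4 samples over 2 types."""
    return make_matrix(
        [[1.0, 2.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 0.0, 0.0]],
        ["t1", "t2", "t3"],
        ["s1", "s2", "s3", "s4"],
        ["liver", "liver", "testis", "testis"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
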