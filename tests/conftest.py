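import numpy as np
import pandas as pd
import pytest

from xorgan.exprio import ExpressionMatrix, GeneLengths, Unit
from xorgan.homology import AlignmentHit


def make_matrix(values, unit=Unit.FPKM, organ_of=None, species="sp",
                genes=None, samples=None):
    """Build an ExpressionMatrix from a 2-D array or dict of columns."""
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        arr = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(arr.shape[0])]
        samples = samples or [f"s{j}" for j in range(arr.shape[1])]
        df = pd.DataFrame(arr, index=genes, columns=samples)
    if organ_of is None:
        organ_of = {s: f"organ_{s}" for s in df.columns}
    return ExpressionMatrix(df, unit, species, organ_of)


def make_hit(query, subject, bitscore, evalue=1e-10, identity=50.0,
             length=100):
    return AlignmentHit(query=query, subject=subject, pct_identity=identity,
                        align_len=length, evalue=evalue, bitscore=bitscore)


def random_hits(rng, n_queries=10, n_subjects=8, n_hits=40):
    """Random hit table; bitscores drawn continuously so ties are rare."""
    hits = []
    for _ in range(n_hits):
        hits.append(make_hit(
            query=f"q{rng.integers(n_queries)}",
            subject=f"s{rng.integers(n_subjects)}",
            bitscore=float(rng.uniform(30, 300)),
            evalue=float(10.0 ** -rng.uniform(3, 60)),
            identity=float(rng.uniform(20, 100)),
        ))
    return hits


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def lengths3():
    return GeneLengths({"g0": 500, "g1": 1000, "g2": 2000})


@pytest.fixture
def counts_one_sample():
    return make_matrix([[10.0], [20.0], [0.0]], unit=Unit.COUNTS,
                       organ_of={"s0": "organ"})
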