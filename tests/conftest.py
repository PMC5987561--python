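import numpy as np
import pandas as pd
import pytest

from polydam.hmm import HMMParams
from polydam.normalize import NormalizedProfile


def make_fragments(starts, ends, chrom="chr1"):
    """Fragment index DataFrame from explicit interval lists."""
    if isinstance(chrom, str):
        chrom = [chrom] * len(starts)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    df["id"] = np.arange(len(df), dtype=np.int64)
    first = df.groupby("chrom")["id"].transform("min")
    last = df.groupby("chrom")["id"].transform("max")
    df["end_flank"] = (df["id"] == first) | (df["id"] == last)
    return df


def tiling_fragments(n, size=100, chrom="chr1"):
    """n adjacent fragments of equal size on one chromosome."""
    starts = np.arange(n) * size
    return make_fragments(starts, starts + size, chrom)


@pytest.fixture
def simple_params():
    return HMMParams(
        mu=np.array([-1.5, 0.0, 1.5]),
        sigma=np.array([0.5, 0.5, 0.5]),
        pi=np.array([0.3, 0.3, 0.4]),
        p0=0.9,
        L=2000.0,
    )


def profile_from(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), dtype=bool)
    return NormalizedProfile(values, mask)
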