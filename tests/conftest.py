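import numpy as np
import pytest

from mdlseg import ChromSites, MethylomeTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def step_series():
    """The canonical two-level step: split cost 0, unsplit cost 1.5."""
    return np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])


def make_track(positions, meth, total, chrom="chr1"):
    return MethylomeTrack(
        chroms={chrom: ChromSites(np.asarray(positions), np.asarray(meth), np.asarray(total))}
    )


@pytest.fixture
def small_track():
    """10 CpGs on one chromosome, mixed coverage."""
    pos = np.arange(10) * 100 + 50
    total = np.array([12, 4, 8, 10, 3, 20, 6, 9, 15, 5])
    meth = np.array([10, 2, 8, 1, 0, 18, 3, 9, 2, 5])
    return make_track(pos, meth, total)
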