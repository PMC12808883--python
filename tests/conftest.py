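import numpy as np
import pytest

from glucocest import SequenceParams, cardiac_tissue
from glucocest.pipeline import ProcessedZSpectrum


@pytest.fixture(scope="session")
def seq():
    """Default cardiac saturation scheme (cumulative mode)."""
    return SequenceParams()


@pytest.fixture(scope="session")
def cardiac_10mM():
    return cardiac_tissue(10.0)


def make_processed(fn, lo=-5.0, hi=5.0, n=4001, **kw) -> ProcessedZSpectrum:
    """Build a ProcessedZSpectrum directly from a callable z(ppm)."""
    grid = np.linspace(lo, hi, n)
    return ProcessedZSpectrum(
        offsets_ppm=grid, z_values=fn(grid), b0_corrected=True, **kw
    )
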