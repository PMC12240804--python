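import numpy as np
import pytest

from regrowage.stack_io import AnnualClassStack, ClassCode, GeoRef

U = int(ClassCode.UNDISTURBED)
D = int(ClassCode.DEGRADED)
N = int(ClassCode.NONFOREST)
R = int(ClassCode.REGROWTH)
P = int(ClassCode.PLANTATION)
W = int(ClassCode.WATER)
ND = int(ClassCode.NODATA)

GEOREF = GeoRef((30.0, 0.0, 0.0, 0.0, -30.0, 0.0), "synthetic")


def make_stack(grid, first_year=1990, pixel_area=0.09, georef=GEOREF):
    """Stack from an (n_years, rows, cols) class-code array."""
    grid = np.asarray(grid, dtype=np.uint8)
    years = np.arange(first_year, first_year + grid.shape[0])
    return AnnualClassStack(years, grid, georef, pixel_area)


def stack_from_sequences(sequences, first_year=1990):
    """Stack whose pixels are the given per-year class sequences (one row)."""
    arr = np.asarray(sequences, dtype=np.uint8).T  # (n_years, n_pixels)
    return make_stack(arr[:, None, :], first_year=first_year)


def oracle_age(seq, min_run=3, min_gap=3):
    """Independent per-pixel reference for the age rule (direct scan).

    Terminal REGROWTH run length if the run is long enough and the most
    recent NONFOREST block before it is long enough (or the run/block is
    left-censored at the window start); else 0.
    """
    seq = list(map(int, seq))
    n = len(seq)
    if seq[-1] != R:
        return 0
    i, run = n - 1, 0
    while i >= 0 and seq[i] == R:
        run += 1
        i -= 1
    if run < min_run:
        return 0
    if i < 0:
        return run
    while i >= 0 and seq[i] != N:
        i -= 1
    gap = 0
    while i >= 0 and seq[i] == N:
        gap += 1
        i -= 1
    if gap >= min_gap or (gap > 0 and i < 0):
        return run
    return 0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
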