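import numpy as np
import pytest

from rxntriage.chemspace import BuildingBlock, Formula, Role
from rxntriage.nmrproc import NmrSpectrum


@pytest.fixture
def supra_blocks():
    from rxntriage.synthgen import default_supramolecular_blocks

    return default_supramolecular_blocks()


@pytest.fixture
def divergent_blocks():
    from rxntriage.synthgen import default_divergent_blocks

    return default_divergent_blocks()


@pytest.fixture
def counterion():
    return BuildingBlock("X", Role.COUNTERION, Formula("CF3O3S"), charge=-1)


def lorentzian_spectrum(
    peaks,
    lo: float = 0.0,
    hi: float = 12.0,
    step: float = 0.002,
    field_mhz: float = 80.0,
    masked=(),
) -> NmrSpectrum:
    """Noiseless sum of Lorentzians; peaks = [(ppm, height, fwhm_hz), ...]."""
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    y = np.zeros_like(grid)
    for ppm, h, fwhm_hz in peaks:
        gamma = (fwhm_hz / field_mhz) / 2.0
        y += h * gamma**2 / ((grid - ppm) ** 2 + gamma**2)
    return NmrSpectrum(grid, y, field_mhz=field_mhz, masked_regions=list(masked))


def dtw_reference(a, b, band=None):
    """Pure-Python DTW dynamic program (the independent oracle).

    Mirrors the production band geometry (centre at i*m/n) when band is set.
    """
    import math

    n, m = len(a), len(b)
    D = [[math.inf] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        if band is None:
            jlo, jhi = 1, m
        else:
            centre = int(round(i * m / n))
            jlo, jhi = max(1, centre - band), min(m, centre + band)
        for j in range(jlo, jhi + 1):
            c = abs(a[i - 1] - b[j - 1])
            D[i][j] = c + min(D[i - 1][j], D[i][j - 1], D[i - 1][j - 1])
    return D[n][m]
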