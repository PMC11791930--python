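import numpy as np
import pytest

from prism_ms import msio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(coords, spectra, pixel_size=20.0, mode=msio.CONTINUOUS):
    """Small helper: build an MsiDataset from {(x, y): [(mz, inten), ...]}."""
    coords = list(coords)
    mzs, intens = [], []
    for c in coords:
        peaks = sorted(spectra[c])
        mzs.append(np.array([p[0] for p in peaks], dtype=float))
        intens.append(np.array([p[1] for p in peaks], dtype=float))
    return msio.MsiDataset(np.array(coords), mzs, intens,
                           pixel_size=pixel_size, mode=mode)


@pytest.fixture
def square_region_doc():
    """One 200x200 µm rectangle at raster 20."""
    poly = np.array([[0.0, 0.0], [200.0, 0.0], [200.0, 200.0], [0.0, 200.0], [0.0, 0.0]])
    return msio.RegionDocument(
        method_name="PreScan_200um",
        raster_size=20.0,
        regions=[msio.Region("R1", poly)],
        transform=msio.GridTransform.scaling(20.0),
    )
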