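import numpy as np
import pytest

from juxtacell import rdmodel, synthdata


@pytest.fixture
def minute_grid():
    """30 minutes sampled every minute, plate-reader style."""
    return np.arange(0.0, 1801.0, 60.0)


@pytest.fixture
def coarse_rd_params():
    """Small, fast-converging model configuration for property tests."""
    return rdmodel.RDParams(n_r=24)


@pytest.fixture
def clean_vesicle_spec():
    """Noiseless, unblurred single-vesicle spec with truth ratio 3."""
    return synthdata.ImageSpec(
        shape=(160, 160),
        vesicles=[
            synthdata.VesicleSpec(
                center=(80.0, 80.0),
                radius=40.0,
                lumen_level=400.0,
                membrane_level=1000.0,
                ring_width=6.0,
            )
        ],
        background_level=100.0,
        psf_sigma=0.0,
        poisson=False,
        read_sigma=0.0,
        seed=0,
    )
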