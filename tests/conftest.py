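import numpy as np
import pytest
from hypothesis import settings

import fluorbind as fb

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture
def band():
    return fb.BandModel(center=340.0, width=15.0, amplitude=100.0)


@pytest.fixture
def make_series(band):
    """Factory for noiseless titration series of any mechanism."""

    def _make(mechanism="simple_static", grid=None, **params):
        if grid is None:
            grid = np.linspace(0.0, 5e-13, 11)
        cfg = fb.GeneratorConfig(band=band, quencher_grid=np.asarray(grid),
                                 mechanism=mechanism, **params)
        return fb.gen_quenching_titration(cfg)

    return _make


# Published secondary-structure fractions (percent) for hen-egg lysozyme
# titrated with cyclophosphamide, alone and with each cyclodextrin: regular/
# distorted helix, regular/distorted sheet, turn, unordered.
CD_FRACTIONS = {
    "LYZ": (16.82, 7.45, 22.13, 14.06, 6.17, 33.37),
    "LYZ-CYC": (13.46, 5.22, 20.14, 14.01, 6.03, 41.14),
    "(LYZ-aCD)CYC": (12.09, 4.66, 18.28, 12.84, 5.86, 46.27),
    "(LYZ-bCD)CYC": (11.71, 4.51, 18.03, 12.81, 5.82, 47.12),
    "(LYZ-gCD)CYC": (10.31, 3.17, 16.24, 10.13, 5.61, 54.54),
}


@pytest.fixture
def cd_records():
    keys = fb.conformation.FRACTION_KEYS
    return {name: fb.CdRecord(system=name,
                              fractions=dict(zip(keys, vals)))
            for name, vals in CD_FRACTIONS.items()}
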