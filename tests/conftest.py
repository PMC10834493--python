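import numpy as np
import pytest

from dissolvekit import QuantConfig, TimeGrid, load_vildagliptin_study

#: Published per-time mean % released of the bundled seven-product study.
VILD_MEANS = {
    "Ref": [98.53, 98.57, 98.00, 97.10, 96.05],
    "V-1": [98.34, 100.01, 99.13, 98.48, 97.45],
    "V-2": [98.48, 103.41, 102.67, 101.86, 100.97],
    "V-3": [96.78, 99.44, 98.29, 97.16, 96.40],
    "V-4": [98.17, 97.77, 96.48, 95.80, 94.92],
    "V-5": [97.50, 97.27, 96.10, 95.09, 93.97],
    "V-6": [99.26, 98.93, 97.76, 96.91, 95.96],
}

#: Published f1/f2 of each generic against the reference.
VILD_FACTORS = {
    "V-1": (1.13, 90.28),
    "V-2": (3.94, 67.80),
    "V-3": (0.68, 93.57),
    "V-4": (1.05, 91.39),
    "V-5": (1.70, 85.09),
    "V-6": (0.33, 98.47),
}


@pytest.fixture(scope="session")
def vild_study():
    return load_vildagliptin_study()


@pytest.fixture
def grid5():
    return TimeGrid([10, 15, 20, 30, 45])


@pytest.fixture
def quant_cfg():
    """The study's standard preparation and dissolution-run constants."""
    return QuantConfig(
        std_mass_mg=12.84,
        std_stock_vol_ml=25,
        std_aliquot_ml=2,
        std_final_vol_ml=20,
        label_claim_mg=50,
        medium_vol_ml=1000,
        withdrawal_vol_ml=10,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
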