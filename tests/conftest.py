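from pathlib import Path

import numpy as np
import pytest

from mirqtl import synthetic

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def mirnas10():
    return synthetic.gen_mirnas(10, rng_seed=101)


@pytest.fixture(scope="session")
def small_bundle():
    """A 10/10/5 planted bundle shared by read-only tests."""
    mirnas = synthetic.gen_mirnas(10, rng_seed=11)
    utrs = synthetic.gen_utrs(12, 300, rng_seed=12)
    return synthetic.plant_sites_and_snps(utrs, mirnas, 10, 10, 5, rng_seed=13)


@pytest.fixture
def toy_vcf_path():
    return DATA_DIR / "toy_screen.vcf"
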