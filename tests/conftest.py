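import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phasepath.features import AcquisitionConfig
from phasepath.phantoms import (
    CohortSpec,
    FieldSpec,
    GroupSpec,
    PhaseImage,
    field_to_phase,
    generate_feature_cohort,
    generate_von_karman_field,
)
from phasepath.reference import PARAMETERS


@pytest.fixture(scope="session")
def acq_20x() -> AcquisitionConfig:
    return AcquisitionConfig(pixel_size=0.3225, magnification="20x")


@pytest.fixture(scope="session")
def small_phantom_phase() -> PhaseImage:
    """64x64 Von Kármán phantom phase map for oracle comparisons."""
    spec = FieldSpec(
        shape=(64, 64), pixel_size=0.3225, sigma_n2=5e-5, outer_scale=10.0,
        exponent=1.4, seed=123,
    )
    fld = generate_von_karman_field(spec)
    return field_to_phase(fld, thickness=6.0, wavelength=0.55)


@pytest.fixture(scope="session")
def big_phantom_field():
    """1024^2 field with known spectrum parameters (L0=20 um, m=1.5)."""
    spec = FieldSpec(
        shape=(1024, 1024), pixel_size=0.3225, sigma_n2=0.01, outer_scale=20.0,
        exponent=1.5, seed=11,
    )
    return generate_von_karman_field(spec)


def _gauss_params(mean: float, sd: float) -> dict:
    return {p: (mean, sd) for p in PARAMETERS}


@pytest.fixture(scope="session")
def separable_cohort():
    """Two 5-D Gaussian classes separated by 10 SDs, n=100 per class."""
    spec = CohortSpec(
        groups=(
            GroupSpec("phantom", "healthy", "20x", _gauss_params(0.0, 1.0)),
            GroupSpec("phantom", "tumoral", "20x", _gauss_params(10.0, 1.0)),
        ),
        n_per_group=100,
        seed=42,
    )
    return generate_feature_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Two classes drawn from the same 5-D Gaussian (no signal)."""
    spec = CohortSpec(
        groups=(
            GroupSpec("phantom", "healthy", "20x", _gauss_params(0.0, 1.0)),
            GroupSpec("phantom", "tumoral", "20x", _gauss_params(0.0, 1.0)),
        ),
        n_per_group=100,
        seed=7,
    )
    return generate_feature_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
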