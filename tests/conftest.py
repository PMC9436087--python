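import numpy as np
import pytest

from sxtinstance import PhantomSpec, SemanticMask, Tomogram, assemble_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sphere_dataset():
    """One default-condition sphere benchmark dataset (5 touching phantoms)."""
    return assemble_dataset(PhantomSpec(morphology="sphere", seed=7))


@pytest.fixture(scope="session")
def column_dataset():
    """One default-condition columnar benchmark dataset."""
    return assemble_dataset(PhantomSpec(morphology="column", seed=7))


def make_sphere_volume(centers, radii, peaks, shape=(48, 48, 48), background=0.1):
    """Noise-free volume of solid spheres with quadratic radial intensity."""
    zz, yy, xx = np.indices(shape, dtype=float)
    intensity = np.full(shape, background)
    mask = np.zeros(shape, dtype=bool)
    for (cz, cy, cx), r, peak in zip(centers, radii, peaks):
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= r * r
        prof = background + (peak - background) * (1 - d2 / (r * r))
        intensity = np.where(inside, np.maximum(intensity, prof), intensity)
        mask |= inside
    return Tomogram(intensity.astype(np.float32)), SemanticMask(mask.astype(np.uint8))
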