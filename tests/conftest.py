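import numpy as np
import pytest

from clonescreen.hcs import ClassifierConfig, SmoothingSpec


def gaussian_lowpass_oracle(image: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Dense direct 2-D convolution oracle, independent of the scipy path.

    Builds the full outer-product kernel, extends the image symmetrically,
    and sums the products pixel by pixel.  The filter origin is at index
    ``kernel_size // 2`` along each axis, matching the separable
    implementation's convention for even window lengths.
    """
    w = spec.weights()
    K = np.outer(w, w)
    k = spec.kernel_size
    s = k // 2
    pad = np.pad(image.astype(float), ((s, k - 1 - s), (s, k - 1 - s)), mode="symmetric")
    out = np.empty(image.shape, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(K * pad[i : i + k, j : j + k])
    return out


@pytest.fixture(scope="session")
def red_spec() -> SmoothingSpec:
    return SmoothingSpec(21, 7.0)


@pytest.fixture(scope="session")
def greenblue_spec() -> SmoothingSpec:
    return SmoothingSpec(60, 20.0)


@pytest.fixture(scope="session")
def default_config() -> ClassifierConfig:
    return ClassifierConfig()
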