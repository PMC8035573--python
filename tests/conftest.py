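import numpy as np
import pytest

import dpca

# Combined aberration used in the worked simulation: defocus-like x^2 term,
# tilt-like xy term, and third/fourth-order cross terms (coma/astigmatism
# analogues).  Units: rad / pixel^(k+l).
COMBINED_COEFFS = {
    (2, 0): 1e-5,
    (1, 1): 1e-5,
    (3, 1): 1e-11,
    (1, 3): 1e-11,
    (1, 2): 1e-8,
}


@pytest.fixture(scope="session")
def grid512():
    return dpca.GridConvention(512, 512)


@pytest.fixture(scope="session")
def grid128():
    return dpca.GridConvention(128, 128)


@pytest.fixture(scope="session")
def combined_aberration(grid512):
    return dpca.eval_polynomial_aberration(
        dpca.AberrationSpec(COMBINED_COEFFS), grid512
    )


@pytest.fixture(scope="session")
def sample_phase(grid512):
    spec = dpca.SampleSpec(mask=dpca.letters_mask(grid512))
    return dpca.make_sample_phase(spec, grid512)


def piston_free_std(values: np.ndarray) -> float:
    v = values - values.mean()
    return float(np.std(v))
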