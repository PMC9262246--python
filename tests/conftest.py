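import numpy as np
import pytest

from usdenoise import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def msk_phantom():
    """A small musculoskeletal phantom shared across tests."""
    return render_phantom(PhantomSpec("msk", seed=42, height=128, width=128))


@pytest.fixture(scope="session")
def phantom_set():
    """Six small phantoms spanning the four categories."""
    cats = ["abdominal", "carotid", "neck", "msk", "abdominal", "msk"]
    return [
        render_phantom(PhantomSpec(cat, seed=100 + i, height=128, width=128))
        for i, cat in enumerate(cats)
    ]
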