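import pytest

from augforge import RandomSource, make_fixtures


@pytest.fixture
def rgb_set():
    """Small 3-class RGB fixture set (6 images per class, 32x32)."""
    return make_fixtures(3, 6, (32, 32), channels=3, seed=42)


@pytest.fixture
def gray_set():
    """Small 3-class grayscale fixture set."""
    return make_fixtures(3, 6, (32, 32), channels=1, seed=42)


@pytest.fixture
def rng():
    return RandomSource(1234)
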