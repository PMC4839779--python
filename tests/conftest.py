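import pytest

from pvagree import PriceVolumePoint, fit_two_points


@pytest.fixture
def ranibizumab_model():
    """Two-point fit of the ranibizumab example: (0, 9050), (20000, 6500) EUR."""
    return fit_two_points(PriceVolumePoint(0, 9050), PriceVolumePoint(20000, 6500))


@pytest.fixture
def sofosbuvir_model():
    """Two-point fit of the sofosbuvir example: (0, 37500), (60000, 4000) EUR."""
    return fit_two_points(PriceVolumePoint(0, 37500), PriceVolumePoint(60000, 4000))
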