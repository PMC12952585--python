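from decimal import Decimal

import pytest

import massladder as ml
from massladder.data import (
    DIGEST_PEAKS,
    MINOR_PEAKS,
    SSGII70,
    TABLE1_PEAKS,
    fixture_path,
)


@pytest.fixture(scope="session")
def ladder60():
    """C-terminal ladder over the published 60-70mer range."""
    return ml.build_ladder(SSGII70, side="cterm", mer_min=60, water_max=8)


@pytest.fixture(scope="session")
def ladder_full():
    """C-terminal ladder extended down to the 7mer."""
    return ml.build_ladder(SSGII70, side="cterm", mer_min=7, water_max=8)


@pytest.fixture(scope="session")
def table1_peaks():
    return ml.read_peaklist(fixture_path(TABLE1_PEAKS))


@pytest.fixture(scope="session")
def minor_peaks():
    return ml.read_peaklist(fixture_path(MINOR_PEAKS))


@pytest.fixture(scope="session")
def digest_peaks():
    return ml.read_peaklist(fixture_path(DIGEST_PEAKS))


def d2(x) -> Decimal:
    return Decimal(str(x)).quantize(Decimal("0.01"))
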