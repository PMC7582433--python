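import warnings

import pytest

from pbpkddi import load_drug, load_inhibition, load_physiology


@pytest.fixture(scope="session")
def physio():
    return load_physiology()


@pytest.fixture(scope="session")
def inhibition():
    return load_inhibition()


@pytest.fixture(scope="session")
def drugs():
    """All bundled drug parameter sets (lovastatin's gut-CLint warning is expected)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        from pbpkddi.params import BUNDLED_DRUGS
        return {name: load_drug(name) for name in BUNDLED_DRUGS}
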