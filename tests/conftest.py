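import warnings

import pytest

from diffoptix.propagation import SamplingWarning, ContainmentWarning


@pytest.fixture(autouse=True)
def _quiet_diagnostic_warnings():
    """Containment/sampling diagnostics are exercised explicitly in dedicated
    tests; elsewhere they are noise on deliberately tiny grids."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SamplingWarning)
        warnings.simplefilter("ignore", ContainmentWarning)
        yield
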