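import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from coralith.markers import default_marker_panel
from coralith.simulate import build_reference_set


@pytest.fixture(scope="session")
def panel():
    return default_marker_panel()


@pytest.fixture(scope="session")
def small_refs(panel):
    """Three single-sequence genera across all four markers."""
    return build_reference_set(3, 1, panel, seed=5)


@pytest.fixture(scope="session")
def genus_refs(panel):
    """Five genera x four sequences, the classifier-evaluation reference set."""
    return build_reference_set(5, 4, panel, seed=2)
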