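import numpy as np
import pytest

from titerscreen.normalization import normalize_screen
from titerscreen.synthetic_data import (
    ScreenSimConfig,
    default_control_layout,
    generate_library,
    generate_screen,
)


@pytest.fixture(scope="session")
def small_config() -> ScreenSimConfig:
    """A one-plate triplicate screen with default control layout."""
    return ScreenSimConfig(n_genes=120, amplicons_per_gene={1: 1.0}, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_config):
    """(manifest, readouts, normalized wells) for the small screen."""
    manifest = generate_library(small_config)
    readouts = generate_screen(manifest, small_config)
    normalized = normalize_screen(
        readouts, control_wells=list(default_control_layout())
    )
    return manifest, readouts, normalized


def make_unit_spread_scores(extra=(3.0, -3.0)):
    """A score multiset with median exactly 0 and 1.4826*MAD exactly 1,
    even after appending the symmetric ``extra`` values."""
    base = [0.0]
    for v in (0.1, 0.2, 0.3, 0.4, 0.5, 1.0 / 1.4826, 0.9, 1.1, 1.3, 1.5):
        base.extend([v, -v])
    scores = np.asarray(base + list(extra))
    # symmetric multiset: median is exactly 0; divide once by the realized
    # robust scale (MAD is scale-equivariant) to pin 1.4826*MAD to 1
    scores = scores / (1.4826 * np.median(np.abs(scores)))
    med = float(np.median(scores))
    scale = 1.4826 * float(np.median(np.abs(scores - med)))
    assert med == 0.0 and abs(scale - 1.0) < 1e-12
    return scores.tolist()
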