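import warnings

import numpy as np
import pytest

from silafract import synthgen


@pytest.fixture(scope="session")
def r5_block():
    """One deterministic R5 trimer building block."""
    return synthgen.generate_building_block(synthgen.BuildingBlock(), seed=1)


@pytest.fixture(scope="session")
def small_assemblies(r5_block):
    """One 12-block assembly per morphology mode (fixed seeds)."""
    frames = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mode in ("linear", "planar", "compact", "dla"):
            frames[mode] = synthgen.aggregate_assembly(
                r5_block, synthgen.MorphologySpec(mode=mode, n_blocks=12, seed=7)
            )
    return frames


@pytest.fixture(scope="session")
def reference_peaks():
    return synthgen.reference_peak_table(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
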