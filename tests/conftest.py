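import numpy as np
import pytest

import canopy_wsss as cw


@pytest.fixture(scope="session")
def trained_classifier():
    """Desk-scale CNN trained once on the default synthetic patch set."""
    patches, labels = cw.generate_patch_training_set(0, n_per_class=200)
    rng = np.random.default_rng(0)
    order = rng.permutation(len(patches))
    split = int(0.8 * len(patches))
    tr, va = order[:split], order[split:]
    return cw.train_classifier(patches[tr], labels[tr], patches[va], labels[va])


@pytest.fixture(scope="session")
def canopy_sample():
    """One default synthetic canopy with its ground truth."""
    return cw.generate_canopy(cw.CanopySpec(), rng=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
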