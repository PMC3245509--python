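import numpy as np
import pytest

import flexmotion as fm

MIXED60_SS = "CCCHHHHHHHHHHCCCCEEEEEECCCCHHHHHHHHCCCCEEEEEECCCCHHHHHHHCCC"  # 59 aa


@pytest.fixture(scope="session")
def helix30():
    spec = fm.TopologySpec(ss_string="H" * 30, jitter=0.0, seed=1)
    return fm.generate_toy_structure(spec)


@pytest.fixture(scope="session")
def mixed60():
    """Compact mixed helix/sheet/coil chain with all its normal modes."""
    spec = fm.TopologySpec(ss_string=MIXED60_SS, jitter=0.15, seed=5)
    structure = fm.generate_toy_structure(spec)
    modes = fm.build_anm_modes(structure)
    return structure, modes, spec


@pytest.fixture(scope="session")
def corpus16():
    """The package's standard desk-scale training corpus."""
    return fm.generate_training_corpus(16, seed=42)


@pytest.fixture(scope="session")
def internal_model(corpus16):
    return fm.train_from_corpus(
        corpus16, "internal", config=fm.TrainConfig(seed=7)
    )


@pytest.fixture()
def uniform_annotated():
    """Homopolymer with uniform annotations (translation-invariant input)."""
    n = 30
    return fm.AnnotatedSequence(
        sequence="A" * n, ss="C" * n, asa=np.full(n, 30.0)
    )
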