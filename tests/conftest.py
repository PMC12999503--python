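import numpy as np
import pytest

from enantiokit import (
    ConformerEnsemble,
    Structure,
    SyntheticSpec,
    gen_conformer_ensemble,
    make_template_structure,
)


@pytest.fixture
def template() -> Structure:
    return make_template_structure(24)


@pytest.fixture
def small_ensemble(template) -> ConformerEnsemble:
    """Five jittered conformers of the helical template, with properties."""
    spec = SyntheticSpec(n_conformers=5, jitter_sd=0.03, seed=7)
    return gen_conformer_ensemble(template, spec)


@pytest.fixture
def h2_pair() -> ConformerEnsemble:
    """Two H2 conformers at energies 0 and 1 kcal/mol."""
    a = Structure(["H", "H"], [[0, 0, 0], [0, 0, 0.74]], id="a")
    b = Structure(["H", "H"], [[0, 0, 0], [0, 0, 0.80]], id="b")
    return ConformerEnsemble([a, b], np.array([0.0, 1.0]))
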