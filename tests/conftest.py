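import warnings

import numpy as np
import pytest

from distrank import synth
from distrank.structio import Structure


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline-internal warnings (top-k shortfalls, empty contact sets) are
    part of normal operation on tiny fixtures."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* contacts available")
        warnings.filterwarnings("ignore", message="empty predicted contact set")
        yield


@pytest.fixture(scope="session")
def native60():
    return synth.make_native(60, seed=7)


@pytest.fixture(scope="session")
def native30():
    return synth.make_native(30, seed=3)


@pytest.fixture(scope="session")
def pool30(native30):
    return synth.make_decoys(
        native30, synth.DecoySpec(n_decoys=8, noise_levels=(0.5, 2.0), seed=3))


def random_structure(L: int, seed: int, spread: float = 8.0) -> Structure:
    """Unstructured random coordinate cloud (not self-avoiding)."""
    rng = np.random.default_rng(seed)
    return Structure(
        target_id=f"rand{seed}",
        sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L)),
        residue_index=np.arange(1, L + 1),
        ca_coords=rng.normal(scale=spread, size=(L, 3)),
    )
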