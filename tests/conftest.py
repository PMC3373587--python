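import numpy as np
import pytest

import ssekit as sk


@pytest.fixture(scope="session")
def birth_death():
    return sk.make_birth_death(k_in=1e-6, k_out=1.0, volume_liters=1e-15)


@pytest.fixture(scope="session")
def bd_system(birth_death):
    return sk.compile_system(birth_death)


@pytest.fixture(scope="session")
def mm_cellular():
    """Michaelis-Menten model at the cellular scale (0.5 fl, 1204 enzymes)."""
    return sk.make_paper_model("F1")


@pytest.fixture(scope="session")
def mm_small():
    """Michaelis-Menten model in a small compartment (24 enzymes)."""
    return sk.make_paper_model("F2")


@pytest.fixture(scope="session")
def mm_cellular_system(mm_cellular):
    return sk.compile_system(mm_cellular)


@pytest.fixture(scope="session")
def mm_small_system(mm_small):
    return sk.compile_system(mm_small)


@pytest.fixture(scope="session")
def coop_cellular_system():
    return sk.compile_system(sk.make_paper_model("F3"))


def rel_err(a, b):
    return abs(a - b) / max(abs(b), 1e-300)
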