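import numpy as np
import pytest
from hypothesis import settings

from gjdock.synthetic import (
    make_cylinder_channel,
    make_sc_fixture,
    make_toy_connexon,
)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def connexon_closed12():
    return make_toy_connexon(12, "closed")


@pytest.fixture(scope="session")
def connexon_open12():
    return make_toy_connexon(12, "open")


@pytest.fixture(scope="session")
def connexon_closed6():
    return make_toy_connexon(6, "closed")


@pytest.fixture(scope="session")
def connexon_open6():
    return make_toy_connexon(6, "open")


@pytest.fixture(scope="session")
def sc_default():
    return make_sc_fixture("default")


@pytest.fixture(scope="session")
def cylinder_uniform():
    return make_cylinder_channel([6.7] * 21, z_step=1.0)


def random_toy_structure(rng: np.random.Generator, n_chains=2, n_res=20,
                         z_offset=0.0):
    """Random-walk toy chains for oracle-equivalence tests.

    Step lengths ~2-3 Å keep neighbouring residues adjacent while the walks
    repeatedly approach each other, producing a mix of contacts, SCs and
    near-misses.
    """
    from gjdock.core import Structure

    chains, res_nums, names, res_names, elements, coords = \
        [], [], [], [], [], []
    for ci in range(n_chains):
        chain = "AB"[ci] if n_chains <= 2 else chr(ord("A") + ci)
        p = rng.uniform(-4, 4, size=3)
        for r in range(1, n_res + 1):
            step = rng.normal(size=3)
            step *= rng.uniform(2.0, 3.0) / np.linalg.norm(step)
            p = p + step
            p = np.clip(p, -9, 9)  # confinement makes long-range contacts
            for k, (nm, el) in enumerate((("CA", "C"), ("O", "O"))):
                if k == 1 and rng.random() < 0.5:
                    continue
                chains.append(chain)
                res_nums.append(r)
                names.append(nm)
                res_names.append("GLY")
                elements.append(el)
                coords.append(p + rng.normal(scale=0.3, size=3)
                              + [0, 0, z_offset])
    return Structure(
        chain_ids=np.array(chains), res_nums=np.array(res_nums),
        res_names=np.array(res_names), names=np.array(names),
        elements=np.array(elements), coords=np.array(coords))
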