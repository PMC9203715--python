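import pytest

from quadtrot.params import preset
from quadtrot.periodic import find_periodic


@pytest.fixture(scope="session")
def dog():
    p, z_star = preset("dog")
    return p, z_star


@pytest.fixture(scope="session")
def horse():
    p, z_star = preset("horse")
    return p, z_star


@pytest.fixture(scope="session")
def dog_sym_solution(dog):
    p, z_star = dog
    return find_periodic(p.replace(eps_mu=0.0, eps_k=0.0), z_star)


@pytest.fixture(scope="session")
def dog_solution(dog, dog_sym_solution):
    p, z_star = dog
    return find_periodic(p, z_star, x_guess=dog_sym_solution.x_star)


@pytest.fixture(scope="session")
def horse_sym_solution(horse):
    p, z_star = horse
    return find_periodic(p.replace(eps_mu=0.0, eps_k=0.0), z_star)


@pytest.fixture(scope="session")
def horse_solution(horse, horse_sym_solution):
    p, z_star = horse
    return find_periodic(p, z_star, x_guess=horse_sym_solution.x_star)
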