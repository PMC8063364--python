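import pytest

from pederr.genotypes import FamilyStructure
from pederr.simulate import SimulationSpec, simulate_dataset


@pytest.fixture
def trio_structure():
    return FamilyStructure("FAM1", "MOM", "DAD", ("KID",))


@pytest.fixture
def quad_structure():
    return FamilyStructure("FAM1", "MOM", "DAD", ("C1", "C2"))


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort shared by tests that only need plausible
    family call data, not statistical power."""
    return simulate_dataset(
        SimulationSpec(n_families=3, children_per_family=2, n_sites=30_000, seed=11)
    )


def brute_force_mendelian(fg):
    """Independent validity oracle: enumerate every way of drawing one
    allele from each parent for each child."""
    alleles = {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)]}
    if any(c == 3 for c in fg):
        return False
    mother, father, children = fg[0], fg[1], fg[2:]
    for child in children:
        ok = False
        for am in alleles[mother][0]:
            for af in alleles[father][0]:
                if am + af == child:
                    ok = True
        if not ok:
            return False
    return True
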