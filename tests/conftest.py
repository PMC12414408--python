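import numpy as np
import pytest

from phenocal import SimConfig, a_matrix, build_design, dichotomize, simulate_trait
from phenocal.pedigree import RelationshipMatrix, pedigree_from_arrays


@pytest.fixture(scope="session")
def trio_pedigree():
    return pedigree_from_arrays(["1", "2", "3"], ["0", "0", "1"], ["0", "0", "2"])


@pytest.fixture(scope="session")
def study_trait():
    """One realization of the default study design (643 cows), dichotomized."""
    return dichotomize(simulate_trait(SimConfig(seed=20240901)), 0.8)


@pytest.fixture(scope="session")
def study_design(study_trait):
    """Design matrices and marginal A/A^-1 over the phenotyped cohort."""
    trait = study_trait
    animals = list(trait.animal_ids)
    mm = build_design(trait.phenotype_frame(), trait.pedigree, animals=animals)
    A = a_matrix(trait.pedigree).submatrix(animals)
    Ainv = RelationshipMatrix(tuple(animals), np.linalg.inv(A.values))
    return mm, A, Ainv


def random_pedigree(rng, n_founders, n_nonfounders):
    """Random valid pedigree: founders first, later animals pick earlier parents."""
    animals = [f"A{i}" for i in range(n_founders + n_nonfounders)]
    sires, dams = [], []
    for i, _ in enumerate(animals):
        if i < n_founders:
            sires.append("0")
            dams.append("0")
        else:
            s, d = rng.choice(i, size=2, replace=True)
            sires.append(animals[s])
            dams.append(animals[d])
    return pedigree_from_arrays(animals, sires, dams)
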