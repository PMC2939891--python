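import numpy as np
import pytest
from hypothesis import settings

from sh3score.matrixio import AMINO_ACIDS, EnergyMatrix, MatrixEnsemble

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_matrix(
    rng: np.random.Generator,
    domain_id: str = "toy",
    template_id: int = 1,
    template_class: str = "I",
    conformation_id: int = 1,
) -> EnergyMatrix:
    return EnergyMatrix(
        domain_id=domain_id,
        template_id=template_id,
        template_class=template_class,
        conformation_id=conformation_id,
        values=rng.normal(0, 1, size=(20, 10)),
    )


def random_ensemble(
    rng: np.random.Generator,
    n_templates: int = 3,
    n_conformations: int = 3,
    n_class_i: int = 1,
    domain_id: str = "toy",
) -> MatrixEnsemble:
    matrices = {}
    for t in range(1, n_templates + 1):
        cls = "I" if t <= n_class_i else "II"
        for c in range(1, n_conformations + 1):
            matrices[(t, c)] = random_matrix(
                rng, domain_id=domain_id, template_id=t,
                template_class=cls, conformation_id=c,
            )
    return MatrixEnsemble(domain_id=domain_id, matrices=matrices)


def random_peptide(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
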