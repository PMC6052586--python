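import numpy as np
import pytest

from iolmc import AKREOS_AO, SOFTEC_HD, CohortSpec, EyeBiometry, generate

# A Table-2-average eye (pooled bilateral biometry of the study cohort).
AVERAGE_EYE = EyeBiometry("avg", "OD", K=44.41, ACD=3.14, AL=23.42)


def random_eyes(n, seed, k=(41.0, 48.0), acd=(2.2, 4.2), al=(20.5, 26.5)):
    """Uniformly sampled eyes within clinically common biometry ranges."""
    rng = np.random.default_rng(seed)
    return [
        EyeBiometry(
            f"R{i:04d}",
            "OD" if i % 2 == 0 else "OS",
            K=float(rng.uniform(*k)),
            ACD=float(rng.uniform(*acd)),
            AL=float(rng.uniform(*al)),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def average_eye():
    return AVERAGE_EYE


@pytest.fixture(scope="session")
def lenses():
    return {"softec": SOFTEC_HD, "akreos": AKREOS_AO}


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort (40 patients, defaults) at a fixed seed."""
    return generate(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def large_cohort():
    """A 400-patient cohort for distributional checks."""
    return generate(CohortSpec(n_patients=400, seed=2))
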