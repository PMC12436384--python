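import numpy as np
import pytest

import dexpop as dp


@pytest.fixture(scope="session")
def model():
    """The published final adult model."""
    return dp.final_model()


@pytest.fixture(scope="session")
def patient_cov():
    return dp.SubjectCovariates(
        bw=60.0, age=40.0, sex=0, bmi=23.0, bsa=1.6, state=1, study="phase3"
    )


@pytest.fixture(scope="session")
def hv_cov():
    return dp.SubjectCovariates(
        bw=60.0, age=25.0, sex=0, bmi=22.0, bsa=1.6, state=0,
        study="phase1_part2",
    )


@pytest.fixture(scope="session")
def full_study(model):
    """One synthetic full two-study design (48 rich HV + 148 sparse patients)."""
    return dp.generate_full_study(model, dp.PUBLISHED_ER, seed=123)


@pytest.fixture(scope="session")
def full_dataset(full_study):
    """The M1-filtered analysis dataset of the synthetic full study."""
    return dp.apply_blq_m1(full_study.dataset).dataset


def random_params(rng: np.random.Generator) -> dp.IndividualParams:
    """Plausible random PK parameter draws for oracle comparisons."""
    return dp.IndividualParams(
        cl=float(rng.uniform(10.0, 80.0)),
        vc=float(rng.uniform(10.0, 60.0)),
        q=float(rng.uniform(30.0, 200.0)),
        vp=float(rng.uniform(30.0, 200.0)),
        ka=float(rng.uniform(0.2, 4.0)),
        f1=float(rng.uniform(0.3, 1.0)),
        alag=float(rng.uniform(0.0, 0.15)),
    )
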