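import numpy as np
import pytest

from seqnz.model import (
    MarkerCatalog,
    MarkerModelParams,
    ModelTheta,
    PrevalenceParams,
)
from seqnz.simulate import adni_like_theta, default_preset, simulate_cohort


def make_theta(
    markers,
    beta,
    psi=None,
    rho=None,
    lambda0=0.0,
    lambda1=0.0,
    psi_by_class=None,
    rho_by_class=None,
):
    """Small hand-built model for closed-form unit tests."""
    h = len(markers)
    beta = np.asarray(beta, dtype=float)
    psi = np.zeros((2 * h, 2 * h)) if psi is None else np.asarray(psi, dtype=float)
    rho = np.ones(h) if rho is None else np.asarray(rho, dtype=float)
    return ModelTheta(
        prevalence=PrevalenceParams(lambda0=lambda0, lambda1=lambda1),
        markers=MarkerModelParams(
            beta=beta, psi=psi, rho=rho,
            psi_by_class=psi_by_class, rho_by_class=rho_by_class,
        ),
        catalog=MarkerCatalog(markers=tuple(markers)),
    )


def scalar_theta(mu0=-1.0, mu1=1.0, var=1.0, prior_logit=0.0):
    """One marker, no age/time effects: class means mu0/mu1, total variance
    ``var`` (all residual), prior = expit(prior_logit)."""
    return make_theta(
        ["m"],
        beta=[[[mu0, 0.0, 0.0]], [[mu1, 0.0, 0.0]]],
        rho=[var],
        lambda0=prior_logit,
    )


@pytest.fixture(scope="session")
def theta_true():
    return adni_like_theta()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(default_preset("adni_like", n_subjects=80, seed=42))
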