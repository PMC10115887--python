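"""Probabilistic core: longitudinal Gaussian discriminant model.

The model classifies a subject into one of two diagnostic classes (z = 1:
MCI-converter, z = 0: MCI-stable) from an arbitrary subset of longitudinal
marker measurements.  It combines

* a prevalence model: logistic regression of the class label on baseline age,
  supplying the prior ``pi0 = expit(lambda0 + lambda1 * age)``;
* a marker model: a stacked linear mixed-effects model over the marker
  catalog.  For a measurement of marker ``h`` at time ``t`` (years since
  baseline) on a subject with baseline age ``a``, the class-conditional mean
  is ``beta[z, h] . (1, a, t)``; a shared per-subject random intercept and
  slope per marker (joint covariance ``Psi``, dimension ``2 * n_markers``)
  plus marker-specific residual variance ``rho[h]`` induce the covariance
  ``Z Psi Z' + R`` of any measurement subset.

Given the class-conditional Gaussian moments, posterior class probabilities
follow from Bayes' rule; all density work is done in the log domain.  The
default variant shares (Psi, rho) across classes (linear discriminant); a
quadratic variant with class-specific covariance parameters is supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

__all__ = [
    "MarkerCatalog",
    "MeasurementSlot",
    "Observation",
    "SubjectRecord",
    "PrevalenceParams",
    "MarkerModelParams",
    "ModelTheta",
    "DEFAULT_MARKERS",
    "default_catalog",
    "prevalence_probability",
    "marginal_moments",
    "condition_on_observed",
    "posterior_probability",
    "posterior_log_odds",
]

#: jitter added to a covariance diagonal when a Cholesky factorization fails
JITTER = 1e-8

DEFAULT_MARKERS = ("mri_spare_ad", "csf_abeta", "mmse", "ravlt")

_DISPLAY = {
    "mri_spare_ad": "SPARE-AD (structural MRI)",
    "csf_abeta": "A-beta 1-42 CSF",
    "mmse": "MMSE (normalized)",
    "ravlt": "RAVLT",
}


class CatalogError(KeyError):
    """A marker name not present in the catalog was used."""


class ModelError(ValueError):
    """The model parameters are invalid (e.g. non-PSD covariance)."""


@dataclass(frozen=True)
class MarkerCatalog:
    """Ordered catalog of marker types.

    The order is load-bearing: it defines the dummy coding of marker types
    and the block layout of the random-effects covariance ``Psi`` (two
    consecutive rows/columns -- intercept then time slope -- per marker).
    """

    markers: tuple[str, ...]
    display: dict[str, str] = field(default_factory=dict)
    #: optional per-marker value transforms applied on ingest (hook only)
    transforms: dict[str, Callable[[float], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if not self.markers:
            raise ValueError("catalog must contain at least one marker")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise CatalogError(
                f"unknown marker {marker!r}; catalog: {list(self.markers)}"
            ) from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


def default_catalog() -> MarkerCatalog:
    """The four-marker catalog used throughout: MRI atrophy score, CSF
    amyloid, and two cognitive tests."""
    return MarkerCatalog(markers=DEFAULT_MARKERS, display=dict(_DISPLAY))


@dataclass(frozen=True, order=True)
class MeasurementSlot:
    """A (marker, time) pair: where/when a value can be measured.

    Ordering is (time, marker) -- but note sorting by time with catalog-order
    tie-break is done explicitly where it matters.
    """

    time: float
    marker: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"slot time must be finite and >= 0, got {self.time}")


@dataclass(frozen=True)
class Observation:
    slot: MeasurementSlot
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"observation value must be finite, got {self.value}")


@dataclass
class SubjectRecord:
    """One subject: covariates, measured values and unmeasured slots.

    ``label`` is 1 for an MCI-converter, 0 for MCI-stable, None when unknown.
    ``conversion_time`` (years since baseline) is present only for converters.
    """

    subject_id: str
    baseline_age: float
    label: Optional[int] = None
    conversion_time: Optional[float] = None
    observations: list[Observation] = field(default_factory=list)
    candidates: list[MeasurementSlot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.baseline_age):
            raise ValueError("baseline_age must be finite")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label}")
        if self.conversion_time is not None and self.label != 1:
            raise ValueError("conversion_time present but label != 1")
        observed = {o.slot for o in self.observations}
        if observed & set(self.candidates):
            raise ValueError("candidate slots must be disjoint from observed slots")


@dataclass(frozen=True)
class PrevalenceParams:
    """Logistic prevalence model: P(z=1 | age) = expit(lambda0 + lambda1*age).

    ``lambda1 = 0`` gives the constant-prevalence mode (relative frequency).
    """

    lambda0: float
    lambda1: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lambda0) and math.isfinite(self.lambda1)):
            raise ValueError("prevalence parameters must be finite")


@dataclass
class MarkerModelParams:
    """Fitted marker-model parameters.

    beta : ndarray, shape (2, n_markers, 3)
        Class-specific fixed effects per marker: (intercept, age slope,
        time slope); ``beta[z, h]``.
    psi : ndarray, shape (2H, 2H)
        Random-effects covariance (intercept/slope blocks in catalog order),
        shared across classes in the default (linear) variant.
    rho : ndarray, shape (H,)
        Marker-specific residual variances, shared across classes.
    psi_by_class, rho_by_class : optional
        Class-specific covariance parameters for the quadratic variant;
        arrays of shape (2, 2H, 2H) and (2, H).
    """

    beta: np.ndarray
    psi: np.ndarray
    rho: np.ndarray
    psi_by_class: Optional[np.ndarray] = None
    rho_by_class: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        h = self.rho.shape[0]
        if self.beta.shape != (2, h, 3):
            raise ValueError(f"beta must have shape (2, {h}, 3), got {self.beta.shape}")
        if self.psi.shape != (2 * h, 2 * h):
            raise ValueError("psi must be square with two rows per marker")
        if not np.allclose(self.psi, self.psi.T, atol=1e-10):
            raise ModelError("psi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.psi)) < -1e-8:
            raise ModelError("psi must be positive semi-definite")
        if np.any(self.rho <= 0):
            raise ModelError("residual variances rho must be > 0")

    @property
    def n_markers(self) -> int:
        return self.rho.shape[0]

    @property
    def class_specific(self) -> bool:
        return self.psi_by_class is not None or self.rho_by_class is not None

    def psi_for(self, z: int) -> np.ndarray:
        if self.psi_by_class is not None:
            return self.psi_by_class[z]
        return self.psi

    def rho_for(self, z: int) -> np.ndarray:
        if self.rho_by_class is not None:
            return self.rho_by_class[z]
        return self.rho


@dataclass
class ModelTheta:
    """All parameters of the discriminant model."""

    prevalence: PrevalenceParams
    markers: MarkerModelParams
    catalog: MarkerCatalog

    def __post_init__(self) -> None:
        if self.markers.n_markers != len(self.catalog):
            raise ValueError("marker parameter dimension does not match catalog")

    @property
    def equal_covariance(self) -> bool:
        return not self.markers.class_specific

    def with_prevalence(self, prev: PrevalenceParams) -> "ModelTheta":
        return replace(self, prevalence=prev)


# ---------------------------------------------------------------------------
# operations


def prevalence_probability(baseline_age: float, params: PrevalenceParams) -> float:
    """Prior probability of being a converter at the given baseline age."""
    if not math.isfinite(baseline_age):
        raise ValueError(f"baseline_age must be finite, got {baseline_age}")
    return float(expit(params.lambda0 + params.lambda1 * baseline_age))


def _design(slots: Sequence[MeasurementSlot], catalog: MarkerCatalog):
    """Fixed- and random-effects designs for a list of slots.

    Returns (marker indices, X (m,3 stacked per-slot [1, a-placeholder, t]
    is not used -- X here is (m, 3) of [1, age, t] filled by caller), Z
    (m, 2H)).
    """
    m = len(slots)
    h = len(catalog)
    idx = np.array([catalog.index(s.marker) for s in slots], dtype=int)
    t = np.array([s.time for s in slots], dtype=float)
    z_mat = np.zeros((m, 2 * h))
    rows = np.arange(m)
    z_mat[rows, 2 * idx] = 1.0
    z_mat[rows, 2 * idx + 1] = t
    return idx, t, z_mat


def marginal_moments(
    baseline_age: float,
    slots: Sequence[MeasurementSlot],
    theta: ModelTheta,
    class_label: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional mean and covariance of a set of measurement slots.

    Mean entry for slot (h, t) is ``beta[z,h,0] + beta[z,h,1]*age +
    beta[z,h,2]*t``; covariance is ``Z Psi Z' + diag(rho_h)``.
    """
    if not slots:
        raise ValueError("slots must be non-empty")
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    mk = theta.markers
    idx, t, z_mat = _design(slots, theta.catalog)
    b = mk.beta[class_label][idx]  # (m, 3)
    mean = b[:, 0] + b[:, 1] * baseline_age + b[:, 2] * t
    psi = mk.psi_for(class_label)
    rho = mk.rho_for(class_label)
    cov = z_mat @ psi @ z_mat.T
    cov[np.diag_indices_from(cov)] += rho[idx]
    return mean, 0.5 * (cov + cov.T)


def _chol(cov: np.ndarray):
    """Cholesky factor with a documented jitter fallback."""
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        pass
    try:
        return cho_factor(cov + JITTER * np.eye(cov.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ModelError(
            "covariance matrix is not positive definite even after "
            f"jitter {JITTER:g}"
        ) from exc


def condition_on_observed(
    joint_mean: np.ndarray,
    joint_cov: np.ndarray,
    observed_indices: Sequence[int],
    observed_values: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditioning: predictive moments of the remaining slots.

    Conditioning on the empty set returns the input unchanged.  A singular
    observed block is regularized with a small diagonal jitter; a clear
    error is raised if that fails.
    """
    joint_mean = np.asarray(joint_mean, dtype=float)
    joint_cov = np.asarray(joint_cov, dtype=float)
    obs = np.asarray(observed_indices, dtype=int)
    vals = np.asarray(observed_values, dtype=float)
    if obs.size != vals.size:
        raise ValueError("observed_indices and observed_values differ in length")
    if obs.size == 0:
        return joint_mean.copy(), joint_cov.copy()
    n = joint_mean.shape[0]
    rest = np.setdiff1d(np.arange(n), obs)
    s_oo = joint_cov[np.ix_(obs, obs)]
    s_ro = joint_cov[np.ix_(rest, obs)]
    s_rr = joint_cov[np.ix_(rest, rest)]
    factor = _chol(s_oo)
    gain = cho_solve(factor, s_ro.T).T  # S_ro S_oo^{-1}
    mean = joint_mean[rest] + gain @ (vals - joint_mean[obs])
    cov = s_rr - gain @ s_ro.T
    return mean, 0.5 * (cov + cov.T)


def _log_mvn_pdf(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    factor = _chol(cov)
    diff = y - mean
    alpha = cho_solve(factor, diff)
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    m = y.shape[0]
    return -0.5 * (m * math.log(2 * math.pi) + logdet + float(diff @ alpha))


def posterior_log_odds(
    baseline_age: float,
    observations: Sequence[Observation],
    theta: ModelTheta,
) -> float:
    """Log-odds that z = 1 given the observations (log-domain Bayes rule)."""
    pi0 = prevalence_probability(baseline_age, theta.prevalence)
    pi0 = min(max(pi0, 1e-300), 1 - 1e-16)
    prior_lo = float(logit(pi0))
    if not observations:
        return prior_lo
    slots = [o.slot for o in observations]
    y = np.array([o.value for o in observations], dtype=float)
    mean1, cov1 = marginal_moments(baseline_age, slots, theta, 1)
    mean0, cov0 = marginal_moments(baseline_age, slots, theta, 0)
    return prior_lo + _log_mvn_pdf(y, mean1, cov1) - _log_mvn_pdf(y, mean0, cov0)


def posterior_probability(
    baseline_age: float,
    observations: Sequence[Observation],
    theta: ModelTheta,
) -> float:
    """Posterior probability that the subject is a converter (z = 1).

    Empty observation list returns the age prevalence.  Supports both the
    equal-covariance (linear) and class-specific-covariance (quadratic)
    variants, determined by ``theta``.
    """
    return float(expit(posterior_log_odds(baseline_age, observations, theta)))
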