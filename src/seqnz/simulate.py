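"""Synthetic cohort generator matching the model's assumed structure.

Subjects are drawn exactly from the generative model the classifier
assumes: a Bernoulli label with logistic-in-age prevalence, per-marker
class-specific fixed effects linear in baseline age and time since
baseline, a shared per-subject random intercept + slope per marker with
joint covariance ``Psi``, and marker-specific Gaussian residual noise.
Visit schedules are irregular (jittered nominal visits with per-visit
dropout and per-marker availability), converters receive a conversion time,
and labels respect the cohort-definition windows (stable subjects keep at
least 2.75 years of follow-up; converters convert within 3.25 years).

The preset effect sizes are invented but chosen so the markers behave like
their clinical counterparts (an invasive high-sensitivity CSF assay, an MRI
atrophy score of intermediate accuracy, two cheap noisier cognitive tests);
see docs/methods.md for the rationale and exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .model import (
    MarkerCatalog,
    MarkerModelParams,
    MeasurementSlot,
    ModelTheta,
    Observation,
    PrevalenceParams,
    SubjectRecord,
    default_catalog,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_preset",
    "simulate_cohort",
    "adni_like_theta",
]


@dataclass
class SimulationConfig:
    theta_true: ModelTheta
    n_subjects: int = 612
    age_mean: float = 73.0
    age_sd: float = 7.0
    age_bounds: tuple[float, float] = (55.0, 90.0)
    #: nominal visit times in years since baseline
    visit_times: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0)
    visit_jitter_sd: float = 0.05
    #: per-marker visit indices at which the marker is measured
    availability: dict[str, tuple[int, ...]] = field(default_factory=dict)
    #: probability of continuing to each subsequent visit
    retention: float = 0.9
    #: converters' conversion times are uniform on (low, high]
    conversion_range: tuple[float, float] = (0.3, 3.25)
    #: cohort-definition windows: stable >= 2.75y follow-up, converter <= 3.25y
    stable_window: float = 2.75
    converter_window: float = 3.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        times = np.asarray(self.visit_times)
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("visit times must be non-negative and increasing")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")
        if self.stable_window <= 0 or self.converter_window <= 0:
            raise ValueError("label windows must be positive")
        if not self.availability:
            self.availability = {
                "mmse": tuple(range(len(self.visit_times))),
                "ravlt": tuple(range(len(self.visit_times))),
                "mri_spare_ad": (0, 3, 5),  # nominal years 0, 1, 2
                "csf_abeta": (0, 3),  # nominal years 0, 1
            }


@dataclass
class SyntheticCohort:
    records: list[SubjectRecord]
    config: SimulationConfig

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def split(self, n_train: int) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
        return self.records[:n_train], self.records[n_train:]


def adni_like_theta(zero_effect: bool = False) -> ModelTheta:
    """Ground-truth parameters for the default presets.

    Prevalence targets a converter fraction of 270/612 at the mean baseline
    age of 73.  Effect sizes (invented; roughly standardized units) give a
    baseline-MRI-only accuracy near 0.73 and markedly stronger CSF
    separation, with cognitive decline dominating the converters' time
    slopes.  ``zero_effect=True`` equalizes the class means for null tests.
    """
    catalog = default_catalog()
    lambda1 = 0.05
    lambda0 = float(logit(270.0 / 612.0)) - lambda1 * 73.0
    # rows: (intercept, age slope, time slope); stable class then converter
    beta_stable = np.array(
        [
            [-2.00, 0.020, 0.05],  # mri_spare_ad (higher = more AD-like)
            [2.33, -0.020, -0.02],  # csf_abeta (lower = worse)
            [1.165, -0.005, -0.05],  # mmse (normalized)
            [1.23, -0.010, -0.04],  # ravlt (scaled)
        ]
    )
    beta_conv = np.array(
        [
            [-1.20, 0.020, 0.25],
            [0.87, -0.020, -0.05],
            [0.765, -0.005, -0.35],
            [0.63, -0.010, -0.25],
        ]
    )
    if zero_effect:
        beta = np.stack([beta_stable, beta_stable.copy()])
    else:
        beta = np.stack([beta_stable, beta_conv])
    sd_int = np.array([0.6, 0.7, 0.7, 0.8])
    sd_slope = np.array([0.15, 0.10, 0.20, 0.20])
    h = len(catalog)
    corr = np.eye(2 * h)
    for a in range(h):
        corr[2 * a, 2 * a + 1] = corr[2 * a + 1, 2 * a] = 0.2
        for b in range(a + 1, h):
            corr[2 * a, 2 * b] = corr[2 * b, 2 * a] = 0.3
            corr[2 * a + 1, 2 * b + 1] = corr[2 * b + 1, 2 * a + 1] = 0.2
    sd = np.empty(2 * h)
    sd[0::2] = sd_int
    sd[1::2] = sd_slope
    psi = corr * np.outer(sd, sd)
    rho = np.array([0.09, 0.16, 0.25, 0.36])
    return ModelTheta(
        prevalence=PrevalenceParams(lambda0=lambda0, lambda1=lambda1),
        markers=MarkerModelParams(beta=beta, psi=psi, rho=rho),
        catalog=catalog,
    )


_PRESETS = ("adni_like", "zero_effect")


def default_preset(name: str, n_subjects: Optional[int] = None, seed: int = 0) -> SimulationConfig:
    """Named simulation presets.

    ``adni_like``: 612 subjects, converter fraction near 270/612, four
    markers on a jittered visit schedule near {0, 0.25, 0.5, 1, 1.5, 2, 3}
    years with CSF scheduled sparsely.  ``zero_effect``: identical but with
    equal class means, for null testing.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {list(_PRESETS)}")
    theta = adni_like_theta(zero_effect=(name == "zero_effect"))
    cfg = SimulationConfig(theta_true=theta, seed=seed)
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    return cfg


def _truncated_normal(rng, mean, sd, bounds, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, size=remaining.size)
        ok = (draw >= bounds[0]) & (draw <= bounds[1])
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model; deterministic given the seed.

    Stable subjects always retain their final scheduled visit so their
    follow-up respects the >= 2.75-year window that defines the stable
    label; converters may drop out at any visit.
    """
    theta = config.theta_true
    catalog = theta.catalog
    mk = theta.markers
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ages = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_bounds, n
    )
    pi0 = expit(theta.prevalence.lambda0 + theta.prevalence.lambda1 * ages)
    labels = (rng.random(n) < pi0).astype(int)
    records = []
    n_visits = len(config.visit_times)
    last_idx = n_visits - 1
    for i in range(n):
        z = int(labels[i])
        a = float(ages[i])
        psi = mk.psi_for(z)
        try:
            chol = np.linalg.cholesky(psi + 1e-12 * np.eye(psi.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ValueError("theta_true.psi is not positive semi-definite") from exc
        zeta = chol @ rng.standard_normal(psi.shape[0])
        rho = mk.rho_for(z)
        # jittered visit times; baseline stays exactly at 0
        times = np.asarray(config.visit_times, dtype=float).copy()
        jitter = rng.normal(0.0, config.visit_jitter_sd, size=n_visits)
        times[1:] = np.maximum(times[1:] + jitter[1:], 0.01)
        times[1:] = np.sort(times[1:])
        # per-visit dropout (first visit always attended)
        attended = [0]
        cont = rng.random(n_visits - 1) < config.retention
        for v in range(1, n_visits):
            if cont[v - 1]:
                attended.append(v)
            else:
                break
        if z == 0 and last_idx not in attended:
            attended.append(last_idx)
        obs = []
        for v in attended:
            t = float(times[v])
            for h, marker in enumerate(catalog):
                if v not in config.availability.get(marker, ()):
                    continue
                b = mk.beta[z, h]
                mean = b[0] + b[1] * a + b[2] * t
                value = (
                    mean
                    + zeta[2 * h]
                    + zeta[2 * h + 1] * t
                    + np.sqrt(rho[h]) * rng.standard_normal()
                )
                obs.append(Observation(MeasurementSlot(time=t, marker=marker), float(value)))
        conv_time = None
        if z == 1:
            low, high = config.conversion_range
            conv_time = float(high - rng.random() * (high - low))
        records.append(
            SubjectRecord(
                subject_id=f"s{i:04d}",
                baseline_age=a,
                label=z,
                conversion_time=conv_time,
                observations=obs,
            )
        )
    return SyntheticCohort(records=records, config=config)
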