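"""Synthetic study-cohort generator.

Generates virtual datasets with the statistical structure of the
pediatric valproate cohort: 103 children contributing ~376 steady-state
troughs, right-skewed ages on 0.5-15 y (mean 5.30, SD 3.39), weights
from an age-weight curve with multiplicative noise (mean ~19.9 kg),
maintenance doses of 9.9-45.7 mg/kg/day (mean 23.8) split q12h,
genotypes drawn under Hardy-Weinberg equilibrium at the cohort's allele
frequencies, and trough concentrations generated from the final
population-PK model (log-normal IIV on clearance plus additive residual
error).

Ages are sampled from a truncated log-normal whose parameters are
solved numerically so the *truncated* distribution hits the target mean
and SD.  Concentrations falling below the 1 mg/L assay quantification
limit are resampled (keeping n fixed) and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import datasets as ref
from .io import Dataset
from .nlme import LikelihoodKernel, _model_params
from .structural import ModelSpec

log = logging.getLogger("valpop")


def default_weight_for_age(age_y: np.ndarray) -> np.ndarray:
    """Median pediatric weight-for-age from the growth-reference table."""
    return ref.weight_for_age(age_y)


@dataclass
class CohortConfig:
    """Generative settings for a virtual cohort; defaults emulate the study."""

    n_subjects: int = 103
    #: distribution of troughs per subject; mean 3.65 matches 376/103
    obs_per_subject_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: 0.25, 4: 0.40, 5: 0.20}
    )
    age_mean_y: float = 5.30
    age_sd_y: float = 3.39
    age_range_y: tuple[float, float] = (0.5, 15.0)
    weight_for_age: Callable[[np.ndarray], np.ndarray] = default_weight_for_age
    weight_noise_cv: float = 0.15
    weight_range_kg: tuple[float, float] = (6.5, 52.0)
    dose_mean_mg_kg_day: float = 23.8
    dose_sd_mg_kg_day: float = 5.7
    dose_range_mg_kg_day: tuple[float, float] = (9.9, 45.7)
    #: fraction of subjects dosed three times daily (q8h); the rest are
    #: q12h - the cohort took the drug two to three times a day, and the
    #: bid/tid contrast is what lets trough-only data inform V/F
    tid_fraction: float = 1.0 / 3.0
    dose_rounding_mg: float = 5.0
    female_fraction: float = 47 / 103
    snp_allele_freqs: dict[str, float] = field(
        default_factory=lambda: {s: i.ref_allele_freq for s, i in ref.SNP_PANEL.items()}
    )
    comed_probs: dict[str, float] = field(
        default_factory=lambda: dict(ref.COMEDICATION_RATES)
    )
    generating_model: ModelSpec = field(default_factory=ref.final_model)
    lloq_mg_L: float = 1.0
    #: uniform back-shift of sampling times from the scheduled dose (h):
    #: TDM troughs are drawn in the window before the next dose, not at
    #: the exact dosing instant, and that recorded time variation is what
    #: (with the bid/tid mix) identifies V/F from trough-only data
    time_jitter_h: float = 2.0
    seed: int = 20220103

    def validate(self) -> None:
        for name, (mean, lo, hi) in {
            "age": (self.age_mean_y, *self.age_range_y),
            "dose": (self.dose_mean_mg_kg_day, *self.dose_range_mg_kg_day),
        }.items():
            if not lo < mean < hi:
                raise ValueError(
                    f"{name} range ({lo}, {hi}) must contain its mean {mean}"
                )
        if abs(sum(self.obs_per_subject_probs.values()) - 1.0) > 1e-9:
            raise ValueError("obs_per_subject_probs must sum to 1")
        for p in list(self.snp_allele_freqs.values()) + list(self.comed_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.tid_fraction <= 1.0:
            raise ValueError("tid_fraction must lie in [0, 1]")
        if self.time_jitter_h < 0 or self.time_jitter_h >= 8.0:
            raise ValueError("time_jitter_h must lie in [0, 8)")


@lru_cache(maxsize=32)
def _truncated_lognormal_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Solve (mu, s) of a log-normal so its [lo, hi]-truncation has the
    requested mean and SD (closed-form truncated moments, numeric root)."""

    def trunc_moments(mu: float, s: float) -> tuple[float, float]:
        a, b = (math.log(lo) - mu) / s, (math.log(hi) - mu) / s
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        m1 = math.exp(mu + s**2 / 2) * (
            stats.norm.cdf(b - s) - stats.norm.cdf(a - s)
        ) / z
        m2 = math.exp(2 * mu + 2 * s**2) * (
            stats.norm.cdf(b - 2 * s) - stats.norm.cdf(a - 2 * s)
        ) / z
        return m1, math.sqrt(max(m2 - m1**2, 1e-12))

    def resid(x):
        m, v = trunc_moments(x[0], abs(x[1]))
        return [m - mean, v - sd]

    x0 = [math.log(mean) - 0.5 * math.log(1 + (sd / mean) ** 2),
          math.sqrt(math.log(1 + (sd / mean) ** 2))]
    sol = optimize.fsolve(resid, x0, full_output=False, xtol=1e-12)
    mu, s = float(sol[0]), abs(float(sol[1]))
    m, v = trunc_moments(mu, s)
    if abs(m - mean) > 0.02 * mean or abs(v - sd) > 0.05 * sd:
        raise ValueError(
            f"could not match truncated log-normal moments (got mean {m:.3f}, sd {v:.3f})"
        )
    return mu, s


def _sample_truncated_lognormal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    mu, s = _truncated_lognormal_params(mean, sd, lo, hi)
    ca, cb = stats.norm.cdf((math.log(lo) - mu) / s), stats.norm.cdf(
        (math.log(hi) - mu) / s
    )
    u = rng.uniform(ca, cb, size=n)
    return np.exp(mu + s * stats.norm.ppf(u))


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Dataset:
    """Draw one virtual cohort; fully reproducible from the seed.

    Returns a :class:`~valpop.io.Dataset` whose observation DVs were
    generated as ``predict_trough(model, subject, eta_i) + eps`` with
    eta_i ~ N(0, omega^2) per subject and eps ~ N(0, sigma^2) per
    observation.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    model = config.generating_model

    age = _sample_truncated_lognormal(
        rng, n, config.age_mean_y, config.age_sd_y, *config.age_range_y
    )
    wt = config.weight_for_age(age) * np.exp(
        rng.normal(0.0, config.weight_noise_cv, size=n)
    )
    wt = np.clip(wt, *config.weight_range_kg)

    lo_d, hi_d = config.dose_range_mg_kg_day
    a = (lo_d - config.dose_mean_mg_kg_day) / config.dose_sd_mg_kg_day
    b = (hi_d - config.dose_mean_mg_kg_day) / config.dose_sd_mg_kg_day
    mg_kg_day = stats.truncnorm.rvs(
        a, b, loc=config.dose_mean_mg_kg_day, scale=config.dose_sd_mg_kg_day,
        size=n, random_state=rng,
    )
    doses_per_day = np.where(rng.uniform(size=n) < config.tid_fraction, 3.0, 2.0)
    tau = 24.0 / doses_per_day
    dose_mg = mg_kg_day * wt / doses_per_day
    if config.dose_rounding_mg > 0:
        dose_mg = np.maximum(
            np.round(dose_mg / config.dose_rounding_mg) * config.dose_rounding_mg,
            config.dose_rounding_mg,
        )

    sex = (rng.uniform(size=n) < config.female_fraction).astype(int)

    sub = pd.DataFrame(
        {
            "ID": [f"S{i + 1:03d}" for i in range(n)],
            "AGE": age,
            "WT": wt,
            "SEX": sex,
            "DOSE_MG": dose_mg,
            "II_H": tau,
        }
    )
    for snp, p in config.snp_allele_freqs.items():
        labels = ref.SNP_PANEL[snp].genotype_labels
        probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        sub[snp] = rng.choice(list(labels), size=n, p=probs / probs.sum())
    for drug, prob in config.comed_probs.items():
        sub[drug] = (rng.uniform(size=n) < prob).astype(int)

    k_choices = np.array(sorted(config.obs_per_subject_probs))
    k_probs = np.array([config.obs_per_subject_probs[k] for k in k_choices], dtype=float)
    n_obs_per = rng.choice(k_choices, size=n, p=k_probs / k_probs.sum())

    obs = pd.DataFrame(
        {
            "ID": np.repeat(sub["ID"].to_numpy(), n_obs_per),
            "DOSE_MG": np.repeat(dose_mg, n_obs_per),
            "II_H": np.repeat(tau, n_obs_per),
            "TIME_H": np.repeat(tau, n_obs_per),
            "DV": np.nan,
        }
    )
    if config.time_jitter_h > 0:
        obs["TIME_H"] = obs["II_H"] - rng.uniform(0, config.time_jitter_h, len(obs))

    ds = Dataset(subjects=sub, observations=obs)
    eta = rng.normal(0.0, model.omega.omega_cl, size=n)
    _simulate_dv_inplace(ds, model, eta, rng, lloq=config.lloq_mg_L)
    return ds


def _simulate_dv_inplace(
    dataset: Dataset,
    model: ModelSpec,
    eta: np.ndarray,
    rng: np.random.Generator,
    lloq: float = 0.0,
    include_residual: bool = True,
) -> int:
    """Fill DV from the model; resample values below the LLOQ.  Returns the
    number of resampled observations."""
    kern = LikelihoodKernel(dataset, model)
    params = _model_params(model)
    f = kern.predict(params, eta)
    if include_residual:
        y = f + model.error.sigma(f, params) * rng.standard_normal(len(f))
    else:
        y = f.copy()
    n_resampled = 0
    for _ in range(100):
        low = y < lloq
        if not np.any(low):
            break
        n_resampled += int(low.sum())
        y[low] = f[low] + model.error.sigma(f[low], params) * rng.standard_normal(
            int(low.sum())
        )
    else:
        y = np.maximum(y, lloq)
    if n_resampled:
        log.info("resampled %d observation(s) below the %.1f mg/L LLOQ", n_resampled, lloq)
    dataset.observations["DV"] = y
    return n_resampled


def simulate_from_model(
    dataset: Dataset,
    model: ModelSpec,
    seed: int,
    include_residual: bool = True,
) -> Dataset:
    """Re-simulate the DVs of an existing design (subjects, regimens,
    times) from a model with fresh eta and eps - the VPC primitive."""
    rng = np.random.default_rng(seed)
    out = Dataset(
        subjects=dataset.subjects.copy(), observations=dataset.observations.copy()
    )
    eta = rng.normal(0.0, model.omega.omega_cl, size=out.n_subjects)
    _simulate_dv_inplace(out, model, eta, rng, lloq=0.0, include_residual=include_residual)
    return out


def generate_replicates(
    config: CohortConfig, n_replicates: int, base_seed: int
) -> list[Dataset]:
    """Independent cohort replicates with seeds ``base_seed + index``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [generate_cohort(config, seed=base_seed + i) for i in range(n_replicates)]
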