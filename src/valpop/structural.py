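"""Structural pharmacokinetic model for oral valproic acid at steady state.

The drug follows a one-compartment disposition model with first-order
absorption and first-order elimination.  Because only oral data are
available, clearance and volume are apparent quantities (CL/F, V/F) with
bioavailability F absorbed into the parameter; the absorption rate
constant Ka cannot be identified from trough-only sampling and is fixed
(1.9 h^-1 by default).

Clearance carries the covariate model.  In the final pediatric model the
typical clearance is

    CL/F = theta_CL * (AGE / 5)**theta_age * theta_AG**[AG] * theta_GG**[GG]

where [AG] and [GG] are indicator variables for the ABCB1 rs3789243
genotype and AA is the reference level.  Individual clearance is
log-normal around the typical value, CL_i = TVCL * exp(eta_i).

All quantities are in mg, L and h; concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a runtime cycle
    from .nlme import ErrorModel, OmegaSpec

ABCB1_SNP = "rs3789243"

#: relative |ka - ke| below which the absorption/elimination-rate
#: degeneracy is handled by the analytic limit form
_FLIP_FLOP_TOL = 1e-9


@dataclass(frozen=True)
class Regimen:
    """A maintenance dosing schedule: ``dose_mg`` every ``tau_h`` hours, oral."""

    dose_mg: float
    tau_h: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError(f"dose_mg must be >= 0, got {self.dose_mg}")
        if self.tau_h <= 0:
            raise ValueError(f"tau_h must be > 0, got {self.tau_h}")

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.tau_h


@dataclass
class Subject:
    """One child: demographics, genotypes, co-medications and regimen."""

    id: str
    age_y: float
    weight_kg: float
    sex: str = "male"
    genotypes: dict[str, str] = field(default_factory=dict)
    comeds: set[str] = field(default_factory=set)
    regimen: Regimen | None = None

    def __post_init__(self) -> None:
        if self.age_y <= 0:
            raise ValueError(f"age_y must be > 0, got {self.age_y}")
        if self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")

    @property
    def daily_dose_mg_kg(self) -> float:
        """Total daily dose normalized by body weight (mg/kg/day)."""
        if self.regimen is None:
            raise ValueError(f"subject {self.id} has no regimen")
        return self.regimen.daily_dose_mg / self.weight_kg


@dataclass(frozen=True)
class Observation:
    """A steady-state trough measurement for one subject."""

    subject_id: str
    time_after_dose_h: float
    conc_mg_L: float


@dataclass(frozen=True)
class PKParameters:
    """Individual PK parameter set (apparent, i.e. /F)."""

    cl_f_L_h: float
    v_f_L: float
    ka_h: float = 1.9

    def __post_init__(self) -> None:
        for name in ("cl_f_L_h", "v_f_L", "ka_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def ke_h(self) -> float:
        return self.cl_f_L_h / self.v_f_L

    @property
    def half_life_h(self) -> float:
        return math.log(2.0) / self.ke_h


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the final pediatric clearance model."""

    theta_cl: float
    theta_v: float
    theta_age: float
    theta_abcb1_ag: float
    theta_abcb1_gg: float

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v", "theta_abcb1_ag", "theta_abcb1_gg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate effect on a structural parameter.

    ``coefficients`` are names of entries in the model's theta mapping,
    so the same term definition serves both evaluation and estimation.
    For categorical terms ``levels`` lists the genotype/flag levels with
    the reference level first; each non-reference level gets its own
    multiplier coefficient.
    """

    covariate: str
    form: str  # {"linear", "power", "exponential", "piecewise", "multiplier"}
    coefficients: tuple[str, ...]
    target: str = "CL"
    reference: float | None = None
    levels: tuple[str, ...] | None = None

    _FORMS = ("linear", "power", "exponential", "piecewise", "multiplier")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "multiplier":
            if not self.levels or len(self.levels) < 2:
                raise ValueError("categorical term needs >= 2 levels")
            if len(self.coefficients) != len(self.levels) - 1:
                raise ValueError(
                    "categorical term needs one multiplier per non-reference level"
                )
        elif self.form == "piecewise":
            if len(self.coefficients) != 2 or self.reference is None:
                raise ValueError("piecewise term needs 2 slopes and a breakpoint")
        else:
            if len(self.coefficients) != 1 or self.reference is None:
                raise ValueError(f"{self.form} term needs 1 coefficient and a reference")

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients)

    def multiplier(self, theta: Mapping[str, float], values: np.ndarray) -> np.ndarray:
        """Evaluate the multiplicative factor for an array of covariate values."""
        if self.form == "multiplier":
            values = np.asarray(values)
            out = np.ones(values.shape, dtype=float)
            for lvl, coef in zip(self.levels[1:], self.coefficients):
                out = np.where(values == lvl, theta[coef], out)
            known = np.isin(values, np.asarray(self.levels, dtype=object))
            if not np.all(known):
                bad = sorted(set(np.asarray(values)[~known].tolist()))
                raise ValueError(
                    f"unknown level(s) {bad} for covariate {self.covariate!r}; "
                    f"expected one of {list(self.levels)}"
                )
            return out
        x = np.asarray(values, dtype=float)
        if self.form == "power":
            return (x / self.reference) ** theta[self.coefficients[0]]
        if self.form == "exponential":
            return np.exp(theta[self.coefficients[0]] * (x - self.reference))
        if self.form == "linear":
            m = 1.0 + theta[self.coefficients[0]] * (x - self.reference)
            return np.maximum(m, 1e-6)
        # piecewise: separate slopes below/above the breakpoint
        lo, hi = (theta[c] for c in self.coefficients)
        slope = np.where(x < self.reference, lo, hi)
        return np.maximum(1.0 + slope * (x - self.reference), 1e-6)


@dataclass
class ModelSpec:
    """The full hierarchical model: fixed effects, covariate terms, IIV, error.

    ``theta`` maps coefficient names to values and always contains
    ``theta_cl`` and ``theta_v``; covariate terms reference additional
    entries.  One log-normal random effect acts on clearance (its SD in
    ``omega``); Ka is fixed and never estimated.
    """

    theta: dict[str, float]
    covariate_terms: list[CovariateTerm]
    omega: "OmegaSpec"
    error: "ErrorModel"
    ka_fixed_h: float = 1.9
    age_reference_y: float = 5.0

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            theta=dict(self.theta),
            covariate_terms=list(self.covariate_terms),
            omega=self.omega,
            error=self.error,
            ka_fixed_h=self.ka_fixed_h,
            age_reference_y=self.age_reference_y,
        )

    def typical_cl(self, covariates: Mapping[str, np.ndarray]) -> np.ndarray:
        """Typical (population) CL/F for arrays of subject covariates."""
        return self.typical_cl_with(self.theta, covariates)

    def typical_cl_with(
        self, theta: Mapping[str, float], covariates: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        """Typical CL/F evaluated at trial parameter values ``theta``."""
        first = next(iter(covariates.values())) if covariates else np.array([0.0])
        out = np.full(np.asarray(first).shape, theta["theta_cl"], dtype=float)
        for term in self.covariate_terms:
            if term.covariate not in covariates:
                raise KeyError(
                    f"covariate {term.covariate!r} required by the model is missing"
                )
            out = out * term.multiplier(theta, covariates[term.covariate])
        return out


def typical_clearance(
    theta: ThetaVector,
    age_y: float,
    abcb1_genotype: str,
    age_reference_y: float = 5.0,
) -> float:
    """Typical CL/F (L/h) of the final model for an age and ABCB1 genotype.

    The age effect is a power model on age normalized to the reference
    age (5 years); genotype multipliers apply relative to the AA
    wild type.
    """
    if age_y <= 0:
        raise ValueError(f"age_y must be > 0, got {age_y}")
    mult = {"AA": 1.0, "AG": theta.theta_abcb1_ag, "GG": theta.theta_abcb1_gg}
    if abcb1_genotype not in mult:
        raise ValueError(
            f"unknown genotype {abcb1_genotype!r} for SNP {ABCB1_SNP}; "
            "expected one of ['AA', 'AG', 'GG']"
        )
    return (
        theta.theta_cl
        * (age_y / age_reference_y) ** theta.theta_age
        * mult[abcb1_genotype]
    )


def individual_clearance(typical_cl: float, eta: float) -> float:
    """Individual CL/F under the exponential (log-normal) IIV model."""
    if typical_cl <= 0:
        raise ValueError(f"typical_cl must be > 0, got {typical_cl}")
    return typical_cl * math.exp(eta)


def steady_state_conc(
    params: PKParameters,
    regimen: Regimen,
    t_after_dose_h: float | np.ndarray,
) -> float | np.ndarray:
    """Steady-state concentration (mg/L) ``t`` hours after a maintenance dose.

    Closed-form superposition solution of the one-compartment model with
    first-order absorption at dosing interval tau:

        C(t) = D*ka / (V*(ka-ke)) * [ exp(-ke t)/(1-exp(-ke tau))
                                      - exp(-ka t)/(1-exp(-ka tau)) ]

    The expression is linear in dose.  When ka == ke (flip-flop
    degeneracy) the analytic limit is used.
    """
    t = np.asarray(t_after_dose_h, dtype=float)
    if np.any(t <= 0) or np.any(t > regimen.tau_h):
        raise ValueError(
            f"time after dose must lie in (0, tau={regimen.tau_h}], got {t_after_dose_h}"
        )
    out = _ss_conc_arrays(
        dose=regimen.dose_mg,
        tau=regimen.tau_h,
        t=t,
        ke=np.asarray(params.ke_h, dtype=float),
        ka=params.ka_h,
        v=params.v_f_L,
    )
    return float(out) if np.isscalar(t_after_dose_h) else out


def _ss_conc_arrays(dose, tau, t, ke, ka, v):
    """Vectorized steady-state concentration; broadcasts over t/ke/dose."""
    dose, t, ke = np.broadcast_arrays(
        np.asarray(dose, float), np.asarray(t, float), np.asarray(ke, float)
    )
    degenerate = np.abs(ka - ke) < _FLIP_FLOP_TOL * ka
    ke_safe = np.where(degenerate, ka * (1.0 + 1e-3), ke)
    acc_e = np.exp(-ke_safe * t) / (1.0 - np.exp(-ke_safe * tau))
    acc_a = np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
    regular = dose * ka / (v * (ka - ke_safe)) * (acc_e - acc_a)
    if np.any(degenerate):
        # limit ka -> ke of the superposition sum:
        # C(t) = (D/V) k e^{-kt} [ t/(1-r) + tau r/(1-r)^2 ],  r = e^{-k tau}
        r = np.exp(-ka * tau)
        lim = (
            dose / v * ka * np.exp(-ka * t) * (t / (1.0 - r) + tau * r / (1.0 - r) ** 2)
        )
        regular = np.where(degenerate, lim, regular)
    return regular


def predict_trough(model: ModelSpec, subject: Subject, eta: float = 0.0) -> float:
    """Model-predicted steady-state trough (mg/L) for a subject.

    Composes the covariate clearance model, the log-normal individual
    deviation ``eta`` and the closed-form steady-state solution at the
    pre-dose time t = tau.  ``eta = 0`` gives the population prediction.
    """
    if subject.regimen is None:
        raise ValueError(f"subject {subject.id} has no dosing regimen")
    covs = _subject_covariates(subject)
    tvcl = float(model.typical_cl({k: np.asarray([v]) for k, v in covs.items()})[0])
    cl_i = individual_clearance(tvcl, eta)
    params = PKParameters(
        cl_f_L_h=cl_i, v_f_L=model.theta["theta_v"], ka_h=model.ka_fixed_h
    )
    return steady_state_conc(params, subject.regimen, subject.regimen.tau_h)


def _subject_covariates(subject: Subject) -> dict[str, object]:
    """Flatten a Subject into the covariate namespace used by ModelSpec."""
    covs: dict[str, object] = {
        "AGE": subject.age_y,
        "WT": subject.weight_kg,
        "SEX": subject.sex,
    }
    if subject.regimen is not None:
        covs["TDD"] = subject.daily_dose_mg_kg
    for snp, label in subject.genotypes.items():
        covs[snp] = label
    for drug in subject.comeds:
        covs[drug] = "1"
    return covs


def superposition_conc(
    params: PKParameters,
    regimen: Regimen,
    t_after_dose_h: float,
    n_doses: int = 200,
) -> float:
    """Steady-state concentration by explicit superposition of single doses.

    Brute-force check of the closed form: sums ``n_doses`` single-dose
    profiles spaced tau apart.  The omitted tail decays like
    exp(-ke * n * tau).
    """
    ke, ka, v = params.ke_h, params.ka_h, params.v_f_L
    total = 0.0
    for n in range(n_doses):
        t = t_after_dose_h + n * regimen.tau_h
        total += (
            regimen.dose_mg * ka / (v * (ka - ke)) * (math.exp(-ke * t) - math.exp(-ka * t))
        )
    return total
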