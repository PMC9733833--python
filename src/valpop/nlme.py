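"""Nonlinear mixed-effects estimation for the one-random-effect PK model.

The hierarchical model has a single log-normal random effect on
clearance (eta ~ N(0, omega^2)) and a residual error model (additive,
proportional or combined).  Because only one random effect exists, the
per-subject marginal likelihood

    L_i = integral  prod_j N(y_ij; f_ij(eta), sigma_ij^2)  N(eta; 0, omega^2)  d eta

is a one-dimensional integral and can be computed essentially exactly by
adaptive Gauss-Hermite quadrature centered at the conditional mode.
That exact engine is the default; a FOCE-I linearization (the classical
first-order-conditional approximation with interaction) is provided as
an alternative for fidelity comparisons.

The objective function value (OFV) is -2 times the total marginal
log-likelihood, the scale on which likelihood-ratio covariate tests
(delta-OFV > 3.84 for 1 df) operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize

from .structural import ModelSpec, Observation, Subject, _ss_conc_arrays

__all__ = [
    "OmegaSpec",
    "ErrorModel",
    "FitResult",
    "GOFRecord",
    "LikelihoodKernel",
    "subject_marginal_loglik",
    "ofv",
    "fit",
    "empirical_bayes_eta",
    "shrinkage",
    "cwres",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: parameters constrained positive and hence estimated on the log scale
_LOG_SCALE_PREFIXES = ("theta_cl", "theta_v", "omega_cl", "sigma_add", "sigma_prop", "mult_")


@dataclass(frozen=True)
class OmegaSpec:
    """Inter-individual variability: SD of the log-scale random effect on CL."""

    omega_cl: float

    def __post_init__(self) -> None:
        if self.omega_cl < 0:
            raise ValueError(f"omega_cl must be >= 0, got {self.omega_cl}")


@dataclass(frozen=True)
class ErrorModel:
    """Residual error model: additive (mg/L), proportional, or combined."""

    kind: str
    sigma_add: float | None = None
    sigma_prop: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        need_add = self.kind in ("additive", "combined")
        need_prop = self.kind in ("proportional", "combined")
        if need_add and (self.sigma_add is None or self.sigma_add < 0):
            raise ValueError("sigma_add must be a non-negative number")
        if need_prop and (self.sigma_prop is None or self.sigma_prop < 0):
            raise ValueError("sigma_prop must be a non-negative number")
        if not need_add and self.sigma_add is not None:
            raise ValueError("sigma_add given for a model without an additive part")
        if not need_prop and self.sigma_prop is not None:
            raise ValueError("sigma_prop given for a model without a proportional part")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        if self.kind == "additive":
            return ("sigma_add",)
        if self.kind == "proportional":
            return ("sigma_prop",)
        return ("sigma_add", "sigma_prop")

    def sigma(self, pred: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        if self.kind == "additive":
            s = np.full_like(pred, params["sigma_add"])
        elif self.kind == "proportional":
            s = params["sigma_prop"] * np.abs(pred)
        else:
            s = np.sqrt(params["sigma_add"] ** 2 + (params["sigma_prop"] * pred) ** 2)
        return np.maximum(s, 1e-10)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: dict[str, float]
    rse_pct: dict[str, float]
    ofv: float
    aic: float
    bic: float
    ebes: dict[str, float]
    eta_shrinkage_pct: float | None
    eps_shrinkage_pct: float | None
    converged: bool
    n_subjects: int
    n_obs: int
    n_parameters: int
    model: ModelSpec
    fixed: frozenset[str] = field(default_factory=frozenset)
    hessian_pd: bool | None = None
    message: str = ""


@dataclass(frozen=True)
class GOFRecord:
    """Per-observation goodness-of-fit record."""

    subject_id: str
    time_after_dose_h: float
    dv: float
    pred: float
    ipred: float
    cwres: float


class LikelihoodKernel:
    """Vectorized likelihood evaluation for one model structure on one dataset.

    Precomputes flat observation arrays and the per-subject covariate
    namespace so that repeated evaluations during optimization stay
    cheap.  Parameters are passed as a flat mapping containing the
    structural thetas plus ``omega_cl`` and the residual sigmas.
    """

    def __init__(self, dataset, model_template: ModelSpec):
        self.model = model_template.copy()
        subs = dataset.subjects.reset_index(drop=True)
        obs = dataset.observations
        self.ids: list[str] = subs["ID"].astype(str).tolist()
        idx = {sid: k for k, sid in enumerate(self.ids)}
        self.subj_idx = obs["ID"].astype(str).map(idx).to_numpy()
        if np.any(~np.isfinite(self.subj_idx.astype(float))):
            raise ValueError("observation rows reference unknown subject IDs")
        self.y = obs["DV"].to_numpy(dtype=float)
        self.t = obs["TIME_H"].to_numpy(dtype=float)
        self.dose = obs["DOSE_MG"].to_numpy(dtype=float)
        self.tau = obs["II_H"].to_numpy(dtype=float)
        self.n_subjects = len(self.ids)
        self.n_obs = len(self.y)
        self.obs_per_subject = np.bincount(self.subj_idx, minlength=self.n_subjects)
        self._covariates = self._build_covariates(subs, obs)
        self._hermite: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ---------------------------------------------------
    def _build_covariates(self, subs, obs) -> dict[str, np.ndarray]:
        continuous = {"linear", "power", "exponential", "piecewise"}
        covs: dict[str, np.ndarray] = {}
        for term in self.model.covariate_terms:
            name = term.covariate
            if name == "TDD" and "TDD" not in subs.columns:
                tdd = self.dose * (24.0 / self.tau) / subs["WT"].to_numpy(float)[self.subj_idx]
                col = np.bincount(self.subj_idx, tdd, self.n_subjects) / np.maximum(
                    self.obs_per_subject, 1
                )
            elif name in subs.columns:
                col = subs[name].to_numpy()
            else:
                raise KeyError(f"covariate {name!r} not found in the subject table")
            if term.form in continuous:
                covs[name] = np.asarray(col, dtype=float)
            else:
                covs[name] = np.asarray(col).astype(str)
        return covs

    def _nodes(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        if n not in self._hermite:
            x, w = hermgauss(n)
            self._hermite[n] = (x, np.log(w) + x**2)
        return self._hermite[n]

    # -- model evaluation ------------------------------------------------
    def typical_cl(self, params: Mapping[str, float]) -> np.ndarray:
        tv = self.model.typical_cl_with(params, self._covariates)
        if tv.shape != (self.n_subjects,):  # covariate-free model
            tv = np.full(self.n_subjects, float(tv.ravel()[0]))
        return tv

    def predict(self, params: Mapping[str, float], eta: np.ndarray) -> np.ndarray:
        """Predicted concentration per observation given per-subject eta."""
        tvcl = self.typical_cl(params)
        cl = tvcl * np.exp(eta)
        ke = cl[self.subj_idx] / params["theta_v"]
        return _ss_conc_arrays(
            dose=self.dose,
            tau=self.tau,
            t=self.t,
            ke=ke,
            ka=self.model.ka_fixed_h,
            v=params["theta_v"],
        )

    def _obs_loglik(self, params: Mapping[str, float], f: np.ndarray) -> np.ndarray:
        s = self.model.error.sigma(f, params)
        return -0.5 * (_LOG_2PI + 2.0 * np.log(s) + ((self.y - f) / s) ** 2)

    def subject_loglik_at_eta(
        self, params: Mapping[str, float], eta: np.ndarray
    ) -> np.ndarray:
        """Per-subject conditional data log-likelihood at fixed eta (no prior)."""
        ll = self._obs_loglik(params, self.predict(params, eta))
        return np.bincount(self.subj_idx, ll, self.n_subjects)

    def _penalized(self, params: Mapping[str, float], eta: np.ndarray) -> np.ndarray:
        """log p(y_i | eta_i) + log p(eta_i): the AGQ/FOCE integrand (log)."""
        w = params["omega_cl"]
        prior = -0.5 * (_LOG_2PI + 2.0 * math.log(w)) - eta**2 / (2.0 * w**2)
        return self.subject_loglik_at_eta(params, eta) + prior

    # -- conditional mode ------------------------------------------------
    def conditional_mode(
        self, params: Mapping[str, float], tol: float = 1e-10, max_iter: int = 100
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject mode of the penalized log-likelihood and its curvature.

        Damped Newton iteration with central finite differences,
        vectorized across subjects.  Returns (eta_hat, h) where
        h = -d^2 g / d eta^2 at the mode (positive for a proper mode).
        """
        w = params["omega_cl"]
        if w == 0:
            return np.zeros(self.n_subjects), np.full(self.n_subjects, np.inf)
        d = 1e-4
        eta = np.zeros(self.n_subjects)
        g0 = self._penalized(params, eta)
        hess = np.full(self.n_subjects, -1.0 / w**2)
        for _ in range(max_iter):
            gp = self._penalized(params, eta + d)
            gm = self._penalized(params, eta - d)
            grad = (gp - gm) / (2.0 * d)
            hess = (gp - 2.0 * g0 + gm) / d**2
            step = np.where(
                hess < -1e-12, -grad / hess, np.sign(grad) * 0.5
            )
            step = np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < tol:
                break
            # backtracking: only accept steps that do not decrease g
            new_eta = eta + step
            g_new = self._penalized(params, new_eta)
            for _bt in range(25):
                worse = g_new < g0 - 1e-13
                if not np.any(worse):
                    break
                step = np.where(worse, step / 2.0, step)
                new_eta = eta + step
                g_new = self._penalized(params, new_eta)
            eta, g0 = new_eta, g_new
        return eta, -hess

    # -- marginal likelihood ----------------------------------------------
    def subject_logliks(
        self,
        params: Mapping[str, float],
        engine: str = "agq",
        n_nodes: int = 41,
    ) -> np.ndarray:
        """Marginal log-likelihood contribution of every subject."""
        w = params["omega_cl"]
        if w == 0:
            return self.subject_loglik_at_eta(params, np.zeros(self.n_subjects))
        if engine == "agq":
            return self._agq_logliks(params, n_nodes)
        if engine == "foce":
            return self._foce_logliks(params)
        raise ValueError(f"unknown engine {engine!r}; expected 'agq' or 'foce'")

    def _agq_logliks(self, params: Mapping[str, float], n_nodes: int) -> np.ndarray:
        mode, h = self.conditional_mode(params)
        w = params["omega_cl"]
        sd = np.where(h > 1e-12, 1.0 / np.sqrt(np.maximum(h, 1e-12)), w)
        x, logw_x2 = self._nodes(n_nodes)
        G = np.empty((self.n_subjects, n_nodes))
        for k in range(n_nodes):
            G[:, k] = self._penalized(params, mode + math.sqrt(2.0) * sd * x[k])
        A = G + logw_x2[None, :]
        m = A.max(axis=1)
        return m + np.log(np.sum(np.exp(A - m[:, None]), axis=1)) + np.log(
            math.sqrt(2.0) * sd
        )

    def _foce_logliks(self, params: Mapping[str, float]) -> np.ndarray:
        """FOCE-I approximation: linearize f in eta around the conditional mode."""
        mode, _ = self.conditional_mode(params)
        w2 = params["omega_cl"] ** 2
        d = 1e-4
        f0 = self.predict(params, mode)
        F = (self.predict(params, mode + d) - self.predict(params, mode - d)) / (2 * d)
        R = self.model.error.sigma(f0, params) ** 2  # interaction: sigma at eta-hat
        resid = self.y - f0 + F * mode[self.subj_idx]
        A = np.bincount(self.subj_idx, F * F / R, self.n_subjects)
        b = np.bincount(self.subj_idx, F * resid / R, self.n_subjects)
        quad = np.bincount(self.subj_idx, resid * resid / R, self.n_subjects)
        quad -= w2 * b**2 / (1.0 + w2 * A)
        logdet = np.bincount(self.subj_idx, np.log(R), self.n_subjects)
        logdet += np.log1p(w2 * A)
        n_i = self.obs_per_subject
        return -0.5 * (n_i * _LOG_2PI + logdet + quad)

    def ofv(self, params: Mapping[str, float], engine: str = "agq", n_nodes: int = 41) -> float:
        return -2.0 * float(np.sum(self.subject_logliks(params, engine, n_nodes)))


# ---------------------------------------------------------------------------
# free functions on (model, dataset)
# ---------------------------------------------------------------------------


def _model_params(model: ModelSpec) -> dict[str, float]:
    """Flatten a ModelSpec into the parameter mapping used by the kernel."""
    params = dict(model.theta)
    params["omega_cl"] = model.omega.omega_cl
    for name in model.error.parameter_names:
        params[name] = getattr(model.error, name)
    return params


def _model_with_params(model: ModelSpec, params: Mapping[str, float]) -> ModelSpec:
    """Rebuild a ModelSpec carrying updated parameter values."""
    out = model.copy()
    out.theta = {k: float(params[k]) for k in model.theta}
    out.omega = OmegaSpec(float(params["omega_cl"]))
    err = {n: float(params[n]) for n in model.error.parameter_names}
    out.error = ErrorModel(kind=model.error.kind, **err)
    return out


def _single_subject_dataset(subject: Subject, observations: Sequence[Observation]):
    from .io import dataset_from_subjects

    return dataset_from_subjects([subject], list(observations))


def subject_marginal_loglik(
    model: ModelSpec,
    subject_obs: Sequence[Observation],
    subject: Subject,
    engine: str = "agq",
    n_nodes: int = 41,
) -> float:
    """Marginal log-likelihood of one subject's observations.

    The integral over the subject's random effect is evaluated by
    adaptive Gauss-Hermite quadrature (default) or the FOCE-I
    linearization.
    """
    if len(subject_obs) == 0:
        raise ValueError(f"subject {subject.id} has no observations")
    ds = _single_subject_dataset(subject, subject_obs)
    kern = LikelihoodKernel(ds, model)
    return float(kern.subject_logliks(_model_params(model), engine, n_nodes)[0])


def ofv(model: ModelSpec, dataset, engine: str = "agq", n_nodes: int = 41) -> float:
    """Objective function value: -2 x total marginal log-likelihood."""
    kern = LikelihoodKernel(dataset, model)
    return kern.ofv(_model_params(model), engine, n_nodes)


def _is_log_scale(name: str) -> bool:
    return name.startswith(_LOG_SCALE_PREFIXES)


def fit(
    model_template: ModelSpec,
    dataset,
    inits: Mapping[str, float] | None = None,
    fixed: Iterable[str] = (),
    engine: str = "agq",
    n_nodes: int = 41,
    method: str = "L-BFGS-B",
    maxiter: int = 500,
    tol: float = 1e-6,
    compute_rse: bool = True,
    compute_ebes: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of all non-fixed parameters.

    Scale parameters (typical values, multipliers, omega, sigma) are
    log-transformed internally so positivity never needs explicit
    constraints; exponents and slopes are estimated unconstrained.
    Non-convergence is reported through the ``converged`` flag rather
    than raised, so resampling procedures can count failures.
    """
    kern = LikelihoodKernel(dataset, model_template)
    base = _model_params(model_template)
    if inits:
        unknown = set(inits) - set(base)
        if unknown:
            raise KeyError(f"inits reference unknown parameters: {sorted(unknown)}")
        base.update(inits)
    fixed = frozenset(fixed)
    free = [n for n in base if n not in fixed]
    for n in free:
        if _is_log_scale(n) and base[n] <= 0:
            raise ValueError(f"initial value for {n} must be > 0, got {base[n]}")

    def pack(params: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [math.log(params[n]) if _is_log_scale(n) else params[n] for n in free]
        )

    def unpack(x: np.ndarray) -> dict[str, float]:
        out = dict(base)
        for n, v in zip(free, x):
            out[n] = math.exp(v) if _is_log_scale(n) else float(v)
        return out

    def objective(x: np.ndarray) -> float:
        try:
            val = kern.ofv(unpack(x), engine, n_nodes)
        except (FloatingPointError, ValueError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    x0 = pack(base)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = minimize(
            objective,
            x0,
            method=method,
            options={"maxiter": maxiter},
            tol=tol,
        )
    params_hat = unpack(res.x)
    ofv_hat = float(res.fun)
    p = len(free)
    aic = ofv_hat + 2.0 * p
    bic = ofv_hat + p * math.log(kern.n_obs)
    fitted = _model_with_params(model_template, params_hat)

    rse: dict[str, float] = {}
    hessian_pd: bool | None = None
    if compute_rse and p > 0:
        cov, hessian_pd = _rse_covariance(kern, params_hat, free, engine, n_nodes)
        for i, n in enumerate(free):
            if cov is not None and cov[i, i] > 0:
                rse[n] = 100.0 * math.sqrt(cov[i, i]) / abs(params_hat[n])
            else:
                rse[n] = float("nan")

    ebes: dict[str, float] = {}
    eta_shr = eps_shr = None
    if compute_ebes:
        mode, _ = kern.conditional_mode(params_hat)
        ebes = dict(zip(kern.ids, mode.tolist()))
        ipred = kern.predict(params_hat, mode)
        iwres = (kern.y - ipred) / fitted.error.sigma(ipred, params_hat)
        eta_shr, eps_shr = shrinkage(mode, params_hat["omega_cl"], iwres)

    return FitResult(
        estimates={n: float(params_hat[n]) for n in base},
        rse_pct=rse,
        ofv=ofv_hat,
        aic=aic,
        bic=bic,
        ebes=ebes,
        eta_shrinkage_pct=eta_shr,
        eps_shrinkage_pct=eps_shr,
        converged=bool(res.success),
        n_subjects=kern.n_subjects,
        n_obs=kern.n_obs,
        n_parameters=p,
        model=fitted,
        fixed=fixed,
        hessian_pd=hessian_pd,
        message=str(res.message),
    )


def _rse_covariance(
    kern: LikelihoodKernel,
    params: Mapping[str, float],
    free: list[str],
    engine: str,
    n_nodes: int,
) -> tuple[np.ndarray | None, bool]:
    """Covariance of the estimates from the finite-difference OFV Hessian.

    OFV = -2 log L, so cov = 2 * H_OFV^{-1}; relative central-difference
    steps of 1e-3 on the natural scale.
    """
    p = len(free)
    h = np.array([1e-3 * max(abs(params[n]), 1e-3) for n in free])

    def f(x: np.ndarray) -> float:
        pp = dict(params)
        pp.update({n: float(v) for n, v in zip(free, x)})
        if any(_is_log_scale(n) and pp[n] <= 0 for n in free):
            return float("nan")
        return kern.ofv(pp, engine, n_nodes)

    x0 = np.array([params[n] for n in free])
    f0 = f(x0)
    H = np.empty((p, p))
    with np.errstate(all="ignore"):
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = h[i]
            H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            for j in range(i):
                ej = np.zeros(p)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None, False
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.min(eigvals) <= 0:
            return None, False
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, False
    return cov, True


def empirical_bayes_eta(
    model: ModelSpec, subject: Subject, subject_obs: Sequence[Observation]
) -> float:
    """Conditional-mode empirical Bayes estimate of a subject's eta.

    With no observations the posterior equals the prior and the mode
    is 0; the same limit applies as omega -> 0.
    """
    if len(subject_obs) == 0 or model.omega.omega_cl == 0:
        return 0.0
    ds = _single_subject_dataset(subject, subject_obs)
    kern = LikelihoodKernel(ds, model)
    mode, _ = kern.conditional_mode(_model_params(model))
    return float(mode[0])


def shrinkage(
    ebes: np.ndarray, omega_cl: float, iwres: np.ndarray | None = None
) -> tuple[float | None, float | None]:
    """Eta- and epsilon-shrinkage in percent.

    eta-shrinkage = 100 * (1 - SD(eta_hat) / omega); with sparse data
    the EBEs contract toward the prior mode and shrinkage rises toward
    100%.  eps-shrinkage = 100 * (1 - SD(IWRES)).  Undefined (None)
    when omega = 0 or IWRES are not supplied.
    """
    eta_shr = None
    if omega_cl > 0:
        sd = float(np.std(np.asarray(ebes, dtype=float), ddof=1)) if len(ebes) > 1 else 0.0
        eta_shr = 100.0 * (1.0 - sd / omega_cl)
    eps_shr = None
    if iwres is not None and len(iwres) > 1:
        eps_shr = 100.0 * (1.0 - float(np.std(np.asarray(iwres, dtype=float), ddof=1)))
    return eta_shr, eps_shr


def cwres(model: ModelSpec, fit_result: FitResult | None, dataset) -> list[GOFRecord]:
    """Conditional weighted residuals and predictions per observation.

    Uses the FOCE linearization around each subject's conditional mode:
    the residual vector (relative to the linearized marginal mean) is
    decorrelated by the inverse matrix square root of the model-implied
    covariance V_i = omega^2 F F' + R.  Under the true model CWRES are
    approximately standard normal.
    """
    mdl = fit_result.model if fit_result is not None else model
    kern = LikelihoodKernel(dataset, mdl)
    params = _model_params(mdl)
    w2 = params["omega_cl"] ** 2
    mode, _ = kern.conditional_mode(params)
    pred = kern.predict(params, np.zeros(kern.n_subjects))
    f0 = kern.predict(params, mode)
    d = 1e-4
    F = (kern.predict(params, mode + d) - kern.predict(params, mode - d)) / (2 * d)
    R = mdl.error.sigma(f0, params) ** 2
    resid = kern.y - f0 + F * mode[kern.subj_idx]
    cw = np.empty(kern.n_obs)
    for i, sid in enumerate(kern.ids):
        sel = kern.subj_idx == i
        Fi = F[sel]
        Vi = w2 * np.outer(Fi, Fi) + np.diag(R[sel])
        vals, vecs = np.linalg.eigh(Vi)
        if np.min(vals) <= 1e-12:
            raise ValueError(f"singular observation covariance for subject {sid}")
        inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
        cw[sel] = inv_sqrt @ resid[sel]
    return [
        GOFRecord(
            subject_id=kern.ids[kern.subj_idx[j]],
            time_after_dose_h=float(kern.t[j]),
            dv=float(kern.y[j]),
            pred=float(pred[j]),
            ipred=float(f0[j]),
            cwres=float(cw[j]),
        )
        for j in range(kern.n_obs)
    ]
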