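"""Stepwise covariate selection on clearance by likelihood-ratio testing.

Forward inclusion adds, one at a time, the candidate covariate (in its
best functional form) whose inclusion drops the objective function
value the most, provided the drop exceeds the chi-square criterion
(3.84 for a 1-df term, p < 0.05).  Backward elimination then removes
any retained term whose deletion raises the OFV by less than a stricter
criterion (6.635 for 1 df, p < 0.01, the conventional backward cut).
Multi-parameter terms (piecewise, three-level genotypes) are judged
against the chi-square quantile for their own degrees of freedom at the
same alpha; a flat threshold is available via ``df_adjust=False``.

Continuous candidates are tried as linear, power, exponential and
piecewise effects; categorical candidates as per-level multipliers.
Co-medications taken by too small a fraction of the cohort and SNPs
failing the Hardy-Weinberg screen never enter the search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hwe import counts_from_subjects, hwe_screen
from .nlme import FitResult, fit
from .structural import CovariateTerm, ModelSpec

log = logging.getLogger("valpop")

CONTINUOUS_FORMS = ("linear", "power", "exponential", "piecewise")

#: default references for centering continuous covariates
_REFERENCES = {"AGE": 5.0, "WT": 20.0}


@dataclass(frozen=True)
class CandidateCovariate:
    """One covariate offered to the stepwise search."""

    name: str
    kind: str  # {"continuous", "categorical"}
    forms_to_try: tuple[str, ...] = CONTINUOUS_FORMS
    levels: tuple[str, ...] | None = None  # categorical, reference level first

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not self.forms_to_try:
            raise ValueError("candidate needs at least one functional form")
        if self.kind == "categorical" and (self.levels is None or len(self.levels) < 2):
            raise ValueError("categorical candidate needs ordered levels")


@dataclass(frozen=True)
class StepRecord:
    """One decision of the stepwise trace (Table-style audit record)."""

    step_index: int
    action: str  # {"add", "remove", "stop"}
    covariate: str | None
    form: str | None
    ofv_before: float
    ofv_after: float
    delta_ofv: float
    accepted: bool


def screen_candidates(
    dataset,
    comed_threshold_pct: float = 2.5,
    hwe_alpha: float = 0.05,
    include_continuous: bool = True,
) -> list[CandidateCovariate]:
    """Assemble the candidate list from a dataset.

    Continuous: AGE, WT and TDD (daily dose in mg/kg/day).  Categorical:
    SEX, co-medications taken by more than ``comed_threshold_pct`` % of
    subjects, and genotypes of panel SNPs that pass the Hardy-Weinberg
    screen (three-level: wild type / heterozygous / homozygous).
    """
    from .datasets import COMEDICATION_RATES, SNP_PANEL

    subs = dataset.subjects
    out: list[CandidateCovariate] = []
    if include_continuous:
        for name in ("AGE", "WT", "TDD"):
            out.append(CandidateCovariate(name, "continuous"))
    if "SEX" in subs.columns:
        out.append(
            CandidateCovariate("SEX", "categorical", ("multiplier",), ("0", "1"))
        )
    for drug in COMEDICATION_RATES:
        if drug not in subs.columns:
            continue
        pct = 100.0 * float(pd.to_numeric(subs[drug]).mean())
        if pct > comed_threshold_pct:
            out.append(
                CandidateCovariate(drug, "categorical", ("multiplier",), ("0", "1"))
            )
        else:
            log.info(
                "co-medication %s excluded: %.1f%% of subjects <= %.1f%% threshold",
                drug, pct, comed_threshold_pct,
            )
    retained, excluded = hwe_screen(counts_from_subjects(subs), alpha=hwe_alpha)
    for snp in excluded:
        log.info("SNP %s excluded: deviates from Hardy-Weinberg equilibrium", snp)
    for snp in retained:
        out.append(
            CandidateCovariate(
                snp, "categorical", ("multiplier",), SNP_PANEL[snp].genotype_labels
            )
        )
    return out


def _reference(name: str, dataset) -> float:
    if name in _REFERENCES:
        return _REFERENCES[name]
    if name == "TDD":
        obs = dataset.observations
        wt = dataset.subjects.set_index("ID")["WT"]
        tdd = obs["DOSE_MG"] * (24.0 / obs["II_H"]) / wt.loc[obs["ID"]].to_numpy()
        return float(np.median(tdd))
    raise KeyError(f"no centering reference defined for covariate {name!r}")


def candidate_term(
    cand: CandidateCovariate, form: str, dataset
) -> tuple[CovariateTerm, dict[str, float], int]:
    """Build the CovariateTerm, neutral initial values and df for one form."""
    if cand.kind == "categorical":
        coefs = tuple(f"mult_{cand.name}_{lvl}" for lvl in cand.levels[1:])
        term = CovariateTerm(
            covariate=cand.name, form="multiplier", coefficients=coefs, levels=cand.levels
        )
        return term, {c: 1.0 for c in coefs}, len(coefs)
    ref = _reference(cand.name, dataset)
    if form == "piecewise":
        coefs = (f"beta_{cand.name}_lo", f"beta_{cand.name}_hi")
        term = CovariateTerm(
            covariate=cand.name, form=form, coefficients=coefs, reference=ref
        )
        return term, {c: 0.0 for c in coefs}, 2
    coef = f"beta_{cand.name}_{form}"
    term = CovariateTerm(
        covariate=cand.name, form=form, coefficients=(coef,), reference=ref
    )
    return term, {coef: 0.0}, 1


def _with_term(model: ModelSpec, term: CovariateTerm, inits: Mapping[str, float]) -> ModelSpec:
    out = model.copy()
    out.covariate_terms = list(model.covariate_terms) + [term]
    out.theta = {**model.theta, **inits}
    return out


def _without_covariate(model: ModelSpec, covariate: str) -> ModelSpec:
    out = model.copy()
    dropped = [t for t in model.covariate_terms if t.covariate == covariate]
    if not dropped:
        raise KeyError(f"model has no term on covariate {covariate!r}")
    out.covariate_terms = [t for t in model.covariate_terms if t.covariate != covariate]
    gone = {c for t in dropped for c in t.coefficients}
    out.theta = {k: v for k, v in model.theta.items() if k not in gone}
    return out


def _threshold(df: int, base: float, df_adjust: bool) -> float:
    """Chi-square acceptance threshold for a df-parameter term.

    ``base`` is the 1-df cut (e.g. 3.84); with ``df_adjust`` the cut for
    larger df is the chi-square quantile at the same tail probability
    (3.84 -> 5.99 for 2 df).
    """
    if df == 1 or not df_adjust:
        return base
    alpha = float(stats.chi2.sf(base, df=1))
    return float(stats.chi2.isf(alpha, df=df))


def forward_step(
    current_fit: FitResult,
    candidates: Sequence[CandidateCovariate],
    dataset,
    delta_threshold: float = 3.84,
    df_adjust: bool = True,
    step_index: int = 0,
    **fit_kwargs,
) -> tuple[StepRecord, FitResult]:
    """Try every remaining candidate x form; accept the largest OFV drop.

    Returns the accepted add-record and updated fit, or a stop-record
    with the fit unchanged.  Candidates whose trial fit fails to
    converge are skipped and logged.  Ties in OFV are broken by lower
    AIC, then by fewer added parameters.
    """
    in_model = {t.covariate for t in current_fit.model.covariate_terms}
    best: tuple | None = None  # (drop, -aic-rank keys..., fit, cand, form)
    for cand in candidates:
        if cand.name in in_model:
            continue
        for form in cand.forms_to_try:
            term, inits, df = candidate_term(cand, form, dataset)
            trial = _with_term(current_fit.model, term, inits)
            try:
                fr = fit(
                    trial, dataset, inits={**current_fit.estimates, **inits},
                    compute_rse=False, compute_ebes=False, **fit_kwargs,
                )
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                log.warning("candidate %s (%s) failed: %s", cand.name, form, exc)
                continue
            if not fr.converged:
                log.warning("candidate %s (%s) did not converge; skipped", cand.name, form)
                continue
            drop = current_fit.ofv - fr.ofv
            if drop <= _threshold(df, delta_threshold, df_adjust):
                continue
            key = (round(drop, 6), -round(fr.aic, 6), -df)
            if best is None or key > best[0]:
                best = (key, fr, cand, form, drop)
    if best is None:
        rec = StepRecord(
            step_index, "stop", None, None, current_fit.ofv, current_fit.ofv, 0.0, False
        )
        return rec, current_fit
    _, fr, cand, form, drop = best
    rec = StepRecord(
        step_index, "add", cand.name, form, current_fit.ofv, fr.ofv, fr.ofv - current_fit.ofv,
        True,
    )
    return rec, fr


def backward_step(
    current_fit: FitResult,
    dataset,
    removal_threshold: float = 6.635,
    df_adjust: bool = False,
    step_index: int = 0,
    **fit_kwargs,
) -> tuple[StepRecord, FitResult]:
    """Remove the weakest term if its deletion costs less than the cut.

    Each included term is deleted in turn and the model refit; the term
    whose removal raises the OFV the least is eliminated when that rise
    stays below the chi-square removal threshold for its df.
    """
    terms = current_fit.model.covariate_terms
    if not terms:
        raise ValueError("backward elimination needs at least one covariate in the model")
    best: tuple | None = None
    for term in terms:
        reduced = _without_covariate(current_fit.model, term.covariate)
        inits = {k: v for k, v in current_fit.estimates.items() if k in reduced.theta
                 or not k.startswith(("beta_", "mult_"))}
        try:
            fr = fit(reduced, dataset, inits=inits, compute_rse=False,
                     compute_ebes=False, **fit_kwargs)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            log.warning("removal of %s failed: %s", term.covariate, exc)
            continue
        if not fr.converged:
            log.warning("removal refit of %s did not converge; skipped", term.covariate)
            continue
        rise = fr.ofv - current_fit.ofv
        if rise >= _threshold(term.n_parameters, removal_threshold, df_adjust):
            continue
        if best is None or rise < best[0]:
            best = (rise, fr, term)
    if best is None:
        rec = StepRecord(
            step_index, "stop", None, None, current_fit.ofv, current_fit.ofv, 0.0, False
        )
        return rec, current_fit
    rise, fr, term = best
    rec = StepRecord(
        step_index, "remove", term.covariate, term.form, current_fit.ofv, fr.ofv,
        fr.ofv - current_fit.ofv, True,
    )
    return rec, fr


def run_stepwise(
    base_fit: FitResult,
    candidates: Sequence[CandidateCovariate],
    dataset,
    delta_threshold: float = 3.84,
    removal_threshold: float = 6.635,
    forward_df_adjust: bool = True,
    backward_df_adjust: bool = False,
    max_cycles: int = 4,
    **fit_kwargs,
) -> tuple[FitResult, list[StepRecord]]:
    """Alternate forward saturation and backward pruning until stable.

    Deterministic given the dataset; emits the full decision trace.
    Stops early if a covariate set recurs (an add/remove oscillation at
    a borderline criterion), keeping the richer of the two states.
    """
    records: list[StepRecord] = []
    current = base_fit
    step = 0
    seen: set[tuple[str, ...]] = set()
    for _cycle in range(max_cycles):
        changed = False
        while True:
            rec, current = forward_step(
                current, candidates, dataset, delta_threshold, forward_df_adjust,
                step_index=step, **fit_kwargs,
            )
            records.append(rec)
            step += 1
            if not rec.accepted:
                break
            changed = True
        while current.model.covariate_terms:
            rec, current = backward_step(
                current, dataset, removal_threshold, backward_df_adjust,
                step_index=step, **fit_kwargs,
            )
            records.append(rec)
            step += 1
            if not rec.accepted:
                break
            changed = True
        # state check at cycle end (after pruning): if a covariate set
        # recurs, a term is oscillating across the add/remove criteria -
        # keep the parsimonious post-elimination state and stop
        state = tuple(sorted(t.covariate for t in current.model.covariate_terms))
        if state in seen:
            log.warning("stepwise oscillation detected at %s; stopping", state)
            break
        seen.add(state)
        if not changed:
            break
    return current, records


def trace_frame(records: Iterable[StepRecord]) -> pd.DataFrame:
    """The stepwise trace as a tidy table (CSV-ready audit of decisions)."""
    return pd.DataFrame(
        [
            {
                "step": r.step_index,
                "action": r.action,
                "covariate": r.covariate,
                "form": r.form,
                "ofv_before": r.ofv_before,
                "ofv_after": r.ofv_after,
                "delta_ofv": r.delta_ofv,
                "accepted": r.accepted,
            }
            for r in records
        ]
    )
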