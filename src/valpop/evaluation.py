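"""Model evaluation: subject-level bootstrap, visual predictive check,
goodness-of-fit summaries.

The bootstrap resamples *subjects* (not observations) with replacement,
preserving within-subject correlation, refits each replicate from the
reference estimates and summarizes the successful runs by their median
and 2.5/97.5 percentile interval.  The VPC re-simulates the original
design many times from the fitted model and overlays the observed
5th/50th/95th percentiles on the simulation-based confidence band of
each percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import simulate_from_model
from .io import Dataset
from .nlme import FitResult, GOFRecord, cwres, fit

log = logging.getLogger("valpop")


@dataclass
class BootstrapResult:
    """Summary of a subject-resampling bootstrap."""

    n_runs: int
    n_success: int
    reference: dict[str, float]
    median: dict[str, float]
    ci_low: dict[str, float]  # 2.5th percentile
    ci_high: dict[str, float]  # 97.5th percentile
    relative_error_pct: dict[str, float]
    replicate_estimates: pd.DataFrame = field(repr=False, default=None)

    @property
    def success_rate_pct(self) -> float:
        return 100.0 * self.n_success / self.n_runs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.median:
            rows.append(
                {
                    "parameter": name,
                    "reference": self.reference[name],
                    "bootstrap_median": self.median[name],
                    "ci95_low": self.ci_low[name],
                    "ci95_high": self.ci_high[name],
                    "relative_error_pct": self.relative_error_pct[name],
                }
            )
        return pd.DataFrame(rows)


def relative_error_pct(bootstrap_median: float, reference: float) -> float:
    """Bootstrap relative error: 100 * (median - reference) / reference."""
    return 100.0 * (bootstrap_median - reference) / reference


def _resample_subjects(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    ids = dataset.subjects["ID"].to_numpy()
    picks = rng.choice(len(ids), size=len(ids), replace=True)
    sub_rows, obs_rows = [], []
    obs_by_id = {sid: g for sid, g in dataset.observations.groupby("ID", sort=False)}
    for k, i in enumerate(picks):
        new_id = f"B{k + 1:03d}"
        row = dataset.subjects.iloc[i].copy()
        row["ID"] = new_id
        sub_rows.append(row)
        og = obs_by_id[ids[i]].copy()
        og["ID"] = new_id
        obs_rows.append(og)
    return Dataset(
        subjects=pd.DataFrame(sub_rows).reset_index(drop=True),
        observations=pd.concat(obs_rows, ignore_index=True),
    )


def bootstrap(
    dataset: Dataset,
    model,
    n_runs: int = 1000,
    seed: int = 0,
    reference_fit: FitResult | None = None,
    check_hessian: bool = True,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric bootstrap of the parameter estimates.

    A replicate counts as successful when the optimizer converged and
    (by default) the OFV Hessian at its optimum is positive definite;
    failed replicates are counted but excluded from the percentiles.
    """
    if reference_fit is None:
        reference_fit = fit(model, dataset, **fit_kwargs)
    ref = {
        k: v
        for k, v in reference_fit.estimates.items()
        if k not in reference_fit.fixed
    }
    rng = np.random.default_rng(seed)
    rows = []
    n_success = 0
    for _run in range(n_runs):
        rep = _resample_subjects(dataset, rng)
        fr = fit(
            reference_fit.model,
            rep,
            inits=reference_fit.estimates,
            fixed=reference_fit.fixed,
            compute_rse=check_hessian,
            compute_ebes=False,
            **fit_kwargs,
        )
        ok = fr.converged and (fr.hessian_pd if check_hessian else True)
        if ok:
            n_success += 1
            rows.append({k: fr.estimates[k] for k in ref})
    if not rows:
        raise RuntimeError(
            f"all {n_runs} bootstrap replicates failed to converge; the model/"
            "dataset combination is unstable"
        )
    reps = pd.DataFrame(rows)
    med = reps.median().to_dict()
    lo = reps.quantile(0.025).to_dict()
    hi = reps.quantile(0.975).to_dict()
    rel = {k: relative_error_pct(med[k], ref[k]) for k in ref}
    return BootstrapResult(
        n_runs=n_runs,
        n_success=n_success,
        reference=ref,
        median=med,
        ci_low=lo,
        ci_high=hi,
        relative_error_pct=rel,
        replicate_estimates=reps,
    )


@dataclass
class VPCResult:
    """Visual-predictive-check table: observed percentiles vs simulated bands."""

    table: pd.DataFrame  # bin_low, bin_high, n_obs, percentile, observed, band_low, band_high
    binning: str
    n_sim: int

    def observed_in_band_pct(self, percentile: int | None = None) -> float:
        t = self.table
        if percentile is not None:
            t = t[t["percentile"] == percentile]
        ok = (t["observed"] >= t["band_low"]) & (t["observed"] <= t["band_high"])
        return 100.0 * float(ok.mean())

    def mean_band_width(self) -> float:
        return float((self.table["band_high"] - self.table["band_low"]).mean())


def _bin_edges(values: np.ndarray, n_bins: int, min_per_bin: int = 5) -> np.ndarray:
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    # merge bins that would hold fewer than min_per_bin observations
    while len(edges) > 2:
        counts, _ = np.histogram(values, bins=edges)
        small = np.where(counts < min_per_bin)[0]
        if len(small) == 0:
            break
        i = small[0]
        drop = i + 1 if i + 1 < len(edges) - 1 else i
        log.info("merging VPC bin %d (only %d observations)", i, counts[i])
        edges = np.delete(edges, drop)
    return edges


def vpc(
    dataset: Dataset,
    model,
    n_sim: int = 1000,
    seed: int = 0,
    binning: str = "time",
    n_bins: int = 6,
    percentiles: tuple[int, ...] = (5, 50, 95),
    band: tuple[float, float] = (2.5, 97.5),
    include_residual: bool = True,
) -> VPCResult:
    """Visual predictive check of a fitted model on its own design.

    ``binning`` is "time" (time after dose; narrow for trough-only
    designs) or "age" (subject age at each observation).  Per bin the
    observed percentiles are compared with the ``band`` percentile range
    of the same statistic across ``n_sim`` fresh simulations.
    """
    obs = dataset.observations
    if binning == "time":
        x = obs["TIME_H"].to_numpy(float)
    elif binning == "age":
        age = dataset.subjects.set_index("ID")["AGE"]
        x = age.loc[obs["ID"]].to_numpy(float)
    else:
        raise ValueError(f"unknown binning {binning!r}; expected 'time' or 'age'")
    y = obs["DV"].to_numpy(float)
    edges = _bin_edges(x, n_bins)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)

    rng_seeds = np.random.SeedSequence(seed).generate_state(n_sim)
    sims = np.empty((n_sim, len(y)))
    for r in range(n_sim):
        sims[r] = simulate_from_model(
            dataset, model, int(rng_seeds[r]), include_residual=include_residual
        ).observations["DV"].to_numpy(float)

    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not np.any(sel):
            continue
        for p in percentiles:
            observed = float(np.percentile(y[sel], p))
            sim_stat = np.percentile(sims[:, sel], p, axis=1)
            lo, hi = np.percentile(sim_stat, band)
            rows.append(
                {
                    "bin_low": float(edges[b]),
                    "bin_high": float(edges[b + 1]),
                    "n_obs": int(sel.sum()),
                    "percentile": p,
                    "observed": observed,
                    "band_low": float(lo),
                    "band_high": float(hi),
                }
            )
    return VPCResult(table=pd.DataFrame(rows), binning=binning, n_sim=n_sim)


def gof_table(
    fit_result: FitResult, dataset: Dataset
) -> tuple[list[GOFRecord], dict[str, float]]:
    """Goodness-of-fit records plus regression summaries.

    Returns the per-observation records (DV, PRED, IPRED, CWRES) and a
    summary with DV~PRED and DV~IPRED least-squares slopes/intercepts
    and CWRES trend slopes against PRED and time (with the 95% CI
    half-width of the time trend).
    """
    records = cwres(fit_result.model, fit_result, dataset)
    dv = np.array([r.dv for r in records])
    pred = np.array([r.pred for r in records])
    ipred = np.array([r.ipred for r in records])
    cw = np.array([r.cwres for r in records])
    t = np.array([r.time_after_dose_h for r in records])
    summary: dict[str, float] = {}
    for name, x_, y_ in (("dv_pred", pred, dv), ("dv_ipred", ipred, dv)):
        res = stats.linregress(x_, y_)
        summary[f"{name}_slope"] = float(res.slope)
        summary[f"{name}_intercept"] = float(res.intercept)
    for name, x_ in (("cwres_pred", pred), ("cwres_time", t)):
        if np.ptp(x_) == 0:
            summary[f"{name}_slope"] = 0.0
            summary[f"{name}_slope_ci95"] = float("inf")
            continue
        res = stats.linregress(x_, cw)
        summary[f"{name}_slope"] = float(res.slope)
        summary[f"{name}_slope_ci95"] = float(1.96 * res.stderr)
    return records, summary


def gof_frame(records: list[GOFRecord]) -> pd.DataFrame:
    """GOF records as the canonical CSV layout."""
    return pd.DataFrame(
        {
            "ID": [r.subject_id for r in records],
            "TIME": [r.time_after_dose_h for r in records],
            "DV": [r.dv for r in records],
            "PRED": [r.pred for r in records],
            "IPRED": [r.ipred for r in records],
            "CWRES": [r.cwres for r in records],
        }
    )
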