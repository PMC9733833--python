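"""Dataset container, CSV/JSON round-tripping and validation.

The on-disk dataset is a NONMEM-style flat long-format CSV: one row per
trough observation, subject-level covariates repeated on each row.
Required columns: ID, AGE (y), WT (kg), SEX (0 = male, 1 = female),
DOSE_MG (per administration), II_H (dosing interval, h), TIME_H (time
after dose, h), DV (concentration, mg/L).  Genotype columns are named
by their rs identifier and hold genotype labels; co-medication columns
hold 0/1 flags.  Unknown columns are carried through as extra
covariates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structural import CovariateTerm, ModelSpec, Observation, Regimen, Subject

log = logging.getLogger("valpop")

REQUIRED_COLUMNS = ("ID", "AGE", "WT", "SEX", "DOSE_MG", "II_H", "TIME_H", "DV")

#: assay lower limit of quantification (mg/L)
LLOQ_MG_L = 1.0

#: subject-level columns; everything else on a row belongs to the observation
_SUBJECT_COLUMNS = ("AGE", "WT", "SEX")

_JSON_SIG_DIGITS = 12


@dataclass
class Dataset:
    """A study dataset split into a subject table and an observation table.

    ``subjects`` has one row per ID carrying covariates plus the
    subject's (first) regimen; ``observations`` has one row per trough
    with ID, DOSE_MG, II_H, TIME_H, DV.
    """

    subjects: pd.DataFrame
    observations: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def to_long(self) -> pd.DataFrame:
        """Flatten back to the long one-row-per-observation layout."""
        sub_cols = [c for c in self.subjects.columns if c not in ("DOSE_MG", "II_H")]
        long = self.observations.merge(self.subjects[sub_cols], on="ID", how="left")
        lead = [c for c in REQUIRED_COLUMNS if c in long.columns]
        rest = [c for c in long.columns if c not in lead]
        return long[lead + rest]

    @classmethod
    def from_long(cls, table: pd.DataFrame, validate: bool = True) -> "Dataset":
        if validate:
            _validate_long(table)
        obs_cols = ["ID", "DOSE_MG", "II_H", "TIME_H", "DV"]
        observations = table[obs_cols].reset_index(drop=True)
        sub_cols = ["ID"] + [c for c in table.columns if c not in obs_cols[1:] and c != "ID"]
        subjects = (
            table[sub_cols + ["DOSE_MG", "II_H"]]
            .groupby("ID", sort=False, as_index=False)
            .first()
        )
        return cls(subjects=subjects, observations=observations)

    def subject_list(self) -> list[Subject]:
        """Materialize rich Subject objects (genotypes, co-meds, regimen)."""
        from .datasets import COMEDICATION_RATES, SNP_PANEL

        out = []
        for _, row in self.subjects.iterrows():
            genos = {s: str(row[s]) for s in SNP_PANEL if s in row.index}
            comeds = {
                d for d in COMEDICATION_RATES if d in row.index and int(row[d]) == 1
            }
            out.append(
                Subject(
                    id=str(row["ID"]),
                    age_y=float(row["AGE"]),
                    weight_kg=float(row["WT"]),
                    sex="female" if int(row["SEX"]) == 1 else "male",
                    genotypes=genos,
                    comeds=comeds,
                    regimen=Regimen(float(row["DOSE_MG"]), float(row["II_H"])),
                )
            )
        return out


def _validate_long(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s): {missing}")
    for col in ("AGE", "WT", "DOSE_MG", "II_H", "TIME_H", "DV"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"non-numeric {col} in row(s) {bad[:10]}")
    for col, pred, what in (
        ("DOSE_MG", lambda v: v > 0, "positive"),
        ("II_H", lambda v: v > 0, "positive"),
        ("AGE", lambda v: v > 0, "positive"),
        ("WT", lambda v: v > 0, "positive"),
    ):
        vals = pd.to_numeric(table[col])
        bad = table.index[~pred(vals)].tolist()
        if bad:
            raise ValueError(f"{col} must be {what}; offending row(s) {bad[:10]}")
    _validate_genotypes(table)
    low = table.index[pd.to_numeric(table["DV"]) < LLOQ_MG_L].tolist()
    if low:
        msg = (
            f"{len(low)} observation(s) below the assay lower limit of "
            f"quantification (1 mg/L), row(s) {low[:10]}"
        )
        warnings.warn(msg)
        log.warning(msg)


def _validate_genotypes(table: pd.DataFrame) -> None:
    from .datasets import SNP_PANEL

    for snp, info in SNP_PANEL.items():
        if snp not in table.columns:
            continue
        allowed = set(info.genotype_labels)
        bad = table.index[~table[snp].astype(str).isin(allowed)].tolist()
        if bad:
            labels = sorted(set(table.loc[bad, snp].astype(str)))
            raise ValueError(
                f"unknown genotype label(s) {labels} for SNP {snp} in row(s) "
                f"{bad[:10]}; expected one of {sorted(allowed)}"
            )


def read_dataset(path) -> Dataset:
    """Read and validate a long-format CSV dataset."""
    table = pd.read_csv(path)
    return Dataset.from_long(table)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the long-format CSV (UTF-8, '.' decimal, empty = missing)."""
    dataset.to_long().to_csv(path, index=False)


def dataset_from_subjects(
    subjects: Sequence[Subject], observations: Sequence[Observation]
) -> Dataset:
    """Build a Dataset from in-memory Subject/Observation objects."""
    sub_rows = []
    for s in subjects:
        if s.regimen is None:
            raise ValueError(f"subject {s.id} has no regimen")
        row: dict[str, object] = {
            "ID": s.id,
            "AGE": s.age_y,
            "WT": s.weight_kg,
            "SEX": 1 if s.sex == "female" else 0,
            "DOSE_MG": s.regimen.dose_mg,
            "II_H": s.regimen.tau_h,
        }
        row.update(s.genotypes)
        for d in sorted(s.comeds):
            row[d] = 1
        sub_rows.append(row)
    subjects_df = pd.DataFrame(sub_rows)
    comed_cols = [
        c
        for c in subjects_df.columns
        if c not in ("ID", "AGE", "WT", "SEX", "DOSE_MG", "II_H")
        and subjects_df[c].dtype != object
    ]
    for c in comed_cols:
        subjects_df[c] = subjects_df[c].fillna(0).astype(int)
    reg = {s.id: s.regimen for s in subjects}
    obs_rows = [
        {
            "ID": o.subject_id,
            "DOSE_MG": reg[o.subject_id].dose_mg,
            "II_H": reg[o.subject_id].tau_h,
            "TIME_H": o.time_after_dose_h,
            "DV": o.conc_mg_L,
        }
        for o in observations
    ]
    return Dataset(subjects=subjects_df, observations=pd.DataFrame(obs_rows))


# ---------------------------------------------------------------------------
# fit-result JSON document
# ---------------------------------------------------------------------------


def _round_sig(x: float, sig: int = _JSON_SIG_DIGITS) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _spec_to_doc(model: ModelSpec) -> dict:
    return {
        "theta": {k: _round_sig(v) for k, v in model.theta.items()},
        "covariate_terms": [
            {
                "covariate": t.covariate,
                "form": t.form,
                "coefficients": list(t.coefficients),
                "target": t.target,
                "reference": t.reference,
                "levels": list(t.levels) if t.levels else None,
            }
            for t in model.covariate_terms
        ],
        "omega_cl": _round_sig(model.omega.omega_cl),
        "error": {
            "kind": model.error.kind,
            "sigma_add": model.error.sigma_add,
            "sigma_prop": model.error.sigma_prop,
        },
        "ka_fixed_h": model.ka_fixed_h,
        "age_reference_y": model.age_reference_y,
    }


def _spec_from_doc(doc: dict) -> ModelSpec:
    from .nlme import ErrorModel, OmegaSpec

    terms = [
        CovariateTerm(
            covariate=t["covariate"],
            form=t["form"],
            coefficients=tuple(t["coefficients"]),
            target=t.get("target", "CL"),
            reference=t.get("reference"),
            levels=tuple(t["levels"]) if t.get("levels") else None,
        )
        for t in doc["covariate_terms"]
    ]
    err = doc["error"]
    return ModelSpec(
        theta=dict(doc["theta"]),
        covariate_terms=terms,
        omega=OmegaSpec(doc["omega_cl"]),
        error=ErrorModel(
            kind=err["kind"], sigma_add=err["sigma_add"], sigma_prop=err["sigma_prop"]
        ),
        ka_fixed_h=doc["ka_fixed_h"],
        age_reference_y=doc["age_reference_y"],
    )


def write_fit_result(fit_result, path, seed: int | None = None) -> None:
    """Serialize a FitResult to the JSON document format (12 sig. digits)."""
    from . import __version__

    doc = {
        "model": _spec_to_doc(fit_result.model),
        "estimates": {k: _round_sig(v) for k, v in fit_result.estimates.items()},
        "rse_pct": {k: _round_sig(v) for k, v in fit_result.rse_pct.items()},
        "ofv": _round_sig(fit_result.ofv),
        "aic": _round_sig(fit_result.aic),
        "bic": _round_sig(fit_result.bic),
        "ebes": {k: _round_sig(v) for k, v in fit_result.ebes.items()},
        "eta_shrinkage_pct": _opt_round(fit_result.eta_shrinkage_pct),
        "eps_shrinkage_pct": _opt_round(fit_result.eps_shrinkage_pct),
        "converged": fit_result.converged,
        "n_subjects": fit_result.n_subjects,
        "n_obs": fit_result.n_obs,
        "n_parameters": fit_result.n_parameters,
        "fixed": sorted(fit_result.fixed),
        "hessian_pd": fit_result.hessian_pd,
        "message": fit_result.message,
        "seed": seed,
        "software_version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, allow_nan=True)
        fh.write("\n")


def _opt_round(x):
    return None if x is None else _round_sig(x)


def read_fit_result(path):
    """Load a fit-result JSON document back into a FitResult."""
    from .nlme import FitResult

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return FitResult(
        estimates=doc["estimates"],
        rse_pct=doc["rse_pct"],
        ofv=doc["ofv"],
        aic=doc["aic"],
        bic=doc["bic"],
        ebes=doc["ebes"],
        eta_shrinkage_pct=doc["eta_shrinkage_pct"],
        eps_shrinkage_pct=doc["eps_shrinkage_pct"],
        converged=doc["converged"],
        n_subjects=doc["n_subjects"],
        n_obs=doc["n_obs"],
        n_parameters=doc["n_parameters"],
        model=_spec_from_doc(doc["model"]),
        fixed=frozenset(doc["fixed"]),
        hessian_pd=doc["hessian_pd"],
        message=doc["message"],
    )
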