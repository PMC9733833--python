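"""Reference constants of the pediatric valproate cohort and fitted models.

These are the published summaries of the 103-child epilepsy cohort the
model was developed on: demographic targets, the genotyped SNP panel
with observed genotype counts, co-medication rates, and the base/final
population-PK parameter estimates.  The synthetic cohort generator and
the worked examples are parameterized from these values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hwe import GenotypeCounts
from .nlme import ErrorModel, OmegaSpec
from .structural import CovariateTerm, ModelSpec, ThetaVector

ABCB1_SNP = "rs3789243"


@dataclass(frozen=True)
class SNPInfo:
    """A panel SNP: gene, genotype labels (hom-ref, het, hom-alt), cohort counts."""

    gene: str
    genotype_labels: tuple[str, str, str]
    cohort_counts: tuple[int, int, int]

    @property
    def ref_allele_freq(self) -> float:
        aa, ab, _ = self.cohort_counts
        n = sum(self.cohort_counts)
        return (2 * aa + ab) / (2 * n)


#: the 15-SNP genotyping panel with genotype counts observed in the cohort
SNP_PANEL: dict[str, SNPInfo] = {
    "rs3789243": SNPInfo("ABCB1", ("AA", "AG", "GG"), (14, 50, 39)),
    "rs1128503": SNPInfo("ABCB1", ("AA", "AG", "GG"), (42, 51, 10)),
    "rs2273697": SNPInfo("ABCC2", ("GG", "GA", "AA"), (88, 14, 1)),
    "rs2606345": SNPInfo("CYP1A1", ("CC", "CA", "AA"), (96, 7, 0)),
    "rs1057910": SNPInfo("CYP2C9", ("AA", "AC", "CC"), (96, 6, 1)),
    "rs1137101": SNPInfo("LEPR", ("AA", "AG", "GG"), (2, 19, 82)),
    "rs1801133": SNPInfo("MTHFR", ("GG", "GA", "AA"), (51, 35, 17)),
    "rs1801131": SNPInfo("MTHFR", ("TT", "TG", "GG"), (67, 31, 5)),
    "rs6732655": SNPInfo("SCN1A", ("AA", "AT", "TT"), (4, 97, 2)),
    "rs6730344": SNPInfo("SCN1A", ("CC", "CA", "AA"), (74, 26, 3)),
    "rs10167228": SNPInfo("SCN1A", ("TT", "TA", "AA"), (1, 17, 85)),
    "rs3812718": SNPInfo("SCN1A", ("CC", "CT", "TT"), (17, 47, 39)),
    "rs2298771": SNPInfo("SCN1A", ("CC", "CT", "TT"), (1, 18, 84)),
    "rs2304016": SNPInfo("SCN2A", ("AA", "AG", "GG"), (82, 20, 1)),
    "rs17183814": SNPInfo("SCN2A", ("GG", "GA", "AA"), (73, 28, 2)),
}

#: published HWE p-values per SNP (chi-square, df=1), used as worked examples
COHORT_HWE_P: dict[str, float] = {
    "rs3789243": 0.748,
    "rs1128503": 0.329,
    "rs2273697": 0.603,
    "rs2606345": 0.721,
    "rs1057910": 0.026,
    "rs1137101": 0.477,
    "rs1801133": 0.016,
    "rs1801131": 0.57,
    "rs6732655": 0.0,
    "rs6730344": 0.699,
    "rs10167228": 0.884,
    "rs3812718": 0.657,
    "rs2298771": 0.974,
    "rs2304016": 0.857,
    "rs17183814": 0.715,
}


def cohort_genotype_counts() -> list[GenotypeCounts]:
    """The full panel as GenotypeCounts objects, ready for HWE screening."""
    return [
        GenotypeCounts(snp_id=snp, labels=info.genotype_labels, counts=info.cohort_counts)
        for snp, info in SNP_PANEL.items()
    ]


#: fraction of the cohort on each co-medication (ibuprofen falls below the
#: 2.5% screening threshold and is excluded from covariate testing)
COMEDICATION_RATES: dict[str, float] = {
    "LEV": 0.1383,  # levetiracetam
    "OXC": 0.1117,  # oxcarbazepine
    "TPM": 0.0426,  # topiramate
    "CNZ": 0.0372,  # clonazepam
    "PB": 0.0319,  # phenobarbital
    "MDZL": 0.0266,  # midazolam
    "IBU": 0.016,  # ibuprofen
}

#: cohort demographic targets: (mean, SD, low, high)
COHORT_DEMOGRAPHICS = {
    "n_subjects": 103,
    "n_obs": 376,
    "age_y": (5.30, 3.39, 0.5, 15.0),
    "weight_kg": (19.9, 10.6, 6.5, 52.0),
    "daily_dose_mg_kg": (23.8, 5.7, 9.9, 45.7),
    "conc_mg_L": (60.54, 19.32, 14.67, 110.99),
    "female_fraction": 47 / 103,
}

#: final-model fixed effects (typical CL/F and V/F; age power; ABCB1
#: rs3789243 genotype multipliers relative to AA)
FINAL_THETA = ThetaVector(
    theta_cl=0.214,
    theta_v=3.63,
    theta_age=0.357,
    theta_abcb1_ag=0.953,
    theta_abcb1_gg=1.08,
)

#: final-model random components: log-scale SD of eta on CL and additive
#: residual SD (mg/L)
FINAL_OMEGA_CL = 0.169
FINAL_SIGMA_ADD = 11.9

#: base (covariate-free) model estimates
BASE_THETA_CL = 0.205
BASE_THETA_V = 3.43
BASE_OMEGA_CL = 0.302
BASE_SIGMA_ADD = 13.7

KA_FIXED_H = 1.9
AGE_REFERENCE_Y = 5.0

#: pediatric median weight-for-age anchors (years -> kg), interpolated
#: linearly; a growth-reference-style stand-in for the national survey
#: table behind the original dosing simulations, which is not public
GROWTH_REFERENCE_AGE_Y = (0.5, 1, 1.5, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
GROWTH_REFERENCE_WEIGHT_KG = (
    7.8, 10.0, 11.6, 13.0, 15.2, 17.0, 19.0, 21.3, 23.8, 26.4, 29.2, 32.3,
    35.7, 39.3, 43.0, 46.8, 50.5,
)


def weight_for_age(age_y):
    """Median pediatric weight (kg) at a given age from the reference table."""
    import numpy as np

    return np.interp(
        np.asarray(age_y, dtype=float), GROWTH_REFERENCE_AGE_Y, GROWTH_REFERENCE_WEIGHT_KG
    )


def age_for_weight(weight_kg):
    """Inverse of the median weight-for-age curve (years)."""
    import numpy as np

    return np.interp(
        np.asarray(weight_kg, dtype=float), GROWTH_REFERENCE_WEIGHT_KG, GROWTH_REFERENCE_AGE_Y
    )


def final_model(age_reference_y: float = AGE_REFERENCE_Y) -> ModelSpec:
    """The final covariate model: power age effect and ABCB1 genotype
    multipliers on CL/F, one log-normal random effect on CL, additive
    residual error."""
    info = SNP_PANEL[ABCB1_SNP]
    return ModelSpec(
        theta={
            "theta_cl": FINAL_THETA.theta_cl,
            "theta_v": FINAL_THETA.theta_v,
            "beta_age": FINAL_THETA.theta_age,
            f"mult_{ABCB1_SNP}_AG": FINAL_THETA.theta_abcb1_ag,
            f"mult_{ABCB1_SNP}_GG": FINAL_THETA.theta_abcb1_gg,
        },
        covariate_terms=[
            CovariateTerm(
                covariate="AGE",
                form="power",
                coefficients=("beta_age",),
                reference=age_reference_y,
            ),
            CovariateTerm(
                covariate=ABCB1_SNP,
                form="multiplier",
                coefficients=(f"mult_{ABCB1_SNP}_AG", f"mult_{ABCB1_SNP}_GG"),
                levels=info.genotype_labels,
            ),
        ],
        omega=OmegaSpec(FINAL_OMEGA_CL),
        error=ErrorModel(kind="additive", sigma_add=FINAL_SIGMA_ADD),
        ka_fixed_h=KA_FIXED_H,
        age_reference_y=age_reference_y,
    )


def base_model() -> ModelSpec:
    """The covariate-free base model (starting point of stepwise selection)."""
    return ModelSpec(
        theta={"theta_cl": BASE_THETA_CL, "theta_v": BASE_THETA_V},
        covariate_terms=[],
        omega=OmegaSpec(BASE_OMEGA_CL),
        error=ErrorModel(kind="additive", sigma_add=BASE_SIGMA_ADD),
        ka_fixed_h=KA_FIXED_H,
        age_reference_y=AGE_REFERENCE_Y,
    )
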