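"""Hardy-Weinberg equilibrium screening of candidate pharmacogenetic SNPs.

Biallelic SNPs entering covariate testing must be in Hardy-Weinberg
equilibrium in the cohort: with allele frequencies p and q = 1 - p the
expected genotype proportions are p^2, 2pq, q^2, and deviation is
screened by the Pearson chi-square statistic on 1 degree of freedom
(genotype counts constrain 2 df, allele frequency estimation uses 1).
No continuity correction and no exact test are applied; a warning is
logged when any expected count falls below 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("valpop")


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one biallelic SNP.

    ``labels`` are ordered (hom-ref, het, hom-alt); counts align.
    """

    snp_id: str
    labels: tuple[str, str, str]
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.labels) != 3 or len(self.counts) != 3:
            raise ValueError("a biallelic SNP has exactly three genotype classes")
        if any(c < 0 for c in self.counts):
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class HWEResult:
    snp_id: str
    allele_freqs: tuple[float, float]
    expected_counts: tuple[float, float, float]
    chi2: float
    p_value: float
    in_hwe: bool
    monomorphic: bool = False


def hwe_chisq(counts: GenotypeCounts, alpha: float = 0.05) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1).

    Allele frequencies by gene counting; a monomorphic SNP fits HWE
    perfectly by construction (chi2 = 0, p = 1) and is flagged.
    """
    n = counts.total
    if n < 1:
        raise ValueError(f"{counts.snp_id}: total genotype count must be >= 1")
    aa, ab, bb = counts.counts
    p = (2 * aa + ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HWEResult(
            snp_id=counts.snp_id,
            allele_freqs=(p, q),
            expected_counts=(n * p * p, 2 * n * p * q, n * q * q),
            chi2=0.0,
            p_value=1.0,
            in_hwe=True,
            monomorphic=True,
        )
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if min(expected) < 5:
        log.warning(
            "%s: expected genotype count below 5 (%.2f); chi-square approximation "
            "may be poor",
            counts.snp_id,
            min(expected),
        )
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts.counts, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(
        snp_id=counts.snp_id,
        allele_freqs=(p, q),
        expected_counts=expected,
        chi2=float(chi2),
        p_value=p_value,
        in_hwe=p_value > alpha,
    )


def genotype_freqs(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Genotype frequencies in percent (exact values, not re-rounded)."""
    n = counts.total
    if n < 1:
        raise ValueError(f"{counts.snp_id}: total genotype count must be >= 1")
    return tuple(100.0 * c / n for c in counts.counts)


def hwe_screen(
    all_counts: Iterable[GenotypeCounts], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition SNPs into (retained, excluded) by the HWE test at ``alpha``.

    SNPs deviating from Hardy-Weinberg proportions (p <= alpha) are
    excluded from covariate model development.
    """
    retained, excluded = [], []
    for c in all_counts:
        res = hwe_chisq(c, alpha=alpha)
        (retained if res.p_value > alpha else excluded).append(c.snp_id)
    return retained, excluded


def counts_from_subjects(
    subjects: pd.DataFrame, snp_panel: Mapping[str, object] | None = None
) -> list[GenotypeCounts]:
    """Tally genotype counts for every panel SNP present in a subject table."""
    if snp_panel is None:
        from .datasets import SNP_PANEL as snp_panel  # noqa: N811
    out = []
    for snp, info in snp_panel.items():
        if snp not in subjects.columns:
            continue
        vals = subjects[snp].astype(str)
        out.append(
            GenotypeCounts(
                snp_id=snp,
                labels=info.genotype_labels,
                counts=tuple(int((vals == g).sum()) for g in info.genotype_labels),
            )
        )
    return out


def hwe_table(all_counts: Sequence[GenotypeCounts], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-SNP summary: counts, frequencies (%), chi2 and HWE p-value."""
    rows = []
    for c in all_counts:
        res = hwe_chisq(c, alpha=alpha)
        freqs = genotype_freqs(c)
        rows.append(
            {
                "snp_id": c.snp_id,
                "genotypes": "/".join(c.labels),
                "counts": "/".join(str(k) for k in c.counts),
                "freq_pct": "/".join(f"{f:.1f}" for f in freqs),
                "chi2": res.chi2,
                "p_value": res.p_value,
                "in_hwe": res.in_hwe,
                "monomorphic": res.monomorphic,
            }
        )
    return pd.DataFrame(rows)
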