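"""Combined risk-genotype scoring and its association with outcome.

Each marker declares a (possibly empty) set of risk genotypes; a
subject's score is the unweighted count of markers at which they carry a
risk genotype.  Scores are top-coded (the highest category means "this
many or more") and each category is contrasted against the zero-risk
reference with a Wald odds ratio, plus a Cochran-Armitage trend test
across categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assoc import (
    AssocResult,
    TrendResult,
    Z975,
    logistic_fit,
    odds_ratio_wald,
    trend_test,
)
from .cohort import Cohort, SnpDef, ValidationError

__all__ = ["RiskScoreResult", "count_risk_genotypes", "combined_risk_association"]


@dataclass(frozen=True)
class RiskScoreResult:
    labels: tuple  # e.g. ("0", "1", "2+")
    counts_case: tuple
    counts_control: tuple
    results: tuple  # AssocResult per non-reference category (crude)
    adjusted_results: tuple  # empty unless covariates were requested
    trend: TrendResult
    n_excluded: int  # subjects missing any scored genotype


def count_risk_genotypes(subject, snps: Sequence[SnpDef]) -> Optional[int]:
    """Number of markers at which a subject carries a risk genotype.

    Returns ``None`` when any scored marker is ungenotyped: the subject
    cannot be placed in a category and is excluded upstream.
    """
    score = 0
    for snp in snps:
        call = subject.genotypes.get(snp.snp_id)
        if call is None:
            return None
        if call in snp.risk_genotypes:
            score += 1
    return score


def combined_risk_association(
    cohort: Cohort,
    snps: Optional[Sequence[SnpDef]] = None,
    top_code: int = 2,
    covariates: Optional[Sequence[str]] = None,
) -> RiskScoreResult:
    """Associate the top-coded risk-genotype count with case status.

    ``top_code=2`` collapses scores of two or more into one category, the
    reading under which the published three categories exhaust the whole
    cohort.  Complete-case: subjects missing any scored genotype are
    excluded and tallied.
    """
    if top_code < 1:
        raise ValueError("top_code must be >= 1")
    if snps is None:
        snps = cohort.snps
    n_cat = top_code + 1
    counts = {"case": [0] * n_cat, "control": [0] * n_cat}
    scored = []  # (category, is_case, subject) for adjusted fits
    n_excluded = 0
    for subj in cohort.subjects:
        score = count_risk_genotypes(subj, snps)
        if score is None:
            n_excluded += 1
            continue
        category = min(score, top_code)
        counts[subj.status][category] += 1
        scored.append((category, subj))
    labels = tuple(
        str(k) if k < top_code else f"{top_code}+" for k in range(n_cat)
    )
    if counts["case"][0] + counts["control"][0] == 0:
        raise ValidationError("empty zero-risk reference category")
    crude = []
    for k in range(1, n_cat):
        crude.append(
            odds_ratio_wald(
                counts["case"][k],
                counts["case"][0],
                counts["control"][k],
                counts["control"][0],
                snp_id="combined_risk",
                contrast=f"{labels[k]}_vs_0",
            )
        )
    z, p, defined = trend_test(
        counts["case"], counts["control"], scores=list(range(n_cat))
    )
    trend = TrendResult("combined_risk", tuple(range(n_cat)), z, p, defined)

    adjusted: list = []
    if covariates:
        rows = [
            (cat, subj)
            for cat, subj in scored
            if all(getattr(subj, c) is not None for c in covariates)
        ]
        for k in range(1, n_cat):
            used = [(cat, subj) for cat, subj in rows if cat in (0, k)]
            y = np.array([1.0 if subj.status == "case" else 0.0 for _, subj in used])
            x = np.array([1.0 if cat == k else 0.0 for cat, _ in used])
            covs = np.array(
                [[float(getattr(subj, c)) for c in covariates] for _, subj in used]
            )
            X = np.column_stack([np.ones(len(used)), x, covs])
            fit = logistic_fit(X, y, names=["intercept", "category", *covariates])
            if not fit.converged:
                adjusted.append(
                    AssocResult("combined_risk", f"{labels[k]}_vs_0", None, None,
                                None, None, adjusted=True, n_used=len(used),
                                defined=False)
                )
                continue
            log_or, se = fit.estimates[1], fit.standard_errors[1]
            adjusted.append(
                AssocResult(
                    snp_id="combined_risk",
                    contrast=f"{labels[k]}_vs_0",
                    or_point=math.exp(log_or),
                    ci_low=math.exp(log_or - Z975 * se),
                    ci_high=math.exp(log_or + Z975 * se),
                    p_value=fit.wald_p[1],
                    adjusted=True,
                    n_used=len(used),
                    defined=True,
                    log_or=log_or,
                    se=se,
                )
            )
    return RiskScoreResult(
        labels=labels,
        counts_case=tuple(counts["case"]),
        counts_control=tuple(counts["control"]),
        results=tuple(crude),
        adjusted_results=tuple(adjusted),
        trend=trend,
        n_excluded=n_excluded,
    )
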