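"""Subgroup (stratified) analysis and cohort descriptives.

Strata are defined on age, gravidity, parity or rASRM stage.  Because
controls are unstaged, rASRM strata restrict the cases only and compare
them against the full control group; covariate strata restrict both
groups.  Within each stratum a SNP is collapsed to a 2x2 via a declared
genotype contrast (e.g. AG/GG vs AA) and summarised with a crude Wald
odds ratio, optionally alongside a covariate-adjusted logistic estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult, Z975, logistic_fit, odds_ratio_wald
from .cohort import Cohort, ValidationError

__all__ = [
    "StratumSpec",
    "GenotypeContrast",
    "default_strata",
    "stratified_analysis",
    "render_descriptives",
    "ttest_from_summary",
]


@dataclass(frozen=True)
class GenotypeContrast:
    """Collapse a SNP's genotypes into exposed vs reference classes."""

    snp_id: str
    exposed: tuple  # genotype labels, e.g. ("AG", "GG")
    reference: tuple

    def label(self) -> str:
        return f"{'/'.join(self.exposed)} vs {'/'.join(self.reference)}"


@dataclass(frozen=True)
class StratumSpec:
    """An ordered binning of one stratification variable.

    For numeric variables each bin is ``(label, low, high)`` denoting the
    half-open interval low < value <= high (``None`` = unbounded), so
    consecutive bins partition a continuous variable; for ``rasrm_stage``
    each bin is ``(label, (stages...))`` and applies to cases only.
    """

    variable: str  # age | gravidity | parity | rasrm_stage
    bins: tuple

    def assign(self, subject) -> Optional[str]:
        if self.variable == "rasrm_stage":
            stage = subject.rasrm_stage
            if stage is None:
                return None
            for label, stages in self.bins:
                if stage in stages:
                    return label
            return None
        value = getattr(subject, self.variable)
        if value is None:
            return None
        for label, low, high in self.bins:
            if (low is None or value > low) and (high is None or value <= high):
                return label
        return None


def default_strata() -> list:
    """The published subgroup definitions."""
    return [
        StratumSpec("age", (("<=30", None, 30), ("31-40", 30, 40), (">40", 40, None))),
        StratumSpec("gravidity", (("<=1", None, 1), (">1", 1, None))),
        StratumSpec("parity", (("<=1", None, 1), (">1", 1, None))),
        StratumSpec("rasrm_stage", (("I", ("I",)), ("II+III+IV", ("II", "III", "IV")))),
    ]


def _classify(subject, contrast: GenotypeContrast) -> Optional[bool]:
    """True = exposed, False = reference, None = missing/other class."""
    call = subject.genotypes.get(contrast.snp_id)
    if call is None:
        return None
    if call in contrast.exposed:
        return True
    if call in contrast.reference:
        return False
    return None


def stratified_analysis(
    cohort: Cohort,
    contrasts: Sequence[GenotypeContrast],
    strata: Optional[Sequence[StratumSpec]] = None,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-stratum 2x2 odds ratios for each SNP contrast.

    Returns a tidy frame with the collapsed counts, the crude Wald OR/CI/p
    (flagged undefined on a zero cell, like published "NA" rows) and,
    when ``covariates`` are given, the adjusted logistic OR.  Strata with
    no cases or no controls are flagged, not fatal.
    """
    if strata is None:
        strata = default_strata()
    rows = []
    for spec in strata:
        labels = [b[0] for b in spec.bins]
        for label in labels:
            if spec.variable == "rasrm_stage":
                case_pool = [
                    s for s in cohort.group("case") if spec.assign(s) == label
                ]
                control_pool = cohort.group("control")
            else:
                case_pool = [
                    s for s in cohort.group("case") if spec.assign(s) == label
                ]
                control_pool = [
                    s for s in cohort.group("control") if spec.assign(s) == label
                ]
            for contrast in contrasts:
                a = sum(1 for s in case_pool if _classify(s, contrast) is True)
                b = sum(1 for s in case_pool if _classify(s, contrast) is False)
                c = sum(1 for s in control_pool if _classify(s, contrast) is True)
                d = sum(1 for s in control_pool if _classify(s, contrast) is False)
                crude = odds_ratio_wald(
                    a, b, c, d, snp_id=contrast.snp_id, contrast=contrast.label()
                )
                record = {
                    "variable": spec.variable,
                    "stratum": label,
                    "snp_id": contrast.snp_id,
                    "contrast": contrast.label(),
                    "exposed_cases": a,
                    "ref_cases": b,
                    "exposed_controls": c,
                    "ref_controls": d,
                    "or_crude": crude.or_point,
                    "ci_low_crude": crude.ci_low,
                    "ci_high_crude": crude.ci_high,
                    "p_crude": crude.p_value,
                    "defined": crude.defined,
                }
                if covariates:
                    adj = _adjusted_stratum_or(
                        case_pool, control_pool, contrast, covariates
                    )
                    record.update(
                        {
                            "or_adjusted": adj.or_point,
                            "ci_low_adjusted": adj.ci_low,
                            "ci_high_adjusted": adj.ci_high,
                            "p_adjusted": adj.p_value,
                        }
                    )
                rows.append(record)
    return pd.DataFrame(rows)


def _adjusted_stratum_or(
    case_pool, control_pool, contrast: GenotypeContrast, covariates
) -> AssocResult:
    data = []
    for status_value, pool in ((1.0, case_pool), (0.0, control_pool)):
        for subj in pool:
            cls = _classify(subj, contrast)
            if cls is None:
                continue
            covs = [getattr(subj, c) for c in covariates]
            if any(v is None for v in covs):
                continue
            data.append((status_value, 1.0 if cls else 0.0, [float(v) for v in covs]))
    undefined = AssocResult(
        contrast.snp_id, contrast.label(), None, None, None, None,
        adjusted=True, n_used=len(data), defined=False,
    )
    if not data:
        return undefined
    y = np.array([row[0] for row in data])
    if y.min() == y.max():
        return undefined
    x = np.array([row[1] for row in data])
    if x.min() == x.max():
        return undefined
    covs = np.array([row[2] for row in data])
    X = np.column_stack([np.ones(len(data)), x, covs])
    try:
        fit = logistic_fit(X, y, names=["intercept", "exposed", *covariates])
    except ValueError:
        return undefined
    if not fit.converged:
        return undefined
    log_or, se = fit.estimates[1], fit.standard_errors[1]
    return AssocResult(
        snp_id=contrast.snp_id,
        contrast=contrast.label(),
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=fit.wald_p[1],
        adjusted=True,
        n_used=len(data),
        defined=True,
        log_or=log_or,
        se=se,
    )


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided equal-variance t-test p from group summaries."""
    result = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(result.pvalue)


def render_descriptives(cohort: Cohort) -> pd.DataFrame:
    """Case/control summary of covariates with the conventional tests.

    Age: mean +/- SD per group with an equal-variance two-sample t-test,
    plus the <35 / >=35 binning with a chi-square.  Gravidity and parity:
    <=1 / >1 chi-square.  rASRM stage: case-only distribution.  Variables
    absent from the cohort are omitted.
    """
    cases = cohort.group("case")
    controls = cohort.group("control")
    rows = []

    case_ages = [s.age for s in cases if s.age is not None]
    control_ages = [s.age for s in controls if s.age is not None]
    if case_ages and control_ages:
        t_p = float(stats.ttest_ind(case_ages, control_ages, equal_var=True).pvalue)
        rows.append(
            {
                "variable": "age",
                "level": "mean±sd",
                "cases": f"{np.mean(case_ages):.2f}±{np.std(case_ages, ddof=1):.2f}",
                "controls": f"{np.mean(control_ages):.2f}±{np.std(control_ages, ddof=1):.2f}",
                "p": t_p,
                "test": "t",
            }
        )
        bins = [sum(1 for a in case_ages if a < 35), sum(1 for a in case_ages if a >= 35),
                sum(1 for a in control_ages if a < 35), sum(1 for a in control_ages if a >= 35)]
        if min(bins[0] + bins[1], bins[2] + bins[3]) > 0:
            table = np.array([[bins[0], bins[1]], [bins[2], bins[3]]], dtype=float)
            if (table.sum(axis=0) > 0).all():
                chi_p = float(stats.chi2_contingency(table, correction=False)[1])
                rows.append({"variable": "age", "level": "<35 / >=35",
                             "cases": f"{bins[0]} / {bins[1]}",
                             "controls": f"{bins[2]} / {bins[3]}",
                             "p": chi_p, "test": "chi2"})

    for variable in ("gravidity", "parity"):
        case_vals = [getattr(s, variable) for s in cases if getattr(s, variable) is not None]
        control_vals = [getattr(s, variable) for s in controls if getattr(s, variable) is not None]
        if not case_vals or not control_vals:
            continue
        table = np.array(
            [
                [sum(1 for v in case_vals if v <= 1), sum(1 for v in case_vals if v > 1)],
                [sum(1 for v in control_vals if v <= 1), sum(1 for v in control_vals if v > 1)],
            ],
            dtype=float,
        )
        p_val = (
            float(stats.chi2_contingency(table, correction=False)[1])
            if (table.sum(axis=0) > 0).all()
            else None
        )
        rows.append(
            {
                "variable": variable,
                "level": "<=1 / >1",
                "cases": f"{int(table[0, 0])} / {int(table[0, 1])}",
                "controls": f"{int(table[1, 0])} / {int(table[1, 1])}",
                "p": p_val,
                "test": "chi2",
            }
        )

    staged = [s for s in cases if s.rasrm_stage is not None]
    if staged:
        for stage in ("I", "II", "III", "IV"):
            count = sum(1 for s in staged if s.rasrm_stage == stage)
            rows.append(
                {
                    "variable": "rasrm_stage",
                    "level": stage,
                    "cases": f"{count} ({100.0 * count / len(staged):.2f}%)",
                    "controls": "",
                    "p": None,
                    "test": "",
                }
            )
    return pd.DataFrame(rows)
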