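"""Per-SNP association statistics for case-control genotype tables.

Implements the classic single-locus battery: Hardy-Weinberg goodness of
fit, the 2-df Pearson test on the 2x3 genotype distribution, the
Cochran-Armitage trend test, Woolf/Wald odds ratios for the codominant,
dominant and recessive contrasts, a per-allele (dosage) logistic estimate
for the additive model, and covariate-adjusted logistic contrasts.

Conventions
-----------
* Confidence intervals use the normal quantile z = 1.959964.
* The additive model reports the genotype-dosage (0/1/2) logistic odds
  ratio, paired with the Cochran-Armitage trend p-value; the allele-count
  odds ratio is exposed separately under the ``allelic`` contrast.
* A contrast with a structural zero cell is returned with
  ``defined=False`` rather than raising, mirroring the "-" cells of
  published association tables.  A continuity flag adds 0.5 to all cells
  instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, GenotypeCountTable, ValidationError

__all__ = [
    "Z975",
    "HweResult",
    "Chi2Result",
    "TrendResult",
    "AssocResult",
    "LogisticFit",
    "SingularDesignError",
    "hwe_chi2",
    "hwe_exact",
    "genotype_dist_chi2",
    "trend_test",
    "armitage_trend",
    "odds_ratio_wald",
    "model_contrasts",
    "logistic_fit",
    "adjusted_contrasts",
]

#: Two-sided 95% normal quantile used throughout for Wald intervals.
Z975 = 1.959964


class SingularDesignError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class HweResult:
    statistic: Optional[float]
    p_value: Optional[float]
    defined: bool = True


@dataclass(frozen=True)
class Chi2Result:
    statistic: Optional[float]
    df: int
    p_value: Optional[float]
    defined: bool = True


@dataclass(frozen=True)
class TrendResult:
    snp_id: str
    scores: tuple
    z_statistic: Optional[float]
    p_value: Optional[float]
    defined: bool = True


@dataclass(frozen=True)
class AssocResult:
    """One contrast's odds ratio with Wald CI and p-value."""

    snp_id: str
    contrast: str
    or_point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    adjusted: bool = False
    n_used: int = 0
    defined: bool = True
    log_or: Optional[float] = None
    se: Optional[float] = None
    counts: Optional[tuple] = None  # (a, b, c, d) when 2x2-based


@dataclass(frozen=True)
class LogisticFit:
    names: tuple
    estimates: tuple
    standard_errors: tuple
    wald_p: tuple
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_used: int


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def hwe_chi2(counts_one_group: Sequence[int]) -> HweResult:
    """1-df Pearson goodness-of-fit test against p^2 : 2pq : q^2.

    ``counts_one_group`` is a (major-hom, het, minor-hom) triple from a
    single group (conventionally controls).  A monomorphic marker has no
    defined test and is flagged rather than raised.
    """
    hom_major, het, hom_minor = counts_one_group
    n = hom_major + het + hom_minor
    if n <= 0:
        raise ValidationError("empty genotype triple")
    p = (2 * hom_major + het) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(expected == 0.0):
        return HweResult(None, None, defined=False)
    observed = np.array([hom_major, het, hom_minor], dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(statistic, float(stats.chi2.sf(statistic, 1)), defined=True)


def hwe_exact(counts_one_group: Sequence[int]) -> HweResult:
    """Exact Hardy-Weinberg test (Wigginton-style mid-less enumeration).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts.  Preferable to the
    chi-square approximation for small groups.
    """
    hom_major, het, hom_minor = (int(c) for c in counts_one_group)
    n = hom_major + het + hom_minor
    if n <= 0:
        raise ValidationError("empty genotype triple")
    n_minor = 2 * hom_minor + het
    n_major = 2 * hom_major + het
    rare = min(n_minor, n_major)
    if rare == 0:
        return HweResult(None, None, defined=False)
    # conditional distribution of the het count given the allele counts
    het_values = list(range(rare % 2, rare + 1, 2))
    logfact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, 2 * n + 1)))))

    def log_prob(het_count: int) -> float:
        hom_rare = (rare - het_count) // 2
        hom_common = n - het_count - hom_rare
        return (
            logfact[n]
            - logfact[het_count]
            - logfact[hom_rare]
            - logfact[hom_common]
            + het_count * math.log(2.0)
            + logfact[rare]
            + logfact[2 * n - rare]
            - logfact[2 * n]
        )

    logs = np.array([log_prob(h) for h in het_values])
    weights = np.exp(logs - logs.max())
    weights /= weights.sum()
    observed_het = het
    p_obs = weights[het_values.index(observed_het)]
    p_value = float(weights[weights <= p_obs + 1e-12].sum())
    return HweResult(None, min(1.0, p_value), defined=True)


# ---------------------------------------------------------------------------
# 2x3 tests
# ---------------------------------------------------------------------------


def genotype_dist_chi2(table: GenotypeCountTable) -> Chi2Result:
    """Pearson chi-square on the 2x3 genotype table (2 df).

    Genotype columns with a zero total are dropped and the degrees of
    freedom reduced accordingly; with fewer than two non-empty columns the
    test is undefined and flagged.
    """
    matrix = table.matrix
    if matrix.sum(axis=1).min() <= 0:
        raise ValidationError(f"{table.snp_id}: a group has no genotyped subjects")
    keep = matrix.sum(axis=0) > 0
    matrix = matrix[:, keep]
    if matrix.shape[1] < 2:
        return Chi2Result(None, 0, None, defined=False)
    statistic, p_value, df, _ = stats.chi2_contingency(matrix, correction=False)
    return Chi2Result(float(statistic), int(df), float(p_value), defined=True)


def trend_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    scores: Sequence[float],
) -> tuple:
    """Cochran-Armitage score test over ordered exposure categories.

    Returns ``(z, p, defined)``.  ``z`` is signed: positive when cases are
    shifted toward higher scores.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    t = np.asarray(scores, dtype=float)
    if not (len(r) == len(s) == len(t)):
        raise ValueError("counts and scores must have equal length")
    n = r + s
    big_r, big_s = r.sum(), s.sum()
    big_n = n.sum()
    if big_r <= 0 or big_s <= 0:
        raise ValidationError("both groups must be non-empty")
    t_stat = float(np.sum(t * r) - big_r / big_n * np.sum(t * n))
    variance = (
        big_r
        * big_s
        * (big_n * np.sum(t * t * n) - np.sum(t * n) ** 2)
        / (big_n**2 * (big_n - 1.0))
    )
    if variance <= 0.0:
        return None, None, False
    z = t_stat / math.sqrt(variance)
    return float(z), float(2.0 * stats.norm.sf(abs(z))), True


def armitage_trend(
    table: GenotypeCountTable, scores: Sequence[float] = (0, 1, 2)
) -> TrendResult:
    """Cochran-Armitage trend test on a 2x3 genotype table."""
    z, p, defined = trend_test(table.counts_case, table.counts_control, scores)
    return TrendResult(table.snp_id, tuple(scores), z, p, defined)


# ---------------------------------------------------------------------------
# 2x2 odds ratios
# ---------------------------------------------------------------------------


def odds_ratio_wald(
    a: float,
    b: float,
    c: float,
    d: float,
    *,
    continuity: bool = False,
    snp_id: str = "",
    contrast: str = "",
    adjusted: bool = False,
) -> AssocResult:
    """Woolf odds ratio with Wald CI and normal p from a 2x2 table.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  Accepts real-valued counts (e.g. expected haplotype counts).
    A zero cell yields an undefined (flagged) result unless ``continuity``
    adds 0.5 to every cell.
    """
    cells = [float(a), float(b), float(c), float(d)]
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    n_used = int(round(sum(cells)))
    if any(x == 0.0 for x in cells):
        if not continuity:
            return AssocResult(
                snp_id=snp_id,
                contrast=contrast,
                or_point=None,
                ci_low=None,
                ci_high=None,
                p_value=None,
                adjusted=adjusted,
                n_used=n_used,
                defined=False,
                counts=(a, b, c, d),
            )
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    z = log_or / se

    def _exp(x: float) -> float:  # fractional cells can push CI bounds past
        return math.exp(x) if x < 700.0 else math.inf  # float range

    return AssocResult(
        snp_id=snp_id,
        contrast=contrast,
        or_point=_exp(log_or),
        ci_low=_exp(log_or - Z975 * se),
        ci_high=_exp(log_or + Z975 * se),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        adjusted=adjusted,
        n_used=n_used,
        defined=True,
        log_or=log_or,
        se=se,
        counts=(a, b, c, d),
    )


def _dosage_logistic(table: GenotypeCountTable) -> tuple:
    """Genotype-dosage (0/1/2) logistic fit on the aggregated 2x3 table.

    Returns ``(log_or, se)`` for the per-allele slope, fitted by binomial
    GLM on the three genotype rows.
    """
    r = np.asarray(table.counts_case, dtype=float)
    s = np.asarray(table.counts_control, dtype=float)
    keep = (r + s) > 0
    dosage = np.arange(3, dtype=float)[keep]
    endog = np.column_stack([r[keep], s[keep]])
    exog = sm.add_constant(dosage)
    result = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    return float(result.params[1]), float(result.bse[1])


def model_contrasts(table: GenotypeCountTable) -> list:
    """All genetic-model contrasts for one marker's 2x3 count table.

    Emits het-vs-major-hom, minor-hom-vs-major-hom, dominant, recessive
    (all as Woolf/Wald 2x2 odds ratios), the additive genotype-dosage
    logistic odds ratio paired with the Cochran-Armitage p, and the
    allele-count odds ratio under the ``allelic`` label.
    """
    r = table.counts_case
    s = table.counts_control
    results = [
        odds_ratio_wald(
            r[1], r[0], s[1], s[0], snp_id=table.snp_id, contrast="het_vs_major_hom"
        ),
        odds_ratio_wald(
            r[2], r[0], s[2], s[0], snp_id=table.snp_id, contrast="minor_hom_vs_major_hom"
        ),
        odds_ratio_wald(
            r[1] + r[2], r[0], s[1] + s[2], s[0], snp_id=table.snp_id, contrast="dominant"
        ),
        odds_ratio_wald(
            r[2], r[0] + r[1], s[2], s[0] + s[1], snp_id=table.snp_id, contrast="recessive"
        ),
    ]
    trend = armitage_trend(table)
    try:
        log_or, se = _dosage_logistic(table)
        results.append(
            AssocResult(
                snp_id=table.snp_id,
                contrast="additive",
                or_point=math.exp(log_or),
                ci_low=math.exp(log_or - Z975 * se),
                ci_high=math.exp(log_or + Z975 * se),
                p_value=trend.p_value,
                n_used=int(sum(r) + sum(s)),
                defined=trend.defined,
                log_or=log_or,
                se=se,
            )
        )
    except Exception:
        results.append(
            AssocResult(table.snp_id, "additive", None, None, None, None, defined=False)
        )
    maj_case, min_case = table.allele_counts("case")
    maj_ctrl, min_ctrl = table.allele_counts("control")
    results.append(
        odds_ratio_wald(
            min_case, maj_case, min_ctrl, maj_ctrl, snp_id=table.snp_id, contrast="allelic"
        )
    )
    return results


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def logistic_fit(
    design: np.ndarray,
    outcome: Sequence[int],
    names: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    Wald standard errors come from the inverse observed information.
    Perfect separation is flagged as non-convergence; a rank-deficient
    design raises :class:`SingularDesignError` naming candidate columns.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome shapes do not match")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValidationError("outcome must contain both classes")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [
            names[i]
            for i in range(X.shape[1])
            if i >= len(diag) or diag[i] < 1e-8 * max(diag.max(), 1.0)
        ]
        raise SingularDesignError(f"collinear design columns: {bad or names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0, warn_convergence=False
            )
        except Exception:
            # rank deficiency is pre-checked, so optimizer failures (incl.
            # a singular Hessian under perfect separation) mean no MLE
            return LogisticFit(
                names=tuple(names),
                estimates=(math.nan,) * X.shape[1],
                standard_errors=(math.nan,) * X.shape[1],
                wald_p=(math.nan,) * X.shape[1],
                converged=False,
                n_iterations=100,
                log_likelihood=math.nan,
                n_used=len(y),
            )
    converged = bool(result.mle_retvals.get("converged", False))
    if converged and np.abs(result.params).max() > 50.0:
        converged = False  # drifting estimates: separation in disguise
    return LogisticFit(
        names=tuple(names),
        estimates=tuple(float(v) for v in result.params),
        standard_errors=tuple(float(v) for v in result.bse),
        wald_p=tuple(float(v) for v in result.pvalues),
        converged=converged,
        n_iterations=int(result.mle_retvals.get("iterations", 0)),
        log_likelihood=float(result.llf),
        n_used=len(y),
    )


def _covariate_vector(subject, name: str) -> Optional[float]:
    value = getattr(subject, name)
    return None if value is None else float(value)


_CONTRAST_CODING = {
    # contrast -> (classes used, coding of each used class)
    "het_vs_major_hom": ((0, 1), {0: 0.0, 1: 1.0}),
    "minor_hom_vs_major_hom": ((0, 2), {0: 0.0, 2: 1.0}),
    "dominant": ((0, 1, 2), {0: 0.0, 1: 1.0, 2: 1.0}),
    "recessive": ((0, 1, 2), {0: 0.0, 1: 0.0, 2: 1.0}),
    "additive": ((0, 1, 2), {0: 0.0, 1: 1.0, 2: 2.0}),
}


def adjusted_contrasts(
    cohort: Cohort,
    snp_id: str,
    covariates: Sequence[str] = ("age", "gravidity", "parity"),
) -> list:
    """Covariate-adjusted logistic odds ratios for all genetic models.

    Complete-case per contrast: subjects missing the genotype or any
    requested covariate are dropped, so ``n_used`` reflects the analysable
    set.  The footnoted adjustment set is a parameter because published
    tables disagree on its exact composition.
    """
    snp = cohort.snp(snp_id)
    rows = []
    for subj in cohort.subjects:
        call = subj.genotypes.get(snp_id)
        if call is None:
            continue
        covs = [_covariate_vector(subj, c) for c in covariates]
        if any(v is None for v in covs):
            continue
        rows.append((snp.genotype_class(call), 1.0 if subj.status == "case" else 0.0, covs))
    if not rows:
        raise ValidationError(f"{snp_id}: empty complete-case set")
    results = []
    for contrast, (classes, coding) in _CONTRAST_CODING.items():
        used = [row for row in rows if row[0] in classes]
        y = np.array([row[1] for row in used])
        geno = np.array([coding[row[0]] for row in used])
        covs = np.array([row[2] for row in used], dtype=float)
        X = np.column_stack([np.ones(len(used)), geno, covs])
        try:
            fit = logistic_fit(X, y, names=["intercept", "genotype", *covariates])
        except (SingularDesignError, ValidationError):
            results.append(
                AssocResult(snp_id, contrast, None, None, None, None, adjusted=True,
                            n_used=len(used), defined=False)
            )
            continue
        if not fit.converged:
            results.append(
                AssocResult(snp_id, contrast, None, None, None, None, adjusted=True,
                            n_used=len(used), defined=False)
            )
            continue
        log_or, se = fit.estimates[1], fit.standard_errors[1]
        results.append(
            AssocResult(
                snp_id=snp_id,
                contrast=contrast,
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
    return results
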