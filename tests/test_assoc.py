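"""Single-locus statistics against published values and exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from endoassoc.assoc import (
    SingularDesignError,
    adjusted_contrasts,
    armitage_trend,
    genotype_dist_chi2,
    hwe_chi2,
    hwe_exact,
    logistic_fit,
    model_contrasts,
    odds_ratio_wald,
)
from endoassoc.cohort import GenotypeCountTable, ValidationError
from endoassoc.simulate import EffectSpec, default_config, simulate_cohort


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected_p",
    [
        ((181, 216, 62), 0.847),
        ((132, 233, 94), 0.633),
        ((316, 130, 13), 0.932),
    ],
)
def test_hwe_published_controls(counts, expected_p):
    result = hwe_chi2(counts)
    assert result.p_value == pytest.approx(expected_p, abs=0.001)


def test_hwe_exact_proportions():
    result = hwe_chi2((25, 50, 25))
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_hwe_monomorphic_flagged():
    assert not hwe_chi2((100, 0, 0)).defined


def test_hwe_allele_relabel_invariance():
    a = hwe_chi2((181, 216, 62))
    b = hwe_chi2((62, 216, 181))
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


@pytest.mark.parametrize("counts", [(5, 2, 3), (10, 6, 1), (3, 9, 2)])
def test_hwe_exact_brute_force_oracle(counts):
    """Exact HWE p equals a rational-arithmetic enumeration oracle."""
    from fractions import Fraction
    from math import factorial

    hom_major, het, hom_minor = counts
    n = sum(counts)
    rare = min(2 * hom_minor + het, 2 * hom_major + het)

    def prob(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return Fraction(
            2**h * factorial(n) * factorial(rare) * factorial(2 * n - rare),
            factorial(h) * factorial(hom_rare) * factorial(hom_common) * factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    assert sum(probs.values()) == 1
    expected = float(sum(p for p in probs.values() if p <= probs[het]))
    assert hwe_exact(counts).p_value == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# 2x3 genotype distribution and trend
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sid,expected_stat,expected_p",
    [
        ("rs1853259", 6.54, 0.038),
        ("rs7766006", None, 0.022),
        ("rs9457712", None, 0.347),
    ],
)
def test_genotype_dist_published(table2, sid, expected_stat, expected_p):
    result = genotype_dist_chi2(table2[sid])
    assert result.df == 2
    assert result.p_value == pytest.approx(expected_p, abs=0.001)
    if expected_stat is not None:
        assert result.statistic == pytest.approx(expected_stat, abs=0.01)


def test_genotype_dist_identical_groups():
    table = GenotypeCountTable("rs1", (30, 40, 30), (30, 40, 30))
    result = genotype_dist_chi2(table)
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_genotype_dist_drops_empty_column():
    table = GenotypeCountTable("rs1", (30, 40, 0), (35, 30, 0))
    assert genotype_dist_chi2(table).df == 1
    degenerate = GenotypeCountTable("rs1", (30, 0, 0), (35, 0, 0))
    assert not genotype_dist_chi2(degenerate).defined


@pytest.mark.parametrize(
    "sid,expected_p",
    [("rs1853259", 0.011), ("rs7766006", 0.008), ("rs9457712", 0.964)],
)
def test_trend_published(table2, sid, expected_p):
    assert armitage_trend(table2[sid]).p_value == pytest.approx(expected_p, abs=0.001)


def test_trend_zero_variance_flagged():
    table = GenotypeCountTable("rs1", (0, 50, 0), (0, 40, 0))
    assert not armitage_trend(table).defined


@settings(max_examples=100, deadline=None)
@given(
    counts=st.lists(st.integers(0, 200), min_size=6, max_size=6).filter(
        lambda c: sum(c[:3]) > 0 and sum(c[3:]) > 0
        and sum(1 for k in range(3) if c[k] + c[k + 3] > 0) >= 2
    )
)
def test_trend_is_component_of_genotype_test(counts):
    """Cochran-Armitage z^2 never exceeds the 2-df Pearson statistic."""
    table = GenotypeCountTable("rs1", tuple(counts[:3]), tuple(counts[3:]))
    trend = armitage_trend(table)
    dist = genotype_dist_chi2(table)
    if trend.defined and dist.defined:
        assert trend.z_statistic**2 <= dist.statistic + 1e-9


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "abcd,expected",
    [
        # (a, b, c, d), (OR, low, high, p) as printed
        ((85, 153, 62, 181), (1.62, 1.10, 2.40, 0.016)),
        ((235, 153, 216, 181), (1.29, 0.97, 1.71, 0.081)),
        ((220, 175, 233, 132), (0.71, 0.53, 0.95, 0.023)),
        ((78, 175, 94, 132), (0.63, 0.43, 0.91, 0.015)),
        ((120, 333, 130, 316), (0.88, 0.65, 1.17, 0.374)),
    ],
)
def test_wald_or_published(abcd, expected):
    result = odds_ratio_wald(*abcd)
    assert result.or_point == pytest.approx(expected[0], abs=0.005)
    assert result.ci_low == pytest.approx(expected[1], abs=0.005)
    assert result.ci_high == pytest.approx(expected[2], abs=0.005)
    assert result.p_value == pytest.approx(expected[3], abs=0.001)


def test_wald_or_symmetry():
    result = odds_ratio_wald(7, 7, 7, 7)
    assert result.or_point == pytest.approx(1.0)
    assert result.p_value == pytest.approx(1.0)


@settings(max_examples=100, deadline=None)
@given(cells=st.lists(st.integers(1, 500), min_size=4, max_size=4))
def test_wald_or_inversion(cells):
    """Swapping case and control rows maps OR -> 1/OR, p unchanged."""
    a, b, c, d = cells
    fwd = odds_ratio_wald(a, b, c, d)
    rev = odds_ratio_wald(c, d, a, b)
    assert rev.or_point == pytest.approx(1.0 / fwd.or_point, rel=1e-12)
    assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-9)


def test_wald_or_zero_cell_flagged_and_continuity():
    result = odds_ratio_wald(0, 10, 5, 5)
    assert not result.defined and result.or_point is None
    corrected = odds_ratio_wald(0, 10, 5, 5, continuity=True)
    assert corrected.defined
    assert corrected.or_point == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-9)


def test_model_contrasts_published(table2):
    by_contrast = {r.contrast: r for r in model_contrasts(table2["rs1853259"])}
    dom = by_contrast["dominant"]
    assert (dom.or_point, dom.ci_low, dom.ci_high) == pytest.approx(
        (1.36, 1.04, 1.78), abs=0.005
    )
    rec = by_contrast["recessive"]
    assert rec.or_point == pytest.approx(1.40, abs=0.005)
    # additive: genotype-dosage logistic OR paired with the trend p
    add = by_contrast["additive"]
    assert add.or_point == pytest.approx(1.28, abs=0.005)
    assert (add.ci_low, add.ci_high) == pytest.approx((1.06, 1.54), abs=0.005)
    assert add.p_value == pytest.approx(0.011, abs=0.001)

    add6 = {r.contrast: r for r in model_contrasts(table2["rs7766006"])}["additive"]
    assert add6.or_point == pytest.approx(0.78, abs=0.005)
    assert add6.p_value == pytest.approx(0.008, abs=0.001)


def test_additive_dosage_matches_grid_search_mle(table2):
    """The dosage logistic OR maximises the binomial likelihood (oracle)."""
    table = table2["rs7766006"]
    r = np.array(table.counts_case, dtype=float)
    s = np.array(table.counts_control, dtype=float)
    dosage = np.arange(3)

    def loglik(beta0, beta1):
        eta = beta0 + beta1 * dosage
        return float(np.sum(r * eta - (r + s) * np.log1p(np.exp(eta))))

    fitted = {c.contrast: c for c in model_contrasts(table)}["additive"]
    b1_hat = fitted.log_or
    best = max(
        (
            loglik(b0, b1)
            for b0 in np.linspace(-0.5, 0.9, 57)
            for b1 in np.linspace(-0.8, 0.4, 49)
        ),
    )
    # profile the intercept at the fitted slope
    from scipy.optimize import minimize_scalar

    prof = minimize_scalar(lambda b0: -loglik(b0, b1_hat), bounds=(-2, 2), method="bounded")
    assert -prof.fun >= best - 1e-6


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def test_logistic_2x2_equals_cross_product():
    """Saturated 2x2 logistic MLE equals the Woolf odds ratio exactly."""
    a, b, c, d = 85, 153, 62, 181
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    fit = logistic_fit(np.column_stack([np.ones_like(x), x]), y)
    wald = odds_ratio_wald(a, b, c, d)
    assert fit.converged
    assert math.exp(fit.estimates[1]) == pytest.approx(wald.or_point, abs=1e-9)
    assert fit.standard_errors[1] == pytest.approx(wald.se, abs=1e-9)


def test_logistic_null_p_uniform():
    """Wald p under the null is U(0,1): KS over seeded replicates."""
    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(200):
        x = rng.normal(size=400)
        y = (rng.random(400) < 0.5).astype(float)
        fit = logistic_fit(np.column_stack([np.ones(400), x]), y)
        pvals.append(fit.wald_p[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_logistic_separation_flagged():
    x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    fit = logistic_fit(np.column_stack([np.ones(6), x]), y)
    assert not fit.converged


def test_logistic_singular_design_names_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    X = np.column_stack([np.ones(50), x, 2.0 * x])
    y = (rng.random(50) < 0.5).astype(float)
    with pytest.raises(SingularDesignError):
        logistic_fit(X, y, names=["intercept", "x", "x2"])


def test_logistic_one_class_raises():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValidationError):
        logistic_fit(X, np.ones(10))


# ---------------------------------------------------------------------------
# Adjusted contrasts
# ---------------------------------------------------------------------------


def test_adjusted_near_crude_under_null_covariates():
    from endoassoc.cohort import count_genotypes

    cohort = simulate_cohort(default_config(seed=3, n_cases=800, n_controls=800))
    crude = {
        r.contrast: r for r in model_contrasts(count_genotypes(cohort, "rs1853259"))
    }
    adjusted = {r.contrast: r for r in adjusted_contrasts(cohort, "rs1853259")}
    for contrast in ("dominant", "recessive", "additive"):
        assert adjusted[contrast].adjusted
        assert adjusted[contrast].log_or == pytest.approx(
            crude[contrast].log_or, abs=0.05
        )


def test_adjusted_recovers_confounded_effect():
    """With genotype-coupled ages that affect risk, adjustment beats crude."""
    from endoassoc.cohort import count_genotypes
    from endoassoc.simulate import CovariateModel

    truth = math.log(1.6)
    wins = 0
    n_rep = 50
    for seed in range(n_rep):
        cohort = simulate_cohort(
            default_config(
                seed=seed,
                n_cases=700,
                n_controls=700,
                effects={"rs1853259": EffectSpec("additive", truth)},
                covariates=CovariateModel(age_effect=0.08),
                confound_age_snp="rs1853259",
                confound_age_per_allele=4.0,
                missing_rate=0.0,
            )
        )
        crude = {
            r.contrast: r
            for r in model_contrasts(count_genotypes(cohort, "rs1853259"))
        }["additive"]
        adj = {
            r.contrast: r
            for r in adjusted_contrasts(cohort, "rs1853259", covariates=("age",))
        }["additive"]
        if abs(adj.log_or - truth) <= abs(crude.log_or - truth):
            wins += 1
    assert wins >= 0.8 * n_rep


def test_adjusted_missing_covariate_drops_subject(tiny_cohort):
    # s4 (control) lacks covariates, s2 (case) lacks the rs7766006 genotype
    results = adjusted_contrasts(tiny_cohort, "rs1853259", covariates=("age",))
    assert all(r.n_used == 3 for r in results if r.contrast == "additive")
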