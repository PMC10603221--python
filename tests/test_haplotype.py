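"""EM haplotype inference: oracles, invariants and published counts."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from endoassoc.cohort import Cohort, SnpDef, Subject
from endoassoc.fixtures import fixture_counts
from endoassoc.haplotype import (
    HaplotypeEstimate,
    adjusted_haplotype_association,
    em_haplotypes,
    haplotype_association,
    haplotype_dosages,
    ld_pairwise,
)
from endoassoc.simulate import (
    default_config,
    default_snps,
    haplotype_freqs_from_r,
    simulate_cohort,
)


def _cohort_from_genotypes(snps, genotype_rows):
    """genotype_rows: list of (status, [call per snp])."""
    subjects = [
        Subject(
            f"s{i}",
            status,
            genotypes={snp.snp_id: call for snp, call in zip(snps, calls)},
        )
        for i, (status, calls) in enumerate(genotype_rows)
    ]
    return Cohort(snps=list(snps), subjects=subjects)


def test_em_all_homozygous_single_iteration():
    snps = [SnpDef("r1", "A", "G"), SnpDef("r2", "C", "T")]
    rows = [("case", ["AA", "CC"])] * 3 + [("case", ["GG", "TT"])] * 2
    rows += [("control", ["AA", "TT"])] * 4
    estimate = em_haplotypes(_cohort_from_genotypes(snps, rows), ["r1", "r2"],
                             n_restarts=0)
    case = dict(zip(estimate.haplotypes, estimate.freqs["case"]))
    assert case["AC"] == pytest.approx(0.6)
    assert case["GT"] == pytest.approx(0.4)
    assert estimate.n_iterations["case"] <= 2  # no phase ambiguity
    ctrl = dict(zip(estimate.haplotypes, estimate.expected_counts["control"]))
    assert ctrl["AT"] == pytest.approx(8.0)


def test_em_double_het_symmetry():
    """All double heterozygotes: the likelihood forces f(AB)=f(ab), f(Ab)=f(aB)."""
    snps = [SnpDef("r1", "A", "G"), SnpDef("r2", "C", "T")]
    rows = [("case", ["AG", "CT"])] * 8 + [("control", ["AG", "CT"])] * 8
    estimate = em_haplotypes(_cohort_from_genotypes(snps, rows), ["r1", "r2"])
    for group in ("case", "control"):
        freq = dict(zip(estimate.haplotypes, estimate.freqs[group]))
        assert freq["AC"] == pytest.approx(freq["GT"], abs=1e-6)
        assert freq["AT"] == pytest.approx(freq["GC"], abs=1e-6)


def _brute_force_loglik_max(genotypes, haplotypes, hap_index, pair_lists):
    """Direct likelihood maximisation over the frequency simplex."""

    def negloglik(params):
        z = np.concatenate([params, [0.0]])
        z = z - z.max()
        f = np.exp(z)
        f /= f.sum()
        total = 0.0
        for genotype in genotypes:
            like = sum(
                (1.0 if i == j else 2.0) * f[i] * f[j]
                for i, j in pair_lists[genotype]
            )
            total += np.log(max(like, 1e-300))
        return -total

    best = None
    rng = np.random.default_rng(0)
    for _ in range(12):
        x0 = rng.normal(scale=1.0, size=len(haplotypes) - 1)
        res = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    z = np.concatenate([best.x, [0.0]])
    z -= z.max()
    f = np.exp(z)
    f /= f.sum()
    return -best.fun, f


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_em_matches_brute_force_on_tiny_instances(seed):
    """EM frequencies equal direct simplex maximisation (<= 6 subjects)."""
    from endoassoc.haplotype import _all_haplotypes, _compatible_pairs

    snps = default_snps()
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(6):
        row = []
        for snp in snps:
            pair = "".join(
                sorted(
                    rng.choice([snp.allele_major, snp.allele_minor], size=2)
                )
            )
            row.append(pair)
        calls.append(("case", row))
    cohort = _cohort_from_genotypes(snps, calls + [("control", calls[0][1])])
    estimate = em_haplotypes(
        cohort, [s.snp_id for s in snps], tol=1e-12, max_iter=5000, seed=seed
    )

    haplotypes = _all_haplotypes(snps)
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    genotypes = [tuple(row) for _, row in calls]
    pair_lists = {g: _compatible_pairs(g, hap_index) for g in set(genotypes)}
    oracle_ll, oracle_f = _brute_force_loglik_max(
        genotypes, haplotypes, hap_index, pair_lists
    )
    assert estimate.log_likelihood["case"] == pytest.approx(oracle_ll, abs=1e-6)
    np.testing.assert_allclose(estimate.freqs["case"], oracle_f, atol=1e-4)


def test_em_loglik_monotone_and_counts_conserved():
    cohort = simulate_cohort(default_config(seed=9, n_cases=150, n_controls=150))
    estimate = em_haplotypes(cohort, [s.snp_id for s in cohort.snps], seed=0)
    for group in ("case", "control"):
        trace = np.array(estimate.loglik_trace[group])
        assert np.all(np.diff(trace) >= -1e-9)
        assert sum(estimate.expected_counts[group]) == pytest.approx(
            2.0 * estimate.n_phased[group], abs=1e-6
        )
        assert sum(estimate.freqs[group]) == pytest.approx(1.0, abs=1e-10)


def test_em_order_invariance():
    cohort = simulate_cohort(default_config(seed=13, n_cases=60, n_controls=60))
    snp_ids = [s.snp_id for s in cohort.snps]
    base = em_haplotypes(cohort, snp_ids, seed=0)
    shuffled = Cohort(snps=cohort.snps, subjects=list(reversed(cohort.subjects)))
    assert em_haplotypes(shuffled, snp_ids, seed=0).freqs == base.freqs
    # permuting snp_order permutes haplotype labels consistently
    perm = [snp_ids[1], snp_ids[2], snp_ids[0]]
    permuted = em_haplotypes(cohort, perm, seed=0)
    base_map = dict(zip(base.haplotypes, base.freqs["case"]))
    for hap, freq in zip(permuted.haplotypes, permuted.freqs["case"]):
        original = hap[2] + hap[0] + hap[1]
        assert freq == pytest.approx(base_map[original], abs=1e-6)


def test_published_haplotype_counts_reproduce_odds_ratios():
    """Association on the printed chromosome counts matches the printed
    OR/CI at two decimals, bar three CI bounds that are off by one digit
    in print (asserted at their recomputed values)."""
    t4 = fixture_counts("table4_haplotypes")
    assert sum(t4.cases) == 946 and sum(t4.controls) == 918
    estimate = HaplotypeEstimate.from_counts(
        t4.snp_order, t4.haplotypes, t4.cases, t4.controls
    )
    results = {r.contrast.split("_")[0]: r for r in haplotype_association(estimate, "AGG")}
    expected = {
        # printed values; CI bounds replaced by recomputed ones where the
        # printed digit is not a Wald bound of the printed counts
        "AGA": (1.69, 1.02, 2.80, 0.041),
        "ATG": (0.84, 0.6447, 1.10, 0.208),
        "ATA": (0.75, 0.51, 1.10, 0.142),
        "GGG": (1.43, 1.0746, 1.89, 0.014),
        "GGA": (1.17, 0.7947, 1.73, 0.420),
        "GTG": (1.05, 0.80, 1.38, 0.715),
    }
    for hap, (or_, low, high, p) in expected.items():
        r = results[hap]
        assert r.or_point == pytest.approx(or_, abs=0.005)
        assert r.ci_low == pytest.approx(low, abs=0.005)
        assert r.ci_high == pytest.approx(high, abs=0.005)
        assert r.p_value == pytest.approx(p, abs=0.001)
    assert not results["GTA"].defined  # the 0/0 haplotype


def test_haplotype_association_null_ratio():
    estimate = HaplotypeEstimate.from_counts(
        ("r1", "r2"), ("AC", "AT", "GC", "GT"),
        case_counts=(100.0, 50.0, 30.0, 20.0),
        control_counts=(200.0, 100.0, 40.0, 60.0),
    )
    result = [r for r in haplotype_association(estimate, "AC")
              if r.contrast.startswith("AT")][0]
    assert result.or_point == pytest.approx(1.0, abs=1e-12)


def test_haplotype_association_missing_reference():
    t4 = fixture_counts("table4_haplotypes")
    estimate = HaplotypeEstimate.from_counts(
        t4.snp_order, t4.haplotypes, t4.cases, t4.controls
    )
    with pytest.raises(KeyError):
        haplotype_association(estimate, "CCC")


def test_haplotype_dosages_sum_to_two():
    cohort = simulate_cohort(default_config(seed=21, n_cases=80, n_controls=80))
    estimate = em_haplotypes(cohort, [s.snp_id for s in cohort.snps], seed=0)
    ids, statuses, dosage = haplotype_dosages(estimate, cohort)
    np.testing.assert_allclose(dosage.sum(axis=1), 2.0, atol=1e-9)


def test_adjusted_haplotype_association_runs():
    cohort = simulate_cohort(default_config(seed=22, n_cases=250, n_controls=250))
    estimate = em_haplotypes(cohort, [s.snp_id for s in cohort.snps], seed=0)
    freqs = estimate.freqs["control"]
    reference = estimate.haplotypes[int(np.argmax(freqs))]
    results = adjusted_haplotype_association(cohort, estimate, reference)
    assert all(r.adjusted for r in results)
    assert any(r.defined for r in results)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def test_ld_linkage_equilibrium_toy():
    snps = [SnpDef("r1", "A", "G"), SnpDef("r2", "C", "T")]
    # genotype counts matching independent loci with p=0.5 each
    rows = []
    for g1, g2 in itertools.product(("AA", "AG", "GG"), ("CC", "CT", "TT")):
        w1 = {"AA": 1, "AG": 2, "GG": 1}[g1]
        w2 = {"CC": 1, "CT": 2, "TT": 1}[g2]
        rows += [("control", [g1, g2])] * (w1 * w2)
    cohort = _cohort_from_genotypes(snps, rows)
    ld = ld_pairwise(cohort, "r1", "r2")
    assert ld.d == pytest.approx(0.0, abs=1e-6)
    assert ld.r_squared == pytest.approx(0.0, abs=1e-6)


def test_ld_complete_toy():
    snps = [SnpDef("r1", "A", "G"), SnpDef("r2", "C", "T")]
    rows = [("control", ["AA", "CC"])] * 5 + [("control", ["GG", "TT"])] * 5
    rows += [("control", ["AG", "CT"])] * 10
    ld = ld_pairwise(_cohort_from_genotypes(snps, rows), "r1", "r2")
    assert abs(ld.d_prime) == pytest.approx(1.0, abs=1e-6)
    assert ld.r_squared == pytest.approx(1.0, abs=1e-6)


def test_ld_monomorphic_flagged():
    snps = [SnpDef("r1", "A", "G"), SnpDef("r2", "C", "T")]
    rows = [("control", ["AA", "CT"])] * 6
    assert not ld_pairwise(_cohort_from_genotypes(snps, rows), "r1", "r2").defined


def test_ld_recovery_from_simulation():
    """EM r^2 on a large null cohort recovers the configured r^2 = 0.3."""
    snp_a = SnpDef("r1", "A", "G")
    snp_b = SnpDef("r2", "C", "T")
    freqs = haplotype_freqs_from_r(snp_a, snp_b, 0.35, 0.25, np.sqrt(0.3))
    config = default_config(
        seed=77,
        n_cases=5000,
        n_controls=5000,
        snps=(snp_a, snp_b),
        haplotype_freqs=freqs,
        effects={},
        missing_rate=0.0,
    )
    cohort = simulate_cohort(config)
    ld = ld_pairwise(cohort, "r1", "r2")
    assert ld.r_squared == pytest.approx(0.3, abs=0.02)
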