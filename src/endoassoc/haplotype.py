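"""EM haplotype-frequency inference and linkage disequilibrium.

Unphased multi-locus genotypes are resolved with the standard
expectation-maximisation algorithm: the E-step distributes each subject
over the ordered haplotype pairs compatible with their genotype in
proportion to the current frequency products (2 f_h f_k for h != k), and
the M-step re-estimates frequencies from the expected haplotype counts.
The likelihood is non-decreasing across iterations; a linkage-equilibrium
start plus a few seeded random restarts guards against local maxima.

Haplotype association contrasts expected chromosome counts between cases
and controls with Woolf/Wald odds ratios, treating chromosomes as
independent.  Pairwise LD (D, D', r^2) is derived from two-locus EM
frequencies.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assoc import AssocResult, Z975, logistic_fit, odds_ratio_wald
from .cohort import Cohort, ValidationError

__all__ = [
    "HaplotypeEstimate",
    "LdStats",
    "em_haplotypes",
    "haplotype_association",
    "adjusted_haplotype_association",
    "haplotype_dosages",
    "ld_pairwise",
]


@dataclass(frozen=True)
class HaplotypeEstimate:
    """Per-group haplotype frequencies and expected chromosome counts."""

    snp_order: tuple
    haplotypes: tuple  # allele strings, one character per SNP
    freqs: dict  # group -> tuple of frequencies
    expected_counts: dict  # group -> tuple (frequency x 2 x group size)
    n_phased: dict  # group -> subjects with complete genotypes
    log_likelihood: dict
    n_iterations: dict
    converged: dict
    loglik_trace: dict  # group -> tuple of per-iteration log-likelihoods

    @classmethod
    def from_counts(
        cls,
        snp_order: Sequence[str],
        haplotypes: Sequence[str],
        case_counts: Sequence[float],
        control_counts: Sequence[float],
    ) -> "HaplotypeEstimate":
        """Build an estimate directly from known chromosome counts.

        Used to anchor analyses on published aggregate haplotype tables.
        """
        case = np.asarray(case_counts, dtype=float)
        ctrl = np.asarray(control_counts, dtype=float)
        return cls(
            snp_order=tuple(snp_order),
            haplotypes=tuple(haplotypes),
            freqs={
                "case": tuple(case / case.sum()),
                "control": tuple(ctrl / ctrl.sum()),
            },
            expected_counts={"case": tuple(case), "control": tuple(ctrl)},
            n_phased={"case": int(case.sum() // 2), "control": int(ctrl.sum() // 2)},
            log_likelihood={},
            n_iterations={},
            converged={"case": True, "control": True},
            loglik_trace={},
        )

    def count(self, group: str, haplotype: str) -> float:
        return self.expected_counts[group][self.haplotypes.index(haplotype)]


@dataclass(frozen=True)
class LdStats:
    snp_a: str
    snp_b: str
    d: Optional[float]
    d_prime: Optional[float]
    r_squared: Optional[float]
    defined: bool = True


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------


def _all_haplotypes(snps) -> tuple:
    """Cartesian product of (major, minor) alleles, last marker fastest."""
    pools = [(s.allele_major, s.allele_minor) for s in snps]
    return tuple("".join(combo) for combo in itertools.product(*pools))


def _compatible_pairs(genotype: tuple, hap_index: dict) -> list:
    """Unordered haplotype-index pairs compatible with a multilocus genotype.

    ``genotype`` is a tuple of sorted allele pairs, one per SNP.  With h
    heterozygous sites there are max(1, 2^(h-1)) distinct unordered pairs;
    symmetry is broken by pinning the first het site's assignment.
    """
    het_sites = [i for i, pair in enumerate(genotype) if pair[0] != pair[1]]
    base = [pair[0] for pair in genotype]
    if not het_sites:
        idx = hap_index["".join(base)]
        return [(idx, idx)]
    pairs = []
    for choices in itertools.product((0, 1), repeat=len(het_sites) - 1):
        hap1 = list(base)
        hap2 = list(base)
        hap2[het_sites[0]] = genotype[het_sites[0]][1]
        for site, flip in zip(het_sites[1:], choices):
            hap1[site] = genotype[site][flip]
            hap2[site] = genotype[site][1 - flip]
        i, j = hap_index["".join(hap1)], hap_index["".join(hap2)]
        pairs.append((i, j) if i <= j else (j, i))
    return pairs


def _em_single_group(
    genotype_counter: Counter,
    pair_lists: dict,
    n_haps: int,
    start: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple:
    """Run EM from one starting point; returns (freqs, trace, iters, conv)."""
    freqs = start.copy()
    n_subjects = sum(genotype_counter.values())
    # fixed iteration order makes the output exactly independent of the
    # order subjects were supplied in
    items = sorted(genotype_counter.items())
    trace = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        counts = np.zeros(n_haps)
        loglik = 0.0
        for genotype, multiplicity in items:
            pairs = pair_lists[genotype]
            weights = np.array(
                [(1.0 if i == j else 2.0) * freqs[i] * freqs[j] for i, j in pairs]
            )
            total = weights.sum()
            if total <= 0.0:
                # genotype unreachable under current freqs: spread uniformly
                weights = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += multiplicity * -745.0  # log of ~5e-324, effectively -inf
            else:
                weights = weights / total
                loglik += multiplicity * math.log(total)
            for (i, j), w in zip(pairs, weights):
                counts[i] += multiplicity * w
                counts[j] += multiplicity * w
        trace.append(loglik)
        new_freqs = counts / (2.0 * n_subjects)
        delta = np.abs(new_freqs - freqs).max()
        freqs = new_freqs
        if delta < tol:
            converged = True
            break
    return freqs, trace, iterations, converged


def _group_genotypes(cohort: Cohort, snp_ids, subjects) -> Counter:
    counter: Counter = Counter()
    for subj in subjects:
        calls = [subj.genotypes.get(sid) for sid in snp_ids]
        if any(c is None for c in calls):
            continue
        counter[tuple(calls)] += 1
    return counter


def em_haplotypes(
    cohort: Cohort,
    snp_ids: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    pooled: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    groups: Sequence[str] = ("case", "control"),
) -> HaplotypeEstimate:
    """EM haplotype frequencies, run separately within each status group.

    Subjects with any missing genotype among ``snp_ids`` are excluded.
    Initialisation is the linkage-equilibrium product of single-locus
    allele frequencies, followed by ``n_restarts`` seeded Dirichlet
    restarts; the best likelihood is kept per group.  With ``pooled=True``
    a single EM is run on all subjects and the pooled frequencies are used
    to split expected counts per group.
    """
    if not snp_ids:
        raise ValueError("need at least one SNP")
    snps = [cohort.snp(sid) for sid in snp_ids]
    haplotypes = _all_haplotypes(snps)
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    n_haps = len(haplotypes)

    grouping: dict = {g: cohort.group(g) for g in groups}
    if pooled:
        grouping = {"pooled": [s for g in groups for s in grouping[g]]}

    freqs_out: dict = {}
    counts_out: dict = {}
    n_phased: dict = {}
    loglik_out: dict = {}
    iters_out: dict = {}
    conv_out: dict = {}
    trace_out: dict = {}

    for group, subjects in grouping.items():
        counter = _group_genotypes(cohort, snp_ids, subjects)
        n_subj = sum(counter.values())
        if n_subj == 0:
            raise ValidationError(f"no phase-complete subjects in group {group!r}")
        pair_lists = {g: _compatible_pairs(g, hap_index) for g in counter}

        # linkage-equilibrium start from single-locus allele frequencies
        allele_freq = []
        for k, snp in enumerate(snps):
            minor = sum(
                mult * sum(1 for a in geno[k] if a == snp.allele_minor)
                for geno, mult in sorted(counter.items())
            )
            allele_freq.append(minor / (2.0 * n_subj))
        le_start = np.array(
            [
                math.prod(
                    allele_freq[k] if h[k] == snp.allele_minor else 1.0 - allele_freq[k]
                    for k, snp in enumerate(snps)
                )
                for h in haplotypes
            ]
        )
        le_start = np.clip(le_start, 1e-12, None)
        le_start /= le_start.sum()

        rng = np.random.default_rng(seed)
        starts = [le_start] + [rng.dirichlet(np.ones(n_haps)) for _ in range(n_restarts)]
        best = None
        for start in starts:
            run = _em_single_group(counter, pair_lists, n_haps, start, tol, max_iter)
            if best is None or run[1][-1] > best[1][-1] + 1e-12:
                best = run
        freqs, trace, iterations, converged = best
        freqs_out[group] = tuple(float(f) for f in freqs)
        counts_out[group] = tuple(float(f * 2.0 * n_subj) for f in freqs)
        n_phased[group] = n_subj
        loglik_out[group] = float(trace[-1])
        iters_out[group] = iterations
        conv_out[group] = converged
        trace_out[group] = tuple(trace)

    if pooled:
        # split pooled expected counts back into the original groups
        pooled_freqs = np.array(freqs_out["pooled"])
        for group in groups:
            counter = _group_genotypes(cohort, snp_ids, cohort.group(group))
            n_subj = sum(counter.values())
            counts = np.zeros(n_haps)
            for genotype, mult in sorted(counter.items()):
                pairs = _compatible_pairs(genotype, hap_index)
                weights = np.array(
                    [(1.0 if i == j else 2.0) * pooled_freqs[i] * pooled_freqs[j] for i, j in pairs]
                )
                weights /= weights.sum()
                for (i, j), w in zip(pairs, weights):
                    counts[i] += mult * w
                    counts[j] += mult * w
            freqs_out[group] = tuple(counts / (2.0 * n_subj)) if n_subj else tuple(pooled_freqs)
            counts_out[group] = tuple(float(c) for c in counts)
            n_phased[group] = n_subj

    return HaplotypeEstimate(
        snp_order=tuple(snp_ids),
        haplotypes=haplotypes,
        freqs=freqs_out,
        expected_counts=counts_out,
        n_phased=n_phased,
        log_likelihood=loglik_out,
        n_iterations=iters_out,
        converged=conv_out,
        loglik_trace=trace_out,
    )


# ---------------------------------------------------------------------------
# Haplotype association
# ---------------------------------------------------------------------------


def haplotype_association(
    estimate: HaplotypeEstimate, reference: str, min_count: float = 1e-3
) -> list:
    """Wald odds ratios of each haplotype against a reference haplotype.

    Expected chromosome counts enter the 2x2 unrounded; rounding is left
    to report rendering.  Expected counts below ``min_count`` chromosomes
    are treated as zero, so effectively absent haplotypes (like EM
    frequencies that decayed to numerical noise) come back flagged
    undefined rather than with an absurd interval.
    """
    if reference not in estimate.haplotypes:
        raise KeyError(f"reference haplotype {reference!r} not in estimate")
    ref_case = estimate.count("case", reference)
    ref_ctrl = estimate.count("control", reference)
    if ref_case <= 0.0 or ref_ctrl <= 0.0:
        raise ValidationError(f"reference {reference!r} has zero expected count")
    label = "-".join(estimate.snp_order)
    results = []
    for hap in estimate.haplotypes:
        if hap == reference:
            continue
        a = estimate.count("case", hap)
        c = estimate.count("control", hap)
        a = a if a >= min_count else 0.0
        c = c if c >= min_count else 0.0
        results.append(
            odds_ratio_wald(
                a, ref_case, c, ref_ctrl,
                snp_id=label, contrast=f"{hap}_vs_{reference}",
            )
        )
    return results


def haplotype_dosages(estimate: HaplotypeEstimate, cohort: Cohort):
    """Posterior-expected haplotype dosages (0..2) per subject.

    Uses each subject's own group frequencies.  Subjects with incomplete
    genotypes are omitted.  Returns ``(subject_ids, statuses, matrix)``
    with one column per haplotype in estimate order.
    """
    snps = [cohort.snp(sid) for sid in estimate.snp_order]
    hap_index = {h: i for i, h in enumerate(estimate.haplotypes)}
    ids, statuses, rows = [], [], []
    for subj in cohort.subjects:
        calls = tuple(subj.genotypes.get(sid) for sid in estimate.snp_order)
        if any(c is None for c in calls):
            continue
        freqs = np.array(estimate.freqs[subj.status])
        pairs = _compatible_pairs(calls, hap_index)
        weights = np.array(
            [(1.0 if i == j else 2.0) * freqs[i] * freqs[j] for i, j in pairs]
        )
        total = weights.sum()
        weights = weights / total if total > 0 else np.full(len(pairs), 1.0 / len(pairs))
        dosage = np.zeros(len(estimate.haplotypes))
        for (i, j), w in zip(pairs, weights):
            dosage[i] += w
            dosage[j] += w
        ids.append(subj.subject_id)
        statuses.append(subj.status)
        rows.append(dosage)
    return ids, statuses, np.array(rows)


def adjusted_haplotype_association(
    cohort: Cohort,
    estimate: HaplotypeEstimate,
    reference: str,
    covariates: Sequence[str] = ("age", "gravidity", "parity"),
) -> list:
    """Covariate-adjusted haplotype odds ratios via dosage logistic.

    One logistic fit with all non-reference haplotype dosages as
    predictors (the reference absorbs the baseline, since dosages sum to
    two); each coefficient is that haplotype's log OR against the
    reference.  Haplotypes with negligible total dosage are dropped and
    reported undefined.
    """
    ids, statuses, dosage = haplotype_dosages(estimate, cohort)
    by_id = {s.subject_id: s for s in cohort.subjects}
    keep_rows, cov_rows = [], []
    for k, sid in enumerate(ids):
        covs = [getattr(by_id[sid], c) for c in covariates]
        if any(v is None for v in covs):
            continue
        keep_rows.append(k)
        cov_rows.append([float(v) for v in covs])
    dosage = dosage[keep_rows]
    y = np.array([1.0 if statuses[k] == "case" else 0.0 for k in keep_rows])
    ref_idx = estimate.haplotypes.index(reference)
    label = "-".join(estimate.snp_order)
    # haplotypes carrying less than half an expected chromosome cannot be
    # estimated and would destabilise the fit
    used = [
        i
        for i in range(len(estimate.haplotypes))
        if i != ref_idx and dosage[:, i].sum() > 0.5
    ]
    X = np.column_stack(
        [np.ones(len(y)), dosage[:, used], np.array(cov_rows, dtype=float)]
    )
    names = ["intercept", *[estimate.haplotypes[i] for i in used], *covariates]
    fit = logistic_fit(X, y, names=names)
    results = []
    for i in range(len(estimate.haplotypes)):
        if i == ref_idx:
            continue
        hap = estimate.haplotypes[i]
        contrast = f"{hap}_vs_{reference}"
        if i not in used or not fit.converged:
            results.append(
                AssocResult(label, contrast, None, None, None, None,
                            adjusted=True, n_used=len(y), defined=False)
            )
            continue
        k = 1 + used.index(i)
        log_or, se = fit.estimates[k], fit.standard_errors[k]
        results.append(
            AssocResult(
                snp_id=label,
                contrast=contrast,
                or_point=math.exp(log_or),
                ci_low=math.exp(log_or - Z975 * se),
                ci_high=math.exp(log_or + Z975 * se),
                p_value=fit.wald_p[k],
                adjusted=True,
                n_used=len(y),
                defined=True,
                log_or=log_or,
                se=se,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_pairwise(
    cohort: Cohort,
    snp_a: str,
    snp_b: str,
    status: Optional[str] = None,
    **em_kwargs,
) -> LdStats:
    """Pairwise D, D' and r^2 from two-locus EM haplotype frequencies.

    ``status`` restricts the estimation to one group; the default pools
    cases and controls.  D is oriented on the major alleles.
    """
    groups = (status,) if status else ("case", "control")
    estimate = em_haplotypes(
        cohort, [snp_a, snp_b], pooled=True, groups=groups, **em_kwargs
    )
    freqs = np.array(estimate.freqs["pooled"])
    # haplotype order: (majA majB), (majA minB), (minA majB), (minA minB)
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0.0:
        return LdStats(snp_a, snp_b, None, None, None, defined=False)
    d = freqs[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = d / d_max if d_max > 0 else 0.0
    r_squared = d * d / (p_a * q_a * p_b * q_b)
    return LdStats(snp_a, snp_b, float(d), float(d_prime), float(r_squared))
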