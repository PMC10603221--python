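"""Synthetic case-control cohort generator.

Emulates the design of a hospital-based candidate-gene study: each
subject draws two haplotypes i.i.d. from a specified population haplotype
frequency vector (which fixes both allele frequencies and pairwise LD),
covariates are drawn independently of genotype (age from a truncated
normal, gravidity/parity from small categorical distributions), and
disease status follows a prospective logistic model on the liability

    logit P(case) = baseline + sum_snp effect(genotype) + covariate terms.

Subjects are accumulated by rejection sampling until exactly the target
numbers of cases and controls are collected, emulating retrospective
ascertainment; under case-control sampling the genotype odds ratios of
the generating logistic model are preserved.  Genotype calls are then
masked missing at a fixed rate.  A single seeded generator drives the
whole simulation, so identical configurations give identical cohorts.

The default configuration mirrors the source study's conditions: 473
cases and 459 controls at three biallelic SNPs, haplotype frequencies
matching the published control chromosome counts, per-allele odds ratios
of 1.28 (rs1853259 G), 0.78 (rs7766006 T) and 1.0 (rs9457712 A), ~10%
population prevalence, and the published rASRM stage mix for cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .cohort import Cohort, SnpDef, Subject
from .fixtures import default_snps

__all__ = [
    "SimulationError",
    "CovariateModel",
    "EffectSpec",
    "SimConfig",
    "default_hap_freqs",
    "default_config",
    "haplotype_freqs_from_r",
    "simulate_cohort",
]

#: rASRM stage distribution of the published case series.
DEFAULT_STAGE_PROBS = (0.7378, 0.2199, 0.0317, 0.0106)


class SimulationError(RuntimeError):
    """The requested case/control counts could not be reached."""


@dataclass(frozen=True)
class EffectSpec:
    """Genotype effect of one SNP on the disease liability (log odds).

    ``model`` is one of additive / dominant / recessive / genotypic; for
    ``genotypic``, ``log_or`` is a (het, minor-hom) pair.
    """

    model: str = "additive"
    log_or: object = 0.0

    def liability(self, dosage: np.ndarray) -> np.ndarray:
        if self.model == "additive":
            return float(self.log_or) * dosage
        if self.model == "dominant":
            return float(self.log_or) * (dosage >= 1)
        if self.model == "recessive":
            return float(self.log_or) * (dosage == 2)
        if self.model == "genotypic":
            b_het, b_hom = self.log_or
            return b_het * (dosage == 1) + b_hom * (dosage == 2)
        raise ValueError(f"unknown effect model {self.model!r}")


@dataclass(frozen=True)
class CovariateModel:
    """Covariate distributions and their liability effects (log odds).

    Ages are truncated-normal; gravidity and parity are categorical over
    counts 0..k.  Defaults match the published control descriptives
    (mean age ~31, ~85% with gravidity <= 1, ~88% with parity <= 1).
    Effects default to zero: covariates are independent of outcome and of
    genotype unless a confounding switch couples them.
    """

    age_mean: float = 31.1
    age_sd: float = 7.0
    age_bounds: tuple = (18.0, 55.0)
    gravidity_probs: tuple = (0.45, 0.40, 0.10, 0.05)
    parity_probs: tuple = (0.55, 0.33, 0.10, 0.02)
    age_effect: float = 0.0
    gravidity_effect: float = 0.0
    parity_effect: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    n_cases: int = 473
    n_controls: int = 459
    snps: tuple = field(default_factory=lambda: tuple(default_snps()))
    haplotype_freqs: dict = field(default_factory=lambda: dict(default_hap_freqs()))
    effects: dict = field(default_factory=dict)  # snp_id -> EffectSpec
    baseline_logit: float = -2.2
    covariates: CovariateModel = field(default_factory=CovariateModel)
    missing_rate: float = 0.02
    stage_probs: tuple = DEFAULT_STAGE_PROBS
    confound_age_snp: Optional[str] = None
    confound_age_per_allele: float = 0.0
    seed: int = 2023
    batch_size: int = 4096
    max_draw_factor: int = 400  # cap on total draws per requested subject

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        n_snps = len(self.snps)
        for hap in self.haplotype_freqs:
            if len(hap) != n_snps:
                raise ValueError(f"haplotype {hap!r} length != number of SNPs")
            for allele, snp in zip(hap, self.snps):
                if allele not in (snp.allele_major, snp.allele_minor):
                    raise ValueError(f"haplotype {hap!r}: bad allele for {snp.snp_id}")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        for snp_id in self.effects:
            if snp_id not in {s.snp_id for s in self.snps}:
                raise ValueError(f"effect for undeclared SNP {snp_id!r}")


def default_hap_freqs() -> dict:
    """Three-SNP haplotype frequencies matching the published control
    chromosome counts (918 control chromosomes)."""
    counts = {
        "AGG": 290, "AGA": 27, "ATG": 189, "ATA": 72,
        "GGG": 123, "GGA": 57, "GTG": 160, "GTA": 0,
    }
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def default_config(seed: int = 2023, **overrides) -> SimConfig:
    """Study-scale default configuration (473 cases / 459 controls)."""
    effects = {
        "rs1853259": EffectSpec("additive", math.log(1.28)),
        "rs7766006": EffectSpec("additive", math.log(0.78)),
        "rs9457712": EffectSpec("additive", 0.0),
    }
    return replace(SimConfig(effects=effects, seed=seed), **overrides)


def config_from_yaml(path) -> SimConfig:
    """Build a :class:`SimConfig` from a flat YAML key/value document.

    Scalar fields map directly; ``haplotype_freqs`` is a mapping of
    haplotype string to frequency, ``effects`` a mapping of snp_id to
    ``{model, log_or}``, and ``covariates`` a mapping of
    :class:`CovariateModel` fields.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "effects" in kwargs:
        kwargs["effects"] = {
            sid: EffectSpec(**spec) for sid, spec in kwargs["effects"].items()
        }
    if "covariates" in kwargs:
        kwargs["covariates"] = CovariateModel(**kwargs["covariates"])
    if "stage_probs" in kwargs:
        kwargs["stage_probs"] = tuple(kwargs["stage_probs"])
    config = replace(default_config(), **kwargs)
    config.validate()
    return config


def haplotype_freqs_from_r(
    snp_a: SnpDef, snp_b: SnpDef, p_minor_a: float, p_minor_b: float, r: float
) -> dict:
    """Two-SNP haplotype frequencies with a prescribed LD correlation r.

    f(minor-minor) = pA pB + r sqrt(pA qA pB qB); the remaining cells
    follow from the marginals.  Raises if the requested r is infeasible
    for the given allele frequencies.
    """
    pa, pb = p_minor_a, p_minor_b
    qa, qb = 1.0 - pa, 1.0 - pb
    d = r * math.sqrt(pa * qa * pb * qb)
    f_mm = pa * pb + d
    freqs = {
        snp_a.allele_minor + snp_b.allele_minor: f_mm,
        snp_a.allele_minor + snp_b.allele_major: pa - f_mm,
        snp_a.allele_major + snp_b.allele_minor: pb - f_mm,
        snp_a.allele_major + snp_b.allele_major: qa - pb + f_mm,
    }
    if min(freqs.values()) < -1e-12:
        raise ValueError(f"r = {r} infeasible at these allele frequencies")
    return {h: max(f, 0.0) for h, f in freqs.items()}


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort under ``config``; reproducible given its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    snps = list(config.snps)
    haplotypes = sorted(config.haplotype_freqs)
    freqs = np.array([config.haplotype_freqs[h] for h in haplotypes])
    # minor-allele dosage contributed by each haplotype at each SNP
    hap_dosage = np.array(
        [[1 if h[k] == snp.allele_minor else 0 for k, snp in enumerate(snps)]
         for h in haplotypes],
        dtype=float,
    )
    cov = config.covariates
    lo = (cov.age_bounds[0] - cov.age_mean) / cov.age_sd
    hi = (cov.age_bounds[1] - cov.age_mean) / cov.age_sd

    cases: list = []
    controls: list = []
    target = config.n_cases + config.n_controls
    max_draws = config.max_draw_factor * target
    drawn = 0
    while (len(cases) < config.n_cases or len(controls) < config.n_controls):
        if drawn >= max_draws:
            raise SimulationError(
                f"could not reach {config.n_cases}/{config.n_controls} "
                f"cases/controls within {max_draws} draws"
            )
        m = min(config.batch_size, max_draws - drawn)
        drawn += m
        hap_idx = rng.choice(len(haplotypes), size=(m, 2), p=freqs)
        dosage = hap_dosage[hap_idx[:, 0]] + hap_dosage[hap_idx[:, 1]]
        # truncated-normal ages by redrawing out-of-bounds values
        age = rng.normal(cov.age_mean, cov.age_sd, size=m)
        bad = (age < cov.age_bounds[0]) | (age > cov.age_bounds[1])
        while bad.any():
            age[bad] = rng.normal(cov.age_mean, cov.age_sd, size=int(bad.sum()))
            bad = (age < cov.age_bounds[0]) | (age > cov.age_bounds[1])
        gravidity = rng.choice(len(cov.gravidity_probs), size=m, p=cov.gravidity_probs)
        parity = rng.choice(len(cov.parity_probs), size=m, p=cov.parity_probs)
        if config.confound_age_snp is not None:
            k = [s.snp_id for s in snps].index(config.confound_age_snp)
            age = age + config.confound_age_per_allele * dosage[:, k]
            np.clip(age, cov.age_bounds[0], cov.age_bounds[1], out=age)

        logit = np.full(m, config.baseline_logit)
        for k, snp in enumerate(snps):
            effect = config.effects.get(snp.snp_id)
            if effect is not None:
                logit += effect.liability(dosage[:, k])
        logit += cov.age_effect * (age - cov.age_mean)
        logit += cov.gravidity_effect * gravidity
        logit += cov.parity_effect * parity
        is_case = rng.random(m) < expit(logit)

        for i in range(m):
            bucket = cases if is_case[i] else controls
            limit = config.n_cases if is_case[i] else config.n_controls
            if len(bucket) >= limit:
                continue
            genotype = {}
            for k, snp in enumerate(snps):
                pair = "".join(
                    sorted(haplotypes[hap_idx[i, 0]][k] + haplotypes[hap_idx[i, 1]][k])
                )
                genotype[snp.snp_id] = pair
            bucket.append(
                {
                    "age": round(float(age[i]), 1),
                    "gravidity": int(gravidity[i]),
                    "parity": int(parity[i]),
                    "genotypes": genotype,
                }
            )

    subjects = []
    stages = rng.choice(len(config.stage_probs), size=config.n_cases,
                        p=config.stage_probs)
    snp_ids = [s.snp_id for s in snps]
    if config.missing_rate > 0.0:
        mask = rng.random((target, len(snps))) < config.missing_rate
    else:
        mask = np.zeros((target, len(snps)), dtype=bool)
    row = 0
    for status, bucket in (("case", cases), ("control", controls)):
        prefix = "C" if status == "case" else "N"
        for j, record in enumerate(bucket):
            genotypes = {
                sid: (None if mask[row, k] else record["genotypes"][sid])
                for k, sid in enumerate(snp_ids)
            }
            subjects.append(
                Subject(
                    subject_id=f"{prefix}{j + 1:05d}",
                    status=status,
                    age=record["age"],
                    gravidity=record["gravidity"],
                    parity=record["parity"],
                    rasrm_stage=("I", "II", "III", "IV")[stages[j]]
                    if status == "case"
                    else None,
                    genotypes=genotypes,
                )
            )
            row += 1
    return Cohort(snps=snps, subjects=subjects)
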