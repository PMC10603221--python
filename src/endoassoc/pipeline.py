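"""End-to-end orchestration: QC -> single-locus -> combined -> haplotype
-> stratified -> credibility, with table rendering and a JSON summary.

``run_all`` executes the full analysis on a cohort (read from TSV or
simulated), writing one TSV per published-table analogue plus a
machine-readable ``summary.json`` (schema in ``docs/output_schema.md``).
Outputs are deterministic for a fixed configuration and seed: reruns
produce byte-identical bundles.  On a fatal stage error, partial outputs
are removed.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import assoc, credibility, haplotype, risk, stratify
from .cohort import Cohort, count_genotypes, qc_snp, read_cohort, write_cohort
from .fixtures import default_contrasts, default_snps
from .simulate import default_config, simulate_cohort
from .stratify import GenotypeContrast

logger = logging.getLogger("endoassoc")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    input_path: Optional[Path] = None  # None -> simulate
    snps: list = field(default_factory=default_snps)
    covariates: tuple = ("age", "gravidity", "parity")
    priors: tuple = (0.25, 0.1, 0.01)
    design_or_risk: float = 1.5
    design_or_protective: float = 0.67
    w_or: float = 1.5
    alpha: float = 0.05
    seed: int = 2023
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 0.001
    drop_failed_qc: bool = False
    reference_haplotype: Optional[str] = None  # None -> most common in controls

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "out_dir" in kwargs:
            kwargs["out_dir"] = Path(kwargs["out_dir"])
        if kwargs.get("input_path"):
            kwargs["input_path"] = Path(kwargs["input_path"])
        for key in ("covariates", "priors"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _fmt_or(value) -> str:
    return "NA" if value is None else f"{value:.2f}"


def _fmt_p(value) -> str:
    return "NA" if value is None else f"{value:.3f}"


def _assoc_row(result) -> dict:
    return {
        "snp_id": result.snp_id,
        "contrast": result.contrast,
        "or": _fmt_or(result.or_point),
        "ci_low": _fmt_or(result.ci_low),
        "ci_high": _fmt_or(result.ci_high),
        "p": _fmt_p(result.p_value),
        "adjusted": str(result.adjusted).lower(),
        "n_used": result.n_used,
    }


def _write_tsv(path: Path, rows: Sequence[dict]) -> None:
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    columns = list(rows[0])
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def _stage(name: str):
    logger.info("stage %s", name)
    return time.time()


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the JSON-serialisable summary."""
    out_dir = Path(config.out_dir)
    work = Path(tempfile.mkdtemp(prefix="endoassoc_"))
    try:
        summary = _run_all_into(config, work)
    except Exception:
        shutil.rmtree(work, ignore_errors=True)
        raise
    out_dir.mkdir(parents=True, exist_ok=True)
    for item in work.iterdir():
        shutil.move(str(item), str(out_dir / item.name))
    shutil.rmtree(work, ignore_errors=True)
    return summary


def _run_all_into(config: RunConfig, out_dir: Path) -> dict:
    # ---- input ------------------------------------------------------
    t0 = _stage("input")
    if config.input_path is None:
        cohort = simulate_cohort(default_config(seed=config.seed))
        write_cohort(cohort, out_dir / "cohort.tsv")
    else:
        cohort = read_cohort(config.input_path, config.snps)
    snp_ids = [s.snp_id for s in cohort.snps]
    logger.info(
        "cohort: %d cases, %d controls, %d SNPs (%.2fs)",
        cohort.n_cases, cohort.n_controls, len(snp_ids), time.time() - t0,
    )

    # ---- QC ---------------------------------------------------------
    _stage("qc")
    tables = {sid: count_genotypes(cohort, sid) for sid in snp_ids}
    qc_reports = [
        qc_snp(tables[sid], config.min_call_rate, config.min_maf, config.min_hwe_p)
        for sid in snp_ids
    ]
    if config.drop_failed_qc:
        from .cohort import drop_failing_snps

        cohort = drop_failing_snps(cohort, qc_reports)
        snp_ids = [s.snp_id for s in cohort.snps]
        tables = {sid: tables[sid] for sid in snp_ids}
    _write_tsv(
        out_dir / "table_qc.tsv",
        [
            {
                "snp_id": r.snp_id,
                "call_rate": f"{r.call_rate:.4f}",
                "maf_controls": f"{r.maf_controls:.4f}",
                "hwe_p_controls": _fmt_p(r.hwe_p_controls),
                "pass": str(r.pass_all).lower(),
            }
            for r in qc_reports
        ],
    )

    # ---- descriptives ----------------------------------------------
    _stage("descriptives")
    descriptives = stratify.render_descriptives(cohort)
    descriptives_rows = descriptives.to_dict("records")
    for row in descriptives_rows:
        row["p"] = _fmt_p(row["p"]) if row["p"] is not None else ""
    _write_tsv(out_dir / "table1_descriptives.tsv", descriptives_rows)

    # ---- single locus ----------------------------------------------
    _stage("single_locus")
    single_rows = []
    crude_results = []
    for sid in snp_ids:
        table = tables[sid]
        hwe = assoc.hwe_chi2(table.counts_control)
        dist = assoc.genotype_dist_chi2(table)
        trend = assoc.armitage_trend(table)
        crude = assoc.model_contrasts(table)
        adjusted = assoc.adjusted_contrasts(cohort, sid, config.covariates) \
            if _covariates_present(cohort, config.covariates) else []
        crude_results.extend(crude)
        for result in crude + list(adjusted):
            row = _assoc_row(result)
            row["hwe_p_controls"] = _fmt_p(hwe.p_value)
            row["p_genotype_dist"] = _fmt_p(dist.p_value)
            row["p_trend"] = _fmt_p(trend.p_value)
            single_rows.append(row)
    _write_tsv(out_dir / "table2_single_locus.tsv", single_rows)

    # ---- combined risk genotypes -----------------------------------
    _stage("combined")
    combined = risk.combined_risk_association(
        cohort,
        top_code=2,
        covariates=config.covariates
        if _covariates_present(cohort, config.covariates)
        else None,
    )
    combined_rows = []
    for k, label in enumerate(combined.labels):
        combined_rows.append(
            {
                "category": label,
                "cases": combined.counts_case[k],
                "controls": combined.counts_control[k],
            }
        )
    _write_tsv(out_dir / "table2_combined_counts.tsv", combined_rows)
    _write_tsv(
        out_dir / "table2_combined_assoc.tsv",
        [_assoc_row(r) for r in combined.results + combined.adjusted_results],
    )

    # ---- haplotypes -------------------------------------------------
    _stage("haplotype")
    estimate = haplotype.em_haplotypes(cohort, snp_ids, seed=config.seed)
    reference = config.reference_haplotype
    if reference is None:
        control_freqs = estimate.freqs["control"]
        reference = estimate.haplotypes[
            max(range(len(control_freqs)), key=control_freqs.__getitem__)
        ]
    hap_results = haplotype.haplotype_association(estimate, reference)
    hap_rows = []
    for hap, case_count, control_count in zip(
        estimate.haplotypes, estimate.expected_counts["case"],
        estimate.expected_counts["control"],
    ):
        row = {
            "haplotype": hap,
            "cases": f"{case_count:.0f}",
            "controls": f"{control_count:.0f}",
            "or": "1.00" if hap == reference else "NA",
            "ci_low": "",
            "ci_high": "",
            "p": "",
        }
        for result in hap_results:
            if result.contrast.startswith(f"{hap}_vs_"):
                row.update(
                    {
                        "or": _fmt_or(result.or_point),
                        "ci_low": _fmt_or(result.ci_low),
                        "ci_high": _fmt_or(result.ci_high),
                        "p": _fmt_p(result.p_value),
                    }
                )
        hap_rows.append(row)
    _write_tsv(out_dir / "table4_haplotypes.tsv", hap_rows)
    ld_rows = []
    for i, sid_a in enumerate(snp_ids):
        for sid_b in snp_ids[i + 1:]:
            ld = haplotype.ld_pairwise(cohort, sid_a, sid_b, seed=config.seed)
            ld_rows.append(
                {
                    "snp_a": sid_a,
                    "snp_b": sid_b,
                    "d": f"{ld.d:.5f}" if ld.defined else "NA",
                    "d_prime": f"{ld.d_prime:.4f}" if ld.defined else "NA",
                    "r_squared": f"{ld.r_squared:.4f}" if ld.defined else "NA",
                }
            )
    _write_tsv(out_dir / "ld_pairwise.tsv", ld_rows)

    # ---- stratified -------------------------------------------------
    _stage("stratified")
    contrast_map = default_contrasts()
    contrasts = [
        GenotypeContrast(sid, *contrast_map[sid])
        for sid in snp_ids
        if sid in contrast_map
    ]
    strat = stratify.stratified_analysis(
        cohort,
        contrasts,
        covariates=config.covariates
        if _covariates_present(cohort, config.covariates)
        else None,
    )
    strat_rows = strat.to_dict("records")
    for row in strat_rows:
        for key in list(row):
            if key.startswith(("or_", "ci_")):
                row[key] = _fmt_or(row[key] if row[key] == row[key] else None)
            elif key.startswith("p_"):
                row[key] = _fmt_p(row[key] if row[key] == row[key] else None)
    _write_tsv(out_dir / "table3_stratified.tsv", strat_rows)

    # ---- credibility ------------------------------------------------
    _stage("credibility")
    significant = [
        r
        for r in crude_results + list(combined.results) + hap_results
        if r.defined and r.p_value is not None and r.p_value < config.alpha
    ]
    cred = credibility.credibility_table(
        significant,
        priors=config.priors,
        design_or_risk=config.design_or_risk,
        design_or_protective=config.design_or_protective,
        w_or=config.w_or,
        alpha=config.alpha,
    )
    cred_rows = []
    for result in cred:
        row = {
            "label": result.label,
            "snp_or_set": result.label,
            "or": _fmt_or(result.or_point),
            "ci_low": _fmt_or(result.ci_low),
            "ci_high": _fmt_or(result.ci_high),
            "p": _fmt_p(result.p_obs),
            "power": _fmt_p(result.power),
            "se_mode": result.se_mode,
        }
        for prior, f_val, b_val in zip(result.priors, result.fprp, result.bfdp):
            row[f"fprp_{prior}"] = _fmt_p(f_val)
            row[f"bfdp_{prior}"] = _fmt_p(b_val)
        cred_rows.append(row)
    _write_tsv(out_dir / "table5_credibility.tsv", cred_rows)

    # ---- summary ----------------------------------------------------
    summary = {
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "snps": snp_ids,
        "seed": config.seed,
        "qc": [
            {
                "snp_id": r.snp_id,
                "call_rate": round(r.call_rate, 6),
                "maf_controls": round(r.maf_controls, 6),
                "hwe_p_controls": round(r.hwe_p_controls, 6)
                if r.hwe_p_controls is not None
                else None,
                "pass": r.pass_all,
            }
            for r in qc_reports
        ],
        "single_locus": [
            {
                "snp_id": r.snp_id,
                "contrast": r.contrast,
                "or": round(r.or_point, 6) if r.defined else None,
                "p": round(r.p_value, 6) if r.defined and r.p_value is not None else None,
                "adjusted": r.adjusted,
            }
            for r in crude_results
        ],
        "combined_risk": {
            "labels": list(combined.labels),
            "cases": list(combined.counts_case),
            "controls": list(combined.counts_control),
            "p_trend": round(combined.trend.p_value, 6)
            if combined.trend.defined
            else None,
        },
        "haplotype": {
            "reference": reference,
            "haplotypes": list(estimate.haplotypes),
            "case_counts": [round(c, 3) for c in estimate.expected_counts["case"]],
            "control_counts": [round(c, 3) for c in estimate.expected_counts["control"]],
        },
        "n_significant": len(significant),
        "credibility": [
            {
                "label": r.label,
                "power": round(r.power, 6),
                "fprp": [round(v, 6) for v in r.fprp],
                "bfdp": [round(v, 6) for v in r.bfdp],
            }
            for r in cred
        ],
    }
    with (out_dir / "summary.json").open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _covariates_present(cohort: Cohort, covariates: Sequence[str]) -> bool:
    return all(
        any(getattr(s, c) is not None for s in cohort.subjects) for c in covariates
    )
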