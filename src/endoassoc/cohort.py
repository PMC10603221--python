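"""Domain types, genotype-table I/O and per-SNP quality control.

The central container is a :class:`Cohort`: an ordered list of biallelic
marker definitions (:class:`SnpDef`) plus a list of subjects, each carrying
case/control status, optional covariates (age, gravidity, parity, rASRM
stage for cases) and one unordered allele-pair call per marker.  Genotype
calls are normalised to alphabetically sorted pairs ("GA" == "AG") so that
counting is invariant to the order alleles appear in the input file.

Quality control follows the usual candidate-gene screening rules: per-SNP
call rate, minor-allele frequency in controls, and a Hardy-Weinberg
goodness-of-fit test in controls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GENOTYPE_CLASSES",
    "MISSING_CODES",
    "STAGES",
    "SchemaError",
    "ValidationError",
    "SnpDef",
    "Subject",
    "Cohort",
    "GenotypeCountTable",
    "QcReport",
    "read_cohort",
    "write_cohort",
    "read_vcf",
    "count_genotypes",
    "qc_snp",
    "drop_failing_snps",
]

#: Genotype classes in the conventional row order of association tables.
GENOTYPE_CLASSES = ("major_hom", "het", "minor_hom")

#: Tokens (lower-cased) interpreted as a missing genotype call.
MISSING_CODES = frozenset({"", "na", "n/a", "--", "./.", ".", "nan"})

STAGES = ("I", "II", "III", "IV")

_SEP_RE = re.compile(r"[/|]")


class SchemaError(ValueError):
    """A required column is absent or a column has an unusable layout."""


class ValidationError(ValueError):
    """A cell violates the declared marker or subject constraints."""


def _sorted_pair(a1: str, a2: str) -> str:
    return "".join(sorted((a1, a2)))


@dataclass(frozen=True)
class SnpDef:
    """A biallelic marker with a fixed major/minor orientation.

    The orientation is declared, never re-estimated from data, so genotype
    classes keep a stable meaning even in small subsamples.
    ``risk_genotypes`` is the (possibly empty) set of genotype labels this
    marker contributes to the combined risk-genotype count.
    """

    snp_id: str
    allele_major: str
    allele_minor: str
    risk_genotypes: frozenset = frozenset()

    def __post_init__(self) -> None:
        maj = self.allele_major.upper()
        mno = self.allele_minor.upper()
        if len(maj) != 1 or len(mno) != 1 or not maj.isalpha() or not mno.isalpha():
            raise ValidationError(f"{self.snp_id}: alleles must be single letters")
        if maj == mno:
            raise ValidationError(f"{self.snp_id}: major and minor allele are equal")
        object.__setattr__(self, "allele_major", maj)
        object.__setattr__(self, "allele_minor", mno)
        norm = frozenset(self._normalize_label(g) for g in self.risk_genotypes)
        object.__setattr__(self, "risk_genotypes", norm)

    # -- genotype labels ------------------------------------------------
    def _normalize_label(self, label: str) -> str:
        g = self.parse(label)
        if g is None:
            raise ValidationError(f"{self.snp_id}: bad genotype label {label!r}")
        return g

    @property
    def genotypes(self) -> tuple:
        """The three genotype labels in ``GENOTYPE_CLASSES`` order."""
        return (
            self.allele_major * 2,
            _sorted_pair(self.allele_major, self.allele_minor),
            self.allele_minor * 2,
        )

    def genotype_class(self, genotype: str) -> int:
        """Index of a normalised genotype in ``GENOTYPE_CLASSES``."""
        try:
            return self.genotypes.index(genotype)
        except ValueError:
            raise ValidationError(
                f"{self.snp_id}: genotype {genotype!r} does not use alleles "
                f"{self.allele_major}/{self.allele_minor}"
            ) from None

    def parse(self, cell: Optional[str], *, strict: bool = True) -> Optional[str]:
        """Normalise a raw genotype cell.

        Accepts adjacent-character ("AG"), slash ("A/G") and pipe ("A|G")
        dialects, case-insensitively.  Missing codes return ``None``.  A
        token that cannot be read as two alleles returns ``None`` as well
        (it is treated as a failed call); a well-formed pair using an
        undeclared allele raises :class:`ValidationError` unless
        ``strict=False``.
        """
        if cell is None:
            return None
        token = str(cell).strip()
        if token.lower() in MISSING_CODES:
            return None
        token = _SEP_RE.sub("", token).upper()
        if len(token) != 2 or not token.isalpha():
            return None
        valid = {self.allele_major, self.allele_minor}
        if not set(token) <= valid:
            if strict:
                raise ValidationError(
                    f"{self.snp_id}: allele outside declared pair in call {cell!r}"
                )
            return None
        return _sorted_pair(token[0], token[1])


@dataclass
class Subject:
    """One study participant with status, covariates and genotype calls."""

    subject_id: str
    status: str  # "case" | "control"
    age: Optional[float] = None
    gravidity: Optional[int] = None
    parity: Optional[int] = None
    rasrm_stage: Optional[str] = None
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"{self.subject_id}: bad status {self.status!r}")
        if self.status == "control" and self.rasrm_stage is not None:
            raise ValidationError(f"{self.subject_id}: controls carry no rASRM stage")
        if self.rasrm_stage is not None and self.rasrm_stage not in STAGES:
            raise ValidationError(
                f"{self.subject_id}: bad rASRM stage {self.rasrm_stage!r}"
            )
        for name, value in (("gravidity", self.gravidity), ("parity", self.parity)):
            if value is not None and value < 0:
                raise ValidationError(f"{self.subject_id}: negative {name}")


@dataclass
class Cohort:
    """An ordered marker panel plus subjects; the unit every stage consumes."""

    snps: list
    subjects: list

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp_id in panel")
        sids = [s.subject_id for s in self.subjects]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate subject_id in cohort")
        by_id = {s.snp_id: s for s in self.snps}
        for subj in self.subjects:
            for snp_id, call in list(subj.genotypes.items()):
                if snp_id not in by_id:
                    raise ValidationError(
                        f"{subj.subject_id}: call for undeclared marker {snp_id}"
                    )
                if call is not None:
                    # normalise allele order and validate against the panel
                    subj.genotypes[snp_id] = by_id[snp_id]._normalize_label(call)

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"unknown snp_id {snp_id!r}")

    def group(self, status: str) -> list:
        return [s for s in self.subjects if s.status == status]

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.subjects if s.status == "case")

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.subjects if s.status == "control")


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control-by-genotype counts for one SNP.

    ``counts_case`` / ``counts_control`` follow ``GENOTYPE_CLASSES`` order
    (major-hom, het, minor-hom).  This 2x3 table is the sufficient statistic
    for every crude single-locus result.
    """

    snp_id: str
    counts_case: tuple
    counts_control: tuple
    missing_case: int = 0
    missing_control: int = 0

    def __post_init__(self) -> None:
        for row in (self.counts_case, self.counts_control):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValidationError(f"{self.snp_id}: bad genotype counts {row}")
        if self.missing_case < 0 or self.missing_control < 0:
            raise ValidationError(f"{self.snp_id}: negative missing counts")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([self.counts_case, self.counts_control], dtype=float)

    def counts(self, status: str) -> tuple:
        return self.counts_case if status == "case" else self.counts_control

    def allele_counts(self, status: str) -> tuple:
        """(major, minor) allele counts in one group."""
        hom_maj, het, hom_min = self.counts(status)
        return (2 * hom_maj + het, 2 * hom_min + het)

    def maf(self, status: str) -> float:
        major, minor = self.allele_counts(status)
        total = major + minor
        if total == 0:
            raise ValidationError(f"{self.snp_id}: no {status} genotypes, MAF undefined")
        return minor / total

    @property
    def call_rate(self) -> float:
        called = sum(self.counts_case) + sum(self.counts_control)
        total = called + self.missing_case + self.missing_control
        return called / total if total else 0.0


@dataclass(frozen=True)
class QcReport:
    snp_id: str
    call_rate: float
    maf_controls: float
    hwe_p_controls: Optional[float]
    pass_call_rate: bool
    pass_maf: bool
    pass_hwe: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_call_rate and self.pass_maf and self.pass_hwe


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "status": "status",
    "age": "age",
    "gravidity": "gravidity",
    "parity": "parity",
    "rasrm_stage": "rasrm_stage",
}

_STATUS_MAP = {"case": "case", "1": "case", "control": "control", "0": "control"}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_cohort(
    path,
    snps: Sequence[SnpDef],
    schema: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a subject-level genotype TSV into a :class:`Cohort`.

    ``schema`` maps canonical column names (``subject_id``, ``status``,
    ``age``, ``gravidity``, ``parity``, ``rasrm_stage``) to the file's
    column names; SNP columns are located by ``snp_id``.  Unparseable
    genotype cells become missing calls; an allele outside a marker's
    declared pair raises :class:`ValidationError`.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index = {name: i for i, name in enumerate(header)}
        for canonical in ("subject_id", "status"):
            if colmap[canonical] not in index:
                raise SchemaError(f"missing required column {colmap[canonical]!r}")
        for snp in snps:
            if snp.snp_id not in index:
                raise SchemaError(f"missing SNP column {snp.snp_id!r}")
        subjects = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")

            def cell(column: str) -> str:
                i = index.get(column)
                return row[i].strip() if i is not None and i < len(row) else ""

            raw_status = cell(colmap["status"]).lower()
            if raw_status not in _STATUS_MAP:
                raise ValidationError(
                    f"line {lineno}: unrecognised status {raw_status!r}"
                )
            age = cell(colmap["age"])
            grav = cell(colmap["gravidity"])
            par = cell(colmap["parity"])
            stage = cell(colmap["rasrm_stage"])
            genotypes = {}
            for snp in snps:
                raw = cell(snp.snp_id)
                try:
                    genotypes[snp.snp_id] = snp.parse(raw)
                except ValidationError as err:
                    raise ValidationError(
                        f"subject {cell(colmap['subject_id'])!r}: {err}"
                    ) from None
            subjects.append(
                Subject(
                    subject_id=cell(colmap["subject_id"]),
                    status=_STATUS_MAP[raw_status],
                    age=float(age) if age else None,
                    gravidity=int(grav) if grav else None,
                    parity=int(par) if par else None,
                    rasrm_stage=stage or None,
                    genotypes=genotypes,
                )
            )
    return Cohort(snps=list(snps), subjects=subjects)


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort as TSV with a deterministic column order."""
    path = Path(path)
    snp_ids = [s.snp_id for s in cohort.snps]
    columns = ["subject_id", "status", "age", "gravidity", "parity", "rasrm_stage"]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns + snp_ids) + "\n")
        for subj in cohort.subjects:
            row = [
                subj.subject_id,
                subj.status,
                _fmt(subj.age),
                _fmt(subj.gravidity),
                _fmt(subj.parity),
                _fmt(subj.rasrm_stage),
            ]
            row += [_fmt(subj.genotypes.get(sid)) for sid in snp_ids]
            fh.write("\t".join(row) + "\n")
    return path


def read_vcf(path, status_by_sample: Mapping[str, str], snps: Optional[Sequence[SnpDef]] = None) -> Cohort:
    """Import diploid biallelic SNV records from a VCF (v4.x).

    ``status_by_sample`` maps VCF sample names to ``case``/``control``.
    Multi-allelic records are rejected.  Marker orientation follows
    ``snps`` when given, else REF is taken as the major allele.
    """
    from cyvcf2 import VCF  # optional dependency

    declared = {s.snp_id: s for s in snps} if snps else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in status_by_sample]
    if unknown:
        raise SchemaError(f"samples without case/control status: {unknown}")
    panel: list = []
    calls: dict = {s: {} for s in samples}
    for record in vcf:
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            raise ValidationError(
                f"{record.ID or record.POS}: only biallelic SNVs are supported"
            )
        snp_id = record.ID or f"{record.CHROM}:{record.POS}"
        if declared is not None:
            if snp_id not in declared:
                continue
            snp = declared[snp_id]
        else:
            snp = SnpDef(snp_id, record.REF, record.ALT[0])
        panel.append(snp)
        alleles = (record.REF.upper(), record.ALT[0].upper())
        for sample, gt in zip(samples, record.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                calls[sample][snp_id] = None
            else:
                calls[sample][snp_id] = _sorted_pair(alleles[a], alleles[b])
    subjects = [
        Subject(subject_id=s, status=status_by_sample[s], genotypes=calls[s])
        for s in samples
    ]
    return Cohort(snps=panel, subjects=subjects)


# ---------------------------------------------------------------------------
# Counting and QC
# ---------------------------------------------------------------------------


def count_genotypes(cohort: Cohort, snp_id: str) -> GenotypeCountTable:
    """Tally the 2x3 case/control-by-genotype table for one marker.

    Missing calls are excluded from the counts and tallied per group in
    the ``missing_*`` fields.
    """
    snp = cohort.snp(snp_id)
    counts = {"case": [0, 0, 0], "control": [0, 0, 0]}
    missing = {"case": 0, "control": 0}
    for subj in cohort.subjects:
        call = subj.genotypes.get(snp_id)
        if call is None:
            missing[subj.status] += 1
        else:
            counts[subj.status][snp.genotype_class(call)] += 1
    return GenotypeCountTable(
        snp_id=snp_id,
        counts_case=tuple(counts["case"]),
        counts_control=tuple(counts["control"]),
        missing_case=missing["case"],
        missing_control=missing["control"],
    )


def qc_snp(
    table: GenotypeCountTable,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    min_hwe_p: float = 0.001,
) -> QcReport:
    """Screen one marker on call rate, control MAF and control HWE.

    QC is reported, not applied; use :func:`drop_failing_snps` to remove
    failing markers from a cohort.
    """
    for name, value in (
        ("min_call_rate", min_call_rate),
        ("min_maf", min_maf),
        ("min_hwe_p", min_hwe_p),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if sum(table.counts_control) == 0:
        raise ValidationError(f"{table.snp_id}: no control genotypes, MAF undefined")
    from .assoc import hwe_chi2  # local import to avoid a module cycle

    maf = table.maf("control")
    hwe = hwe_chi2(table.counts_control)
    call_rate = table.call_rate
    return QcReport(
        snp_id=table.snp_id,
        call_rate=call_rate,
        maf_controls=maf,
        hwe_p_controls=hwe.p_value if hwe.defined else None,
        pass_call_rate=call_rate >= min_call_rate,
        pass_maf=maf >= min_maf,
        pass_hwe=(hwe.defined and hwe.p_value >= min_hwe_p),
    )


def drop_failing_snps(cohort: Cohort, reports: Iterable[QcReport]) -> Cohort:
    """Return a cohort restricted to markers whose QC report passed."""
    failed = {r.snp_id for r in reports if not r.pass_all}
    kept = [s for s in cohort.snps if s.snp_id not in failed]
    subjects = [
        replace(
            subj,
            genotypes={k: v for k, v in subj.genotypes.items() if k not in failed},
        )
        for subj in cohort.subjects
    ]
    return Cohort(snps=kept, subjects=subjects)
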