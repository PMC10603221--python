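"""Published aggregate counts from the ovarian-endometriosis study.

These are data, not computed quantities: the genotype, stratum and
haplotype counts, and the significant-association summary rows, exactly
as printed in the source study of 473 ovarian-endometriosis cases and
459 healthy controls genotyped at three *WTAP* SNPs (rs1853259 A>G,
rs7766006 G>T, rs9457712 G>A).  They anchor regression tests and the
desk-scale reproduction of every crude (unadjusted) result.

Access is through :func:`fixture_counts`, keyed by table-derived names
such as ``"table2_rs1853259"`` or ``"table3_rasrm234_rs7766006"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import Cohort, GenotypeCountTable, SnpDef, Subject

__all__ = [
    "FixtureLookupError",
    "StratumCounts",
    "RiskCategoryCounts",
    "HaplotypeCounts",
    "SignificantRow",
    "default_snps",
    "default_contrasts",
    "fixture_counts",
    "fixture_names",
    "cohort_from_tables",
]


class FixtureLookupError(KeyError):
    """Unknown fixture name; the message lists the available identifiers."""


@dataclass(frozen=True)
class StratumCounts:
    """A collapsed 2x2 stratum: exposed/reference cases and controls."""

    variable: str
    stratum: str
    snp_id: str
    exposed: str  # label of the exposed genotype class, e.g. "AG/GG"
    reference: str
    exposed_cases: int
    ref_cases: int
    exposed_controls: int
    ref_controls: int

    @property
    def abcd(self) -> tuple:
        return (
            self.exposed_cases,
            self.ref_cases,
            self.exposed_controls,
            self.ref_controls,
        )


@dataclass(frozen=True)
class RiskCategoryCounts:
    labels: tuple
    cases: tuple
    controls: tuple


@dataclass(frozen=True)
class HaplotypeCounts:
    snp_order: tuple
    haplotypes: tuple
    cases: tuple
    controls: tuple


@dataclass(frozen=True)
class SignificantRow:
    """One row of the published credibility table (printed inputs only)."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: Optional[tuple] = None  # (a, b, c, d) when recoverable
    printed_power: Optional[float] = None
    printed_fprp: Optional[tuple] = None  # at priors 0.25, 0.1, 0.01
    printed_bfdp: Optional[tuple] = None


def default_snps() -> list:
    """The three-marker panel with its published risk-genotype sets."""
    return [
        SnpDef("rs1853259", "A", "G", risk_genotypes=frozenset({"AG", "GG"})),
        SnpDef("rs7766006", "G", "T", risk_genotypes=frozenset({"GG"})),
        SnpDef("rs9457712", "G", "A", risk_genotypes=frozenset({"AA"})),
    ]


def default_contrasts() -> dict:
    """Stratification contrast per SNP: exposed classes vs reference classes."""
    return {
        "rs1853259": (("AG", "GG"), ("AA",)),
        "rs7766006": (("GG",), ("GT", "TT")),
        "rs9457712": (("AA",), ("GG", "GA")),
    }


_TABLE2 = {
    "table2_rs1853259": GenotypeCountTable(
        "rs1853259", counts_case=(153, 235, 85), counts_control=(181, 216, 62)
    ),
    "table2_rs7766006": GenotypeCountTable(
        "rs7766006", counts_case=(175, 220, 78), counts_control=(132, 233, 94)
    ),
    "table2_rs9457712": GenotypeCountTable(
        "rs9457712", counts_case=(333, 120, 20), counts_control=(316, 130, 13)
    ),
}

_TABLE2_COMBINED = RiskCategoryCounts(
    labels=("0", "1", "2+"), cases=(132, 167, 174), controls=(167, 161, 131)
)

# variable, stratum key, stratum label, then per SNP:
# (exposed cases, ref cases, exposed controls, ref controls)
_TABLE3_RAW = [
    ("age", "le30", "<=30",
     (184, 69, 223, 107), (74, 138, 65, 184), (8, 204, 7, 242)),
    ("age", "31to40", "31-40",
     (163, 65, 132, 61), (82, 125, 52, 110), (10, 197, 6, 156)),
    ("age", "gt40", ">40",
     (41, 19, 42, 13), (19, 35, 15, 33), (2, 52, 0, 48)),
    ("gravidity", "le1", "<=1",
     (313, 152, 256, 168), (171, 294, 122, 302), (20, 455, 13, 411)),
    ("gravidity", "gt1", ">1",
     (7, 1, 22, 13), (4, 4, 10, 25), (0, 8, 0, 35)),
    ("parity", "le1", "<=1",
     (293, 137, 245, 157), (157, 273, 114, 288), (19, 411, 11, 391)),
    ("parity", "gt1", ">1",
     (27, 16, 33, 24), (18, 25, 18, 39), (1, 42, 2, 55)),
    ("rasrm", "1", "I",
     (239, 110, 278, 181), (125, 224, 132, 327), (12, 337, 13, 446)),
    ("rasrm", "234", "II+III+IV",
     (81, 43, 278, 181), (50, 74, 132, 327), (8, 116, 13, 446)),
]

_CONTRAST_LABELS = {
    "rs1853259": ("AG/GG", "AA"),
    "rs7766006": ("GG", "GT/TT"),
    "rs9457712": ("AA", "GG+GA"),
}


def _table3() -> dict:
    entries = {}
    for variable, key, label, *per_snp in _TABLE3_RAW:
        for snp_id, abcd in zip(("rs1853259", "rs7766006", "rs9457712"), per_snp):
            exposed, reference = _CONTRAST_LABELS[snp_id]
            entries[f"table3_{variable}{key}_{snp_id}"] = StratumCounts(
                variable=variable,
                stratum=label,
                snp_id=snp_id,
                exposed=exposed,
                reference=reference,
                exposed_cases=abcd[0],
                ref_cases=abcd[1],
                exposed_controls=abcd[2],
                ref_controls=abcd[3],
            )
    return entries


_TABLE4 = HaplotypeCounts(
    snp_order=("rs1853259", "rs7766006", "rs9457712"),
    haplotypes=("AGG", "AGA", "ATG", "ATA", "GGG", "GGA", "GTG", "GTA"),
    cases=(286, 45, 157, 53, 173, 66, 166, 0),
    controls=(290, 27, 189, 72, 123, 57, 160, 0),
)

# The 17 published significant associations with their printed crude
# inputs and printed power/FPRP/BFDP (priors 0.25, 0.1, 0.01).
_TABLE5 = (
    SignificantRow("rs1853259 AG vs AA", 1.29, 0.97, 1.71, 0.081,
                   counts=(235, 153, 216, 181), printed_power=0.851,
                   printed_fprp=(0.222, 0.461, 0.904),
                   printed_bfdp=(0.646, 0.846, 0.984)),
    SignificantRow("rs1853259 GG vs AA", 1.62, 1.10, 2.40, 0.016,
                   counts=(85, 153, 62, 181), printed_power=0.349,
                   printed_fprp=(0.121, 0.292, 0.819),
                   printed_bfdp=(0.492, 0.744, 0.970)),
    SignificantRow("rs1853259 dominant", 1.36, 1.04, 1.78, 0.024,
                   counts=(320, 153, 278, 181), printed_power=0.753,
                   printed_fprp=(0.087, 0.223, 0.759),
                   printed_bfdp=(0.488, 0.741, 0.969)),
    SignificantRow("rs1853259 AG/GG vs AA, age <=30", 1.56, 1.07, 2.29, 0.022,
                   printed_power=0.785,
                   printed_fprp=(0.078, 0.201, 0.735),
                   printed_bfdp=(0.528, 0.771, 0.974)),
    SignificantRow("rs1853259 AG/GG vs AA, gravidity <=1", 1.37, 1.03, 1.83, 0.031,
                   printed_power=0.763,
                   printed_fprp=(0.109, 0.268, 0.801),
                   printed_bfdp=(0.534, 0.775, 0.974)),
    SignificantRow("rs1853259 AG/GG vs AA, parity <=1", 1.37, 1.03, 1.82, 0.030,
                   printed_power=0.726,
                   printed_fprp=(0.110, 0.271, 0.804),
                   printed_bfdp=(0.518, 0.763, 0.973)),
    SignificantRow("rs1853259 AG/GG vs AA, rASRM I", 1.42, 1.06, 1.90, 0.020,
                   printed_power=0.647,
                   printed_fprp=(0.085, 0.218, 0.754),
                   printed_bfdp=(0.450, 0.711, 0.964)),
    SignificantRow("rs7766006 GT vs GG", 0.71, 0.53, 0.95, 0.023,
                   counts=(220, 175, 233, 132), printed_power=0.666,
                   printed_fprp=(0.094, 0.237, 0.774),
                   printed_bfdp=(0.471, 0.728, 0.967)),
    SignificantRow("rs7766006 TT vs GG", 0.63, 0.43, 0.91, 0.015,
                   counts=(78, 175, 94, 132), printed_power=0.372,
                   printed_fprp=(0.108, 0.266, 0.800),
                   printed_bfdp=(0.458, 0.717, 0.965)),
    SignificantRow("rs7766006 dominant", 0.69, 0.52, 0.90, 0.008,
                   counts=(298, 175, 327, 132), printed_power=0.584,
                   printed_fprp=(0.039, 0.110, 0.575),
                   printed_bfdp=(0.285, 0.544, 0.929)),
    SignificantRow("rs7766006 GG vs GT/TT, age <=30", 1.52, 1.02, 2.26, 0.041,
                   counts=(74, 138, 65, 184), printed_power=0.479,
                   printed_fprp=(0.204, 0.435, 0.894),
                   printed_bfdp=(0.590, 0.812, 0.979)),
    SignificantRow("rs7766006 GG vs GT/TT, gravidity <=1", 1.41, 1.05, 1.90, 0.022,
                   printed_power=0.706,
                   printed_fprp=(0.086, 0.219, 0.755),
                   printed_bfdp=(0.492, 0.744, 0.970)),
    SignificantRow("rs7766006 GG vs GT/TT, parity <=1", 1.45, 1.08, 1.95, 0.012,
                   counts=(157, 273, 114, 288), printed_power=0.586,
                   printed_fprp=(0.058, 0.156, 0.670),
                   printed_bfdp=(0.415, 0.680, 0.959)),
    SignificantRow("rs7766006 GG vs GT/TT, rASRM I", 1.38, 1.03, 1.86, 0.033,
                   counts=(125, 224, 132, 327), printed_power=0.711,
                   printed_fprp=(0.122, 0.295, 0.821),
                   printed_bfdp=(0.543, 0.781, 0.975)),
    SignificantRow("rs7766006 GG vs GT/TT, rASRM II+III+IV", 1.67, 1.10, 2.53, 0.014,
                   counts=(50, 74, 132, 327), printed_power=0.302,
                   printed_fprp=(0.122, 0.294, 0.821),
                   printed_bfdp=(0.501, 0.751, 0.971)),
    SignificantRow("combined risk genotypes 2 vs 0", 1.68, 1.22, 2.32, 0.002,
                   counts=(174, 132, 131, 167), printed_power=0.270,
                   printed_fprp=(0.022, 0.062, 0.423),
                   printed_bfdp=(0.188, 0.409, 0.884)),
    SignificantRow("haplotype GGG vs AGG", 1.43, 1.08, 1.89, 0.014,
                   counts=(173, 286, 123, 290), printed_power=0.643,
                   printed_fprp=(0.061, 0.164, 0.683),
                   printed_bfdp=(0.383, 0.650, 0.953)),
)

# Table 1 summaries: (cases <=cut, cases >cut, controls <=cut, controls >cut)
_TABLE1 = {
    "table1_age_summary": {
        "case_mean": 31.97, "case_sd": 6.06, "case_n": 473,
        "control_mean": 31.14, "control_sd": 7.07, "control_n": 459,
    },
    "table1_age_bins": ((328, 145), (353, 106)),  # <35 / >=35
    "table1_gravidity": ((423, 50), (391, 68)),  # <=1 / >1
    "table1_parity": ((430, 43), (402, 57)),
    "table1_stage": {"I": 349, "II": 104, "III": 15, "IV": 5},
}

_REGISTRY: dict = {}
_REGISTRY.update(_TABLE2)
_REGISTRY["table2_combined"] = _TABLE2_COMBINED
_REGISTRY.update(_table3())
_REGISTRY["table4_haplotypes"] = _TABLE4
_REGISTRY["table5_rows"] = _TABLE5
_REGISTRY.update(_TABLE1)


def fixture_names() -> tuple:
    return tuple(sorted(_REGISTRY))


def fixture_counts(name: str):
    """Return a published aggregate table as a machine-readable structure."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None


def cohort_from_tables() -> Cohort:
    """Deterministic subject-level cohort whose per-SNP genotype tallies
    equal the published 2x3 tables.

    Genotypes are assigned marker-by-marker in a fixed order, so
    single-locus counts are exact; multilocus phase structure is
    arbitrary and carries no information.  Covariates are left unset.
    """
    snps = default_snps()
    tables = [fixture_counts(f"table2_{s.snp_id}") for s in snps]
    subjects = []
    for status, n_group in (("case", 473), ("control", 459)):
        assignments = []
        for snp, table in zip(snps, tables):
            calls = []
            for cls, count in enumerate(table.counts(status)):
                calls.extend([snp.genotypes[cls]] * count)
            calls.extend([None] * (n_group - len(calls)))
            assignments.append(calls)
        for i in range(n_group):
            subjects.append(
                Subject(
                    subject_id=f"{'C' if status == 'case' else 'N'}{i + 1:04d}",
                    status=status,
                    genotypes={
                        snp.snp_id: assignments[k][i] for k, snp in enumerate(snps)
                    },
                )
            )
    return Cohort(snps=snps, subjects=subjects)
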