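import pytest

from endoassoc.cohort import Cohort, SnpDef, Subject
from endoassoc.fixtures import default_snps, fixture_counts


@pytest.fixture(scope="session")
def panel():
    return default_snps()


@pytest.fixture(scope="session")
def table2():
    return {
        sid: fixture_counts(f"table2_{sid}")
        for sid in ("rs1853259", "rs7766006", "rs9457712")
    }


@pytest.fixture
def tiny_cohort(panel):
    """Four hand-built subjects covering genotype dialects and missingness."""
    subjects = [
        Subject("s1", "case", age=30.0, gravidity=1, parity=0, rasrm_stage="I",
                genotypes={"rs1853259": "AG", "rs7766006": "GG", "rs9457712": "GA"}),
        Subject("s2", "case", age=35.5, gravidity=0, parity=0, rasrm_stage="II",
                genotypes={"rs1853259": "GG", "rs7766006": None, "rs9457712": "AA"}),
        Subject("s3", "control", age=28.0, gravidity=2, parity=1,
                genotypes={"rs1853259": "AA", "rs7766006": "GT", "rs9457712": "GG"}),
        Subject("s4", "control", age=None, gravidity=None, parity=None,
                genotypes={"rs1853259": "AG", "rs7766006": "TT", "rs9457712": None}),
    ]
    return Cohort(snps=panel, subjects=subjects)
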