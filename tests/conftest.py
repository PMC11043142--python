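import numpy as np
import pytest

from varburden.datamodel import PopFrequency, VariantRecord, single_interval_gene
from varburden.io import load_fmd_cohort_fixture


@pytest.fixture(scope="session")
def fmd_cohort():
    """The 13 published rare missense variants of the familial MD cohort."""
    return load_fmd_cohort_fixture()


@pytest.fixture(scope="session")
def otog_gene():
    return single_interval_gene("OTOG", 8778, contig="NC_000011.10",
                                start=17_000_000)


def make_variant(pos=100, cds_pos=None, consequence="missense",
                 cohort=None, **pops):
    """Terse variant builder: pops as code=(ac, an) or code=af."""
    per_pop = {}
    for code, value in pops.items():
        if isinstance(value, tuple):
            per_pop[code] = PopFrequency(an=value[1], ac=value[0])
        else:
            per_pop[code] = PopFrequency(an=113_770, af=float(value))
    cohort_ac, cohort_an = cohort if cohort else (None, None)
    return VariantRecord(
        contig="chr1", pos=pos, ref="A", alt="G", per_pop=per_pop,
        consequence=consequence, cds_pos=cds_pos,
        cohort_ac=cohort_ac, cohort_an=cohort_an,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
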