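import numpy as np
import pytest

from cytomr.instruments import InstrumentSet, variance_explained
from cytomr.summary_io import LDTable, SummaryStatRecord, SummaryStatSet


def make_record(
    variant_id: str,
    ea: str = "A",
    oa: str = "G",
    eaf: float = 0.3,
    beta: float = 0.1,
    se: float = 0.01,
    pvalue: float = 1e-9,
    chromosome: str = "1",
    position: int = 1000,
    n: float | None = None,
) -> SummaryStatRecord:
    return SummaryStatRecord(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_set(records, trait_name="trait", trait_type="continuous") -> SummaryStatSet:
    s = SummaryStatSet(trait_name, trait_type)
    for r in records:
        s.add(r)
    return s


def instrument_set_from_records(records, biomarker="trait") -> InstrumentSet:
    inst = InstrumentSet(biomarker)
    for r in records:
        inst.index_snps.append(r)
        inst.per_snp_variance[r.variant_id] = variance_explained(r.beta, r.eaf)
    return inst


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def ld_empty():
    return LDTable()
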