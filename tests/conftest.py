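import numpy as np
import pytest

from mr2s.instruments import HarmonizedInstrument, KEPT
from mr2s.summary_io import GwasTable, SnpAssociation


def make_assoc(
    rsid="rs1",
    chromosome="1",
    position=1000,
    ea="A",
    nea="G",
    eaf=0.3,
    beta=0.05,
    se=0.01,
    pvalue=1e-9,
) -> SnpAssociation:
    return SnpAssociation(
        rsid=rsid,
        chromosome=chromosome,
        position=position,
        effect_allele=ea,
        other_allele=nea,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
    )


def make_table(records, name="trait", **meta) -> GwasTable:
    return GwasTable(trait_name=name, records=list(records), **meta)


def make_inst(
    rsid="rs1", gamma=0.1, se_gamma=0.01, Gamma=0.05, se_Gamma=0.01,
    eaf_exposure=0.3, eaf_outcome=0.3, action=KEPT,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=rsid, gamma=gamma, se_gamma=se_gamma, Gamma=Gamma, se_Gamma=se_Gamma,
        eaf_exposure=eaf_exposure, eaf_outcome=eaf_outcome, action=action,
    )


def random_instruments(rng: np.random.Generator, J: int, beta=0.2):
    """Well-behaved random instrument sets for oracle/property tests."""
    gamma = rng.uniform(0.05, 0.5, J) * rng.choice([-1, 1], J)
    se_gamma = rng.uniform(0.005, 0.02, J)
    se_Gamma = rng.uniform(0.005, 0.05, J)
    Gamma = beta * gamma + rng.normal(0, se_Gamma)
    return [
        make_inst(
            rsid=f"rs{j}", gamma=gamma[j], se_gamma=se_gamma[j],
            Gamma=Gamma[j], se_Gamma=se_Gamma[j],
        )
        for j in range(J)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def table1_frame():
    from mr2s.datasets import load_instruments_frame

    return load_instruments_frame()
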