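import numpy as np
import pytest

from targetmr.types import AssociationRecord, CorrelationMatrix, HarmonizedInstrument


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.05,
    se=0.01,
    eaf=0.3,
    pval=None,
    n=100_000,
    scale="sd",
    **kwargs,
):
    return AssociationRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        eaf=eaf,
        pval=pval,
        n=n,
        scale=scale,
        **kwargs,
    ).validate()


def make_instrument(
    snp_id="rs1",
    beta_exposure=0.07,
    se_exposure=0.005,
    beta_outcome=0.02,
    se_outcome=0.02,
    **kwargs,
):
    return HarmonizedInstrument(
        snp_id=snp_id,
        effect_allele=kwargs.pop("effect_allele", "A"),
        other_allele=kwargs.pop("other_allele", "G"),
        beta_exposure=beta_exposure,
        se_exposure=se_exposure,
        beta_outcome=beta_outcome,
        se_outcome=se_outcome,
        **kwargs,
    ).validate()


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def instrument_factory():
    return make_instrument


@pytest.fixture
def identity_corr():
    def _make(snp_ids):
        return CorrelationMatrix(list(snp_ids), np.eye(len(snp_ids)))

    return _make
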