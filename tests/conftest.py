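import numpy as np
import pandas as pd
import pytest

from clonaldyn.clone_genomics import BiopsySample
from clonaldyn.params import SPParams, PUBLISHED_PARAMS


@pytest.fixture(scope="session")
def row1() -> SPParams:
    return PUBLISHED_PARAMS[0]


@pytest.fixture(scope="session")
def row2() -> SPParams:
    return PUBLISHED_PARAMS[1]


@pytest.fixture(scope="session")
def neutral() -> SPParams:
    return SPParams(r=0.1, division_rate=1.9, stratification_rate=3.5, delta=0.0)


def make_sample(sample_id, row, col, muts, area=2.0):
    """muts: list of (chrom, pos, ref, alt, vaf[, gene[, consequence]])."""
    recs = []
    for m in muts:
        chrom, pos, ref, alt, vaf = m[:5]
        gene = m[5] if len(m) > 5 else "GENE"
        cons = m[6] if len(m) > 6 else "missense"
        recs.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "vaf": vaf, "gene": gene, "consequence": cons}
        )
    df = pd.DataFrame(
        recs, columns=["chrom", "pos", "ref", "alt", "vaf", "gene", "consequence"]
    )
    return BiopsySample(sample_id, row, col, area=area, mutations=df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
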