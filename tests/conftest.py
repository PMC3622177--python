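import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from moderseq.io_formats import AlignmentRecord, ExpressionMatrix, GeneModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def two_gene_models() -> list[GeneModel]:
    return [
        GeneModel("gA", "chr1", "+", ((0, 1000),)),
        GeneModel("gB", "chr1", "+", ((100_000, 101_000),)),
    ]


@pytest.fixture
def toy_multiread_setup(two_gene_models):
    """600/200 unique reads on two 1-kb genes plus 200 shared multireads."""
    records, i = [], 0
    for n, gid, offset in ((600, "gA", 0), (200, "gB", 100_000)):
        for _ in range(n):
            i += 1
            records.append(AlignmentRecord(f"u{i}", "chr1", offset + 10, offset + 60,
                                           "unique", (gid,)))
    for _ in range(200):
        i += 1
        records.append(AlignmentRecord(f"m{i}", "chr1", 10, 60, "multi", ("gA", "gB")))
    return two_gene_models, records


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(200)]
    samples = ["wt_1", "wt_2", "mut_1", "mut_2"]
    counts = rng.poisson(200, size=(200, 4)).astype(float)
    lengths = np.full(200, 1000.0)
    totals = counts.sum(axis=0)
    rpkm = counts * 1e9 / (lengths[:, None] * totals[None, :])
    design = pd.Series(["cond1", "cond1", "cond2", "cond2"], index=samples)
    return ExpressionMatrix(pd.DataFrame(rpkm, index=genes, columns=samples),
                            pd.DataFrame(counts, index=genes, columns=samples),
                            design,
                            pd.Series(totals.astype(int), index=samples))
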