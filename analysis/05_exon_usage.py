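#!/usr/bin/env python
"""Exon-level differential-usage screen on simulated per-exon counts.

Simulates 500 four-exon genes at 1,000 reads/gene with 5% of genes shifting
one exon's usage by 0.4 in the second condition, then runs the
exon-vs-rest Fisher's exact screen with genome-wide BH adjustment and
reports recovery of the shifted exons.
"""

from pathlib import Path

import pandas as pd

from moderseq.exon_splicing import test_exon_usage
from moderseq.io_formats import write_results_table
from moderseq.synthetic_data import simulate_exon_reads

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    models, table, truth = simulate_exon_reads(
        n_genes=500, exons_per_gene=4, depth=1000,
        differential_exon_fraction=0.05, usage_shift=0.4, seed=SEED)
    design = pd.Series(["cond1", "cond1", "cond2", "cond2"], index=table.columns)
    res = test_exon_usage(table, design)
    write_results_table(res, OUT / "exon_usage.tsv")

    hits = res[res["q"] < 0.05]
    diff_genes = set(truth.loc[truth["is_differential"], "gene_id"])
    shifted = set(zip(truth.loc[truth["is_differential"], "gene_id"],
                      truth.loc[truth["is_differential"], "shifted_exon"]))
    recovered = sum((g, e) in shifted for g, e in zip(hits["gene_id"],
                                                     hits["exon_index"]))
    in_diff_genes = hits["gene_id"].isin(diff_genes).sum()
    print(f"tested exons: {len(res)}; q<0.05: {len(hits)} "
          f"({in_diff_genes} in usage-shifted genes — shifting one exon also "
          "rescales its siblings — and "
          f"{len(hits) - in_diff_genes} in null genes)")
    print(f"simulated shifted exons: {len(shifted)}; recovered at q<0.05: {recovered}")


if __name__ == "__main__":
    main()
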