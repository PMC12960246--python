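"""Programmatic read-metric fixture: 77 RNA-seq samples of which 33 fail
one of the two read-level quality rules (low totals or dominant
ambiguous/no-feature counts), leaving 44."""

import numpy as np
import pandas as pd


def qc_metrics_fixture() -> pd.DataFrame:
    rng = np.random.default_rng(440)
    rows = []
    for i in range(77):
        sid = f"RNA{i:02d}"
        if i < 18:      # below the 25M total-read floor
            total = rng.uniform(5e6, 24.9e6)
            rows.append((sid, total, total * 0.05, total * 0.05,
                         total * 0.8))
        elif i < 33:    # ambiguous + no-feature exceed the gene counts
            total = rng.uniform(26e6, 60e6)
            gene = total * 0.3
            rows.append((sid, total, gene * 0.7, gene * 0.7, gene))
        else:
            total = rng.uniform(25e6, 80e6)
            rows.append((sid, total, total * 0.04, total * 0.06,
                         total * 0.8))
    return pd.DataFrame(rows, columns=[
        "sample", "total_reads", "ambiguous_reads", "no_feature_reads",
        "gene_reads"])
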