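#!/usr/bin/env python
"""TMM-normalize the reference dataset and check between-sample agreement.

Writes factors.tsv, normalized.tsv (log2 CPM) and the sample x sample Spearman
correlation matrix. On well-behaved data the off-diagonal correlations within
a condition should be high and the TMM factors close to 1.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mechanoseq import log2_cpm, sample_spearman, tmm_factors
from mechanoseq.io import read_counts, write_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    counts = read_counts(args.out_dir / "counts.tsv")
    factors = tmm_factors(counts)
    write_table(pd.DataFrame({
        "sample_id": factors.factors.index,
        "lib_size": factors.library_sizes.reindex(factors.factors.index).to_numpy(),
        "tmm_factor": factors.factors.to_numpy(),
    }), args.out_dir / "factors.tsv")

    norm = log2_cpm(counts, factors)
    write_table(norm.reset_index(), args.out_dir / "normalized.tsv")

    rho = sample_spearman(norm)
    write_table(rho.rename_axis("sample_id").reset_index(),
                args.out_dir / "sample_spearman.tsv")

    off = rho.to_numpy()[~np.eye(len(rho), dtype=bool)]
    print(f"reference sample: {factors.reference_sample}")
    print(f"TMM factors: {factors.factors.min():.3f}-{factors.factors.max():.3f}")
    print(f"off-diagonal Spearman: min {off.min():.3f}, median "
          f"{np.median(off):.3f}")


if __name__ == "__main__":
    main()
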