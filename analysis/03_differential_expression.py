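#!/usr/bin/env python
"""Two-group differential expression for the four primary contrasts.

Genotype (SUN1L vs KDEL) within each substrate and rigidity (stiff vs soft)
within each genotype, each with the signed fold-change convention, a Welch z
test and BH FDR. Also writes the Venn counts of genotype-responsive genes on
soft vs stiff substrates — LINC disruption is expected to hit different genes
on the two rigidities.
"""

import argparse
import json
from pathlib import Path

from mechanoseq import de_table, log2_cpm, tmm_factors, venn_counts
from mechanoseq.io import read_counts, read_design, write_table
from mechanoseq.pipeline import CONTRAST_SPECS, _contrast_groups


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    counts = read_counts(args.out_dir / "counts.tsv")
    design = read_design(args.out_dir / "design.tsv")
    factors = tmm_factors(counts)
    norm = log2_cpm(counts, factors)

    significant = {}
    for name in CONTRAST_SPECS:
        a, b = _contrast_groups(design, name)
        table = de_table(norm, a, b)
        write_table(table.reset_index(), args.out_dir / f"de_{name}.tsv")
        significant[name] = set(table.index[table["significant"]])
        print(f"{name}: {len(significant[name])} significant genes")

    soft = significant["genotype_within_soft"]
    stiff = significant["genotype_within_stiff"]
    only_soft, both, only_stiff = venn_counts(soft, stiff)
    venn = {"soft_only": only_soft, "both": both, "stiff_only": only_stiff}
    (args.out_dir / "venn_genotype_soft_vs_stiff.json").write_text(
        json.dumps(venn, indent=2) + "\n")
    print(f"genotype-responsive genes: {venn}")


if __name__ == "__main__":
    main()
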