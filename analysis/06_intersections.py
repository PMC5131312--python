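#!/usr/bin/env python
"""Directional intersections across perturbations and over-representation.

Genes that respond alike (same direction, at least two-fold) to LINC
disruption on the stiff substrate and to myosin inhibition (blebbistatin,
Y27632) are candidate nuclear-tension-dependent genes. The planted truth
labels make the intersection self-validating here. A hypergeometric
over-representation test against annotation sets built from the planted
classes stands in for external annotation services.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mechanoseq import (de_table, directional_intersection, log2_cpm,
                        overrepresentation, tmm_factors, venn_counts)
from mechanoseq.genesets import signed_list_from_de
from mechanoseq.io import read_counts, read_design, write_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fc-min", type=float, default=2.0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    counts = read_counts(args.out_dir / "counts.tsv")
    design = read_design(args.out_dir / "design.tsv")
    factors = tmm_factors(counts)
    norm = log2_cpm(counts, factors)

    baseline = design.samples_where(genotype="KDEL", rigidity="stiff",
                                    treatment="none")
    sun = design.samples_where(genotype="SUN1L", rigidity="stiff",
                               treatment="none")
    lists = [signed_list_from_de("LINC", de_table(norm, sun, baseline))]
    for drug in ("blebbistatin", "Y27632"):
        treated = design.samples_where(treatment=drug)
        lists.append(signed_list_from_de(
            drug, de_table(norm, treated, baseline)))

    inter = directional_intersection(lists, fc_min=args.fc_min)
    write_table(inter.reset_index(), args.out_dir / "directional_intersection.tsv")
    sets = [set(lst.entries) for lst in lists]
    venn = venn_counts(*sets)
    (args.out_dir / "venn_three_perturbations.json").write_text(
        json.dumps(venn, indent=2) + "\n")
    print(f"{len(inter)} genes change alike under all three perturbations")
    print(f"3-set Venn regions (LINC, blebbistatin, Y27632): {venn}")

    truth = pd.read_csv(args.out_dir / "truth.tsv", sep="\t").set_index("gene_id")
    annotations = {
        f"planted_{cls}": set(truth.index[truth["true_class"] == cls])
        for cls in ("gained", "lost", "reversed")
    }
    annotations["myosin_dependent"] = set(
        truth.index[truth["myosin_dependent"]])
    hits = pd.read_csv(args.out_dir / "interacting_genes.tsv",
                       sep="\t")["gene_id"].astype(str).tolist()
    enrichment = overrepresentation(set(hits), annotations,
                                    universe=set(truth.index))
    write_table(enrichment.reset_index(), args.out_dir / "enrichment.tsv")
    print("over-representation of planted classes among interacting genes:")
    print(enrichment[["overlap", "expected", "p", "q"]].to_string())


if __name__ == "__main__":
    main()
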