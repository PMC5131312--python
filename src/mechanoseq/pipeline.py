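"""End-to-end orchestration: normalize, test, screen, classify, intersect.

`run_pipeline` is a pure function of the input files and configuration:
repeated runs with the same inputs produce byte-identical outputs. Every stage
writes a TSV under the configured output directory and the run summary JSON
records thresholds, seed, a config hash, library versions, and per-stage
record counts.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import PipelineConfig
from .diffexpr import de_table, low_count_filter, sample_spearman
from .genesets import directional_intersection, signed_list_from_de
from .interaction import interaction_screen, rigidity_dependent_noninteracting
from .io import (ConfigurationError, CountMatrix, DesignTable, read_counts,
                 read_design, write_table)
from .mechano import class_counts, mechano_table, quadrant_scatter
from .normalize import log2_cpm, tmm_factors

log = logging.getLogger("mechanoseq")

CONTRAST_SPECS = {
    # name -> (group A factors, group B factors); A over B
    "genotype_within_soft": (dict(genotype="SUN1L", rigidity="soft"),
                             dict(genotype="KDEL", rigidity="soft")),
    "genotype_within_stiff": (dict(genotype="SUN1L", rigidity="stiff"),
                              dict(genotype="KDEL", rigidity="stiff")),
    "rigidity_within_KDEL": (dict(genotype="KDEL", rigidity="stiff"),
                             dict(genotype="KDEL", rigidity="soft")),
    "rigidity_within_SUN1L": (dict(genotype="SUN1L", rigidity="stiff"),
                              dict(genotype="SUN1L", rigidity="soft")),
}

TREATMENT_SPECS = {
    "blebbistatin_within_KDEL_stiff": dict(treatment="blebbistatin"),
    "Y27632_within_KDEL_stiff": dict(treatment="Y27632"),
}


def _contrast_groups(design: DesignTable, name: str):
    spec_a, spec_b = CONTRAST_SPECS[name]
    a = design.samples_where(treatment="none", **spec_a)
    b = design.samples_where(treatment="none", **spec_b)
    if not a or not b:
        raise ConfigurationError(
            f"contrast {name!r} needs design cells {spec_a} and {spec_b}"
        )
    return a, b


def run_pipeline(config: PipelineConfig,
                 counts: CountMatrix | None = None,
                 design: DesignTable | None = None) -> dict:
    """Run every stage and write the result bundle under config.out_dir.

    Counts and design may be passed in memory; otherwise they are read from
    the configured paths. Returns a dict of in-memory results keyed by stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if counts is None:
        if config.counts_path is None:
            raise ConfigurationError("no counts given and no counts_path configured")
        counts = read_counts(config.counts_path)
    if design is None:
        if config.design_path is None:
            raise ConfigurationError("no design given and no design_path configured")
        design = read_design(config.design_path)
    design.validate_against(counts)

    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "versions": {
            "mechanoseq": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
        "stages": {},
    }
    results: dict = {"counts": counts, "design": design}

    if config.mirna:
        filtered = low_count_filter(counts, config.min_total_count)
        if isinstance(filtered, pd.DataFrame):
            raise ConfigurationError("low-count filter removed every gene")
        log.info("low-count filter: %d -> %d genes",
                 len(counts.gene_ids), len(filtered.gene_ids))
        counts = filtered
        results["counts"] = counts
    summary["stages"]["genes"] = len(counts.gene_ids)
    summary["stages"]["samples"] = len(counts.sample_ids)

    factors = tmm_factors(counts)
    fac_df = pd.DataFrame({
        "sample_id": factors.factors.index,
        "lib_size": factors.library_sizes.reindex(factors.factors.index).to_numpy(),
        "tmm_factor": factors.factors.to_numpy(),
    })
    write_table(fac_df, out_dir / "factors.tsv")
    norm = log2_cpm(counts, factors, config.pseudocount)
    write_table(norm.reset_index(), out_dir / "normalized.tsv")
    results["factors"] = factors
    results["normalized"] = norm

    spearman = sample_spearman(norm)
    write_table(spearman.rename_axis("sample_id").reset_index(),
                out_dir / "sample_spearman.tsv")
    results["spearman"] = spearman

    de_tables = {}
    for name in CONTRAST_SPECS:
        a, b = _contrast_groups(design, name)
        table = de_table(norm, a, b, config.fc_cutoff, config.alpha_fdr)
        de_tables[name] = table
        write_table(table.reset_index(), out_dir / f"de_{name}.tsv")
        summary["stages"][f"de_{name}_significant"] = int(table["significant"].sum())
    results["de"] = de_tables

    hits, anova = interaction_screen(norm, design, counts, factors,
                                     alpha_fwer=config.alpha_fwer)
    write_table(anova.reset_index(), out_dir / "anova.tsv")
    write_table(pd.DataFrame({"gene_id": hits}), out_dir / "interacting_genes.tsv")
    summary["stages"]["interacting_genes"] = len(hits)
    results["interacting_genes"] = hits
    results["anova"] = anova

    rig_only = rigidity_dependent_noninteracting(
        norm, design, config.fc_cutoff, config.alpha_fdr)
    write_table(pd.DataFrame({"gene_id": rig_only}),
                out_dir / "rigidity_dependent_noninteracting.tsv")
    summary["stages"]["rigidity_dependent_noninteracting"] = len(rig_only)
    results["rigidity_dependent_noninteracting"] = rig_only

    mech = mechano_table(norm, design, gene_subset=hits if hits else [])
    write_table(mech.reset_index(), out_dir / "mechano.tsv")
    counts_by_class = class_counts(mech) if len(mech) else None
    if counts_by_class is not None:
        summary["stages"]["ms_class_counts"] = counts_by_class.to_dict()
    if len(mech):
        quadrant_scatter(mech, out_dir / "mechano_quadrants.png")
    results["mechano"] = mech

    # directional intersections with the drug arms, when present
    treated = design.samples_where(genotype="KDEL", rigidity="stiff",
                                   treatment=("blebbistatin", "Y27632"))
    if treated:
        baseline = design.samples_where(genotype="KDEL", rigidity="stiff",
                                        treatment="none")
        lists = [signed_list_from_de("LINC_disruption",
                                     de_tables["genotype_within_stiff"])]
        for name, sel in TREATMENT_SPECS.items():
            drug = design.samples_where(genotype="KDEL", rigidity="stiff", **sel)
            if not drug:
                continue
            table = de_table(norm, drug, baseline, config.fc_cutoff, config.alpha_fdr)
            write_table(table.reset_index(), out_dir / f"de_{name}.tsv")
            lists.append(signed_list_from_de(name.split("_")[0], table))
        if len(lists) >= 2:
            inter = directional_intersection(lists, fc_min=config.fc_cutoff)
            write_table(inter.reset_index(), out_dir / "directional_intersection.tsv")
            summary["stages"]["directional_intersection"] = len(inter)
            results["directional_intersection"] = inter

    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    results["summary"] = summary
    return results
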