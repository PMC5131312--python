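"""Per-gene two-way ANOVA and the genome-wide interaction screen.

Each gene's log2 CPM values are decomposed over the balanced 2x2 design
(substrate rigidity x genotype) into main-effect, interaction and residual
sums of squares; F statistics use the residual mean square with df
(1, n - 4). The screen Bonferroni-corrects the interaction p-value over the
family of testable genes and reports those significant at the family-wise
level — the genes whose rigidity response is altered by LINC disruption.

The decomposition is computed in closed form (balanced designs make the
SS types coincide), vectorized over genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import de_table
from .io import ConfigurationError, CountMatrix, DesignTable
from .normalize import NormalizationFactors, cpm

ANOVA_COLUMNS = [
    "F_rigidity", "F_genotype", "F_interaction",
    "p_rigidity", "p_genotype", "p_interaction",
    "df_effect", "df_residual", "zero_residual",
]


def _cell_samples(design: DesignTable) -> dict[tuple[str, str], list[str]]:
    cells = {}
    for rig in ("soft", "stiff"):
        for gen in ("KDEL", "SUN1L"):
            cells[(rig, gen)] = design.samples_where(
                rigidity=rig, genotype=gen, treatment="none"
            )
    return cells


def _check_balanced(cells: dict) -> int:
    sizes = {k: len(v) for k, v in cells.items()}
    missing = [k for k, n in sizes.items() if n == 0]
    if missing:
        raise ConfigurationError(f"missing design cell(s): {missing}")
    reps = set(sizes.values())
    if len(reps) != 1:
        raise ConfigurationError(f"unbalanced design cells: {sizes}")
    r = reps.pop()
    if r < 2:
        raise ConfigurationError("two-way ANOVA needs >= 2 replicates per cell")
    return r


def two_way_anova(values: np.ndarray, r: int) -> pd.DataFrame:
    """Vectorized balanced 2x2 ANOVA.

    `values` has shape (genes, 4, r): the four cells ordered
    (soft,KDEL), (soft,SUN1L), (stiff,KDEL), (stiff,SUN1L), r replicates each.
    Degenerate genes (zero residual variance) get NaN F and p with a flag.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None, :, :]
    n_genes, n_cells, _ = values.shape
    if n_cells != 4:
        raise ConfigurationError("expected exactly the four 2x2 design cells")
    n = 4 * r
    cell_means = values.mean(axis=2)  # (genes, 4)
    grand = cell_means.mean(axis=1)
    # factor level means: rigidity soft = cells 0,1; stiff = cells 2,3;
    # genotype KDEL = cells 0,2; SUN1L = cells 1,3
    soft = cell_means[:, [0, 1]].mean(axis=1)
    stiff = cell_means[:, [2, 3]].mean(axis=1)
    kdel = cell_means[:, [0, 2]].mean(axis=1)
    sun = cell_means[:, [1, 3]].mean(axis=1)
    ss_rig = 2 * r * ((soft - grand) ** 2 + (stiff - grand) ** 2)
    ss_gen = 2 * r * ((kdel - grand) ** 2 + (sun - grand) ** 2)
    contrast = (cell_means[:, 0] - cell_means[:, 1]
                - cell_means[:, 2] + cell_means[:, 3])
    ss_int = r * contrast ** 2 / 4.0
    ss_res = ((values - cell_means[:, :, None]) ** 2).sum(axis=(1, 2))
    df_res = n - 4
    ms_res = ss_res / df_res
    zero = ms_res == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_rig = ss_rig / ms_res
        f_gen = ss_gen / ms_res
        f_int = ss_int / ms_res
    p_rig = stats.f.sf(f_rig, 1, df_res)
    p_gen = stats.f.sf(f_gen, 1, df_res)
    p_int = stats.f.sf(f_int, 1, df_res)
    for arr in (f_rig, f_gen, f_int, p_rig, p_gen, p_int):
        arr[zero] = np.nan
    return pd.DataFrame({
        "F_rigidity": f_rig, "F_genotype": f_gen, "F_interaction": f_int,
        "p_rigidity": p_rig, "p_genotype": p_gen, "p_interaction": p_int,
        "df_effect": 1, "df_residual": df_res, "zero_residual": zero,
    })


def two_way_anova_gene(cells: dict[tuple[str, str], np.ndarray]) -> pd.Series:
    """Single-gene ANOVA from a mapping (rigidity, genotype) -> replicate values."""
    order = [("soft", "KDEL"), ("soft", "SUN1L"), ("stiff", "KDEL"), ("stiff", "SUN1L")]
    missing = [k for k in order if k not in cells]
    if missing:
        raise ConfigurationError(f"missing design cell(s): {missing}")
    arrays = [np.asarray(cells[k], dtype=float) for k in order]
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ConfigurationError("unbalanced design cells")
    r = sizes.pop()
    if r < 2:
        raise ConfigurationError("two-way ANOVA needs >= 2 replicates per cell")
    return two_way_anova(np.stack(arrays)[None, :, :], r).iloc[0]


def anova_table(norm: pd.DataFrame, design: DesignTable) -> pd.DataFrame:
    """Gene-wise 2x2 ANOVA over the untreated samples of a normalized matrix."""
    cells = _cell_samples(design)
    r = _check_balanced(cells)
    order = [("soft", "KDEL"), ("soft", "SUN1L"), ("stiff", "KDEL"), ("stiff", "SUN1L")]
    stacked = np.stack([norm[cells[k]].to_numpy() for k in order], axis=1)
    out = two_way_anova(stacked, r)
    out.index = norm.index
    out.index.name = "gene_id"
    return out


def interaction_screen(norm: pd.DataFrame, design: DesignTable,
                       counts: CountMatrix, factors: NormalizationFactors,
                       alpha_fwer: float = 0.05,
                       min_mean_cpm: float = 1.0):
    """Bonferroni-corrected genome-wide interaction screen.

    The tested family G is the set of genes with mean CPM >= min_mean_cpm
    across all samples and nonzero residual variance; untestable genes are
    excluded from the family so they do not consume Bonferroni budget (their
    corrected p is NaN). Returns (interacting gene ids sorted by raw
    interaction p, full ANOVA table with `p_interaction_bonferroni` and
    `in_family` columns).
    """
    table = anova_table(norm, design)
    mean_cpm = cpm(counts, factors).mean(axis=1).reindex(table.index)
    in_family = (mean_cpm >= min_mean_cpm) & ~table["zero_residual"]
    g = int(in_family.sum())
    table = table.copy()
    table["mean_cpm"] = mean_cpm
    table["in_family"] = in_family
    bonf = np.minimum(1.0, table["p_interaction"] * g)
    bonf[~in_family] = np.nan
    table["p_interaction_bonferroni"] = bonf
    hits = table.loc[in_family & (table["p_interaction_bonferroni"] < alpha_fwer)]
    hit_ids = list(hits.sort_values("p_interaction").index)
    return hit_ids, table


def rigidity_dependent_noninteracting(norm: pd.DataFrame, design: DesignTable,
                                      fc_cutoff: float = 2.0,
                                      alpha_fdr: float = 0.05) -> list[str]:
    """Genes driven by substrate rigidity but indifferent to LINC disruption:
    significant for stiff-vs-soft within KDEL, and not significant for
    SUN1L-vs-KDEL on either substrate."""
    kdel_stiff = design.samples_where(genotype="KDEL", rigidity="stiff", treatment="none")
    kdel_soft = design.samples_where(genotype="KDEL", rigidity="soft", treatment="none")
    rig = de_table(norm, kdel_stiff, kdel_soft, fc_cutoff, alpha_fdr)
    keep = rig["significant"].copy()
    for rigidity in ("soft", "stiff"):
        sun = design.samples_where(genotype="SUN1L", rigidity=rigidity, treatment="none")
        kdel = design.samples_where(genotype="KDEL", rigidity=rigidity, treatment="none")
        gen = de_table(norm, sun, kdel, fc_cutoff, alpha_fdr)
        keep &= ~gen["significant"]
    return list(rig.index[keep])
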