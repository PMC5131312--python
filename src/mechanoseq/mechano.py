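"""The mechanosensitivity statistic MS_gene and its gained/lost/reversed ratio
classification.

MS_gene is the stiff-over-soft fold change of a gene's expression, re-expressed
on the signed convention (fold < 1 becomes -1/fold, so |MS| >= 1 always). For
each gene the statistic is computed separately in control (KDEL) and
LINC-disrupted (SUN1L) cells, and the ratio R = MS_SUN1L / MS_KDEL classifies
how LINC disruption altered the gene's rigidity response:

    R > 1      gained mechanosensitivity
    0 < R < 1  lost mechanosensitivity
    R < 0      reversed direction of mechanosensitivity
    R = 1      unchanged (within epsilon; boundary cases)

A reversed call is exactly equivalent to MS_KDEL and MS_SUN1L having opposite
signs, i.e. the gene lying in the 2nd or 4th quadrant of the
(MS_KDEL, MS_SUN1L) plane.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import DesignTable

MS_CLASSES = ("gained", "lost", "reversed", "unchanged")


def ms_gene(mean_log2_stiff: float, mean_log2_soft: float) -> float:
    """Signed stiff-over-soft fold change from group-mean log2 CPM."""
    fc = 2.0 ** (np.asarray(mean_log2_stiff, dtype=float)
                 - np.asarray(mean_log2_soft, dtype=float))
    out = np.where(fc >= 1.0, fc, -1.0 / fc)
    return out if out.ndim else float(out)


def classify(ms_sun1l: float, ms_kdel: float, epsilon: float = 1e-9):
    """(ratio, class) from the two genotype mechanosensitivities."""
    if abs(ms_kdel) < 1.0 or abs(ms_sun1l) < 1.0:
        raise ValueError("|MS| must be >= 1 under the signed convention")
    ratio = ms_sun1l / ms_kdel
    if ratio < 0:
        cls = "reversed"
    elif abs(ratio - 1.0) <= epsilon:
        cls = "unchanged"
    elif ratio > 1.0:
        cls = "gained"
    else:
        cls = "lost"
    return ratio, cls


def mechano_table(norm: pd.DataFrame, design: DesignTable,
                  gene_subset=None, epsilon: float = 1e-9) -> pd.DataFrame:
    """Per-gene MS in each genotype, their ratio, and the class label.

    Typically run on the interaction screen's significant genes (the genes
    whose mechanosensitivity demonstrably changed); the full matrix is used
    when gene_subset is None. Also carries the (MS_KDEL, MS_SUN1L) quadrant
    scatter coordinates.
    """
    genes = norm.index if gene_subset is None else pd.Index(list(gene_subset))
    missing = genes.difference(norm.index)
    if len(missing):
        raise KeyError(f"genes absent from matrix: {list(missing)[:5]}")
    if len(genes) == 0:
        warnings.warn("empty gene subset: mechanosensitivity table is empty")
        return pd.DataFrame(
            columns=["MS_KDEL", "MS_SUN1L", "ratio", "ms_class"]
        ).rename_axis("gene_id")

    sub = norm.loc[genes]
    means = {}
    for genotype in ("KDEL", "SUN1L"):
        for rigidity in ("soft", "stiff"):
            ids = design.samples_where(genotype=genotype, rigidity=rigidity,
                                       treatment="none")
            means[(genotype, rigidity)] = sub[ids].mean(axis=1)
    ms_kdel = ms_gene(means[("KDEL", "stiff")], means[("KDEL", "soft")])
    ms_sun = ms_gene(means[("SUN1L", "stiff")], means[("SUN1L", "soft")])
    ratio = ms_sun / ms_kdel
    cls = np.select(
        [ratio < 0, np.abs(ratio - 1.0) <= epsilon, ratio > 1.0],
        ["reversed", "unchanged", "gained"],
        default="lost",
    )
    out = pd.DataFrame({
        "MS_KDEL": ms_kdel,
        "MS_SUN1L": ms_sun,
        "ratio": ratio,
        "ms_class": cls,
    }, index=genes)
    out.index.name = "gene_id"
    return out


def class_counts(table: pd.DataFrame) -> pd.Series:
    """Counts per mechanosensitivity class, all classes present (zeros kept)."""
    counts = table["ms_class"].value_counts()
    return counts.reindex(MS_CLASSES, fill_value=0).astype(int)


def quadrant_scatter(table: pd.DataFrame, path) -> None:
    """MS_KDEL vs MS_SUN1L scatter colored by class (reversed genes populate
    the 2nd/4th quadrants)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"gained": "tab:blue", "lost": "gold",
              "reversed": "tab:red", "unchanged": "gray"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, color in colors.items():
        sub = table[table["ms_class"] == cls]
        if len(sub):
            ax.scatter(sub["MS_KDEL"], sub["MS_SUN1L"], s=12, c=color, label=cls)
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel("MS (KDEL)")
    ax.set_ylabel("MS (SUN1L)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
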