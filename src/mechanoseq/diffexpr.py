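"""Two-group differential expression on log2 CPM.

Group effects are summarized as fold changes with the signed convention used
throughout: a fold change below 1 is re-expressed as -1/fold, so that a gene
halved in A relative to B reads -2 rather than 0.5 and |signed_fc| >= 1
always. Significance combines a Welch z statistic (two-sided normal p) with
Benjamini-Hochberg FDR control, and a gene is called differentially expressed
only when BOTH the q-value and the fold-change cutoff criteria hold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConfigurationError, CountMatrix

TINY_P = np.nextafter(0.0, 1.0)


def signed_fc_from_fold(fold_change):
    """fold >= 1 stays; fold < 1 becomes -1/fold (|signed| >= 1 convention)."""
    fold_change = np.asarray(fold_change, dtype=float)
    out = np.where(fold_change >= 1.0, fold_change, -1.0 / fold_change)
    return out if out.ndim else float(out)


def _check_groups(norm: pd.DataFrame, samples_a, samples_b) -> tuple[list, list]:
    a, b = list(samples_a), list(samples_b)
    if not a or not b:
        raise ConfigurationError("both groups must be nonempty")
    overlap = set(a) & set(b)
    if overlap:
        raise ConfigurationError(f"groups overlap: {sorted(overlap)}")
    missing = (set(a) | set(b)) - set(norm.columns)
    if missing:
        raise ConfigurationError(f"samples absent from matrix: {sorted(missing)}")
    return a, b


def group_fold_change(norm: pd.DataFrame, samples_a, samples_b) -> pd.DataFrame:
    """Per-gene fold change of group A over group B on log2 CPM means."""
    a, b = _check_groups(norm, samples_a, samples_b)
    mean_a = norm[a].mean(axis=1)
    mean_b = norm[b].mean(axis=1)
    fold = 2.0 ** (mean_a - mean_b)
    return pd.DataFrame({
        "mean_log2_A": mean_a,
        "mean_log2_B": mean_b,
        "fold_change": fold,
        "signed_fc": signed_fc_from_fold(fold.to_numpy()),
    })


def z_test(norm: pd.DataFrame, samples_a, samples_b) -> pd.DataFrame:
    """Welch z on log2 CPM with a standard-normal reference.

    Degenerate genes: zero pooled variance with equal means gives z=0, p=1;
    zero variance with unequal means gives the smallest positive p and a flag.
    """
    a, b = _check_groups(norm, samples_a, samples_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("z test needs >= 2 samples per group")
    xa, xb = norm[a].to_numpy(), norm[b].to_numpy()
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    se2 = xa.var(axis=1, ddof=1) / len(a) + xb.var(axis=1, ddof=1) / len(b)
    diff = mean_a - mean_b
    zero_var = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / np.sqrt(se2)
        z = np.where(zero_var,
                     np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(zero_var & (diff != 0.0), TINY_P, p)
    p = np.where(zero_var & (diff == 0.0), 1.0, p)
    return pd.DataFrame({
        "z": z,
        "p": p,
        "degenerate": zero_var & (diff != 0.0),
    }, index=norm.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(norm: pd.DataFrame, samples_a, samples_b,
             fc_cutoff: float = 2.0, alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Full differential-expression table for the contrast A vs B."""
    fc = group_fold_change(norm, samples_a, samples_b)
    zp = z_test(norm, samples_a, samples_b)
    out = fc.join(zp)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < alpha_fdr) & (np.abs(out["signed_fc"]) >= fc_cutoff)
    out.index.name = "gene_id"
    return out


def low_count_filter(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with total raw count below min_total (miRNA pre-filter).

    May return an empty matrix wrapper; in that case the bare DataFrame is
    returned since CountMatrix forbids emptiness.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    if keep.all():
        return counts
    filtered = counts.counts.loc[keep]
    if filtered.shape[0] == 0:
        return filtered
    return CountMatrix(filtered)


def sample_spearman(norm: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman rank correlation (midranks for ties).

    Constant sample vectors have undefined correlation, reported as NaN
    (diagonal stays 1 by definition).
    """
    if norm.shape[0] < 2:
        raise ValueError("Spearman needs >= 2 genes")
    values = norm.to_numpy()
    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # midranks for ties
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    const = values.std(axis=0) == 0.0
    for i in np.flatnonzero(const):
        rho[i, :] = np.nan
        rho[:, i] = np.nan
        rho[i, i] = 1.0
    return pd.DataFrame(rho, index=norm.columns, columns=norm.columns)
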