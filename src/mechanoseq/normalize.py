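"""Trimmed-mean-of-M-values (TMM) scaling factors and log2 counts-per-million.

TMM estimates a per-sample scaling factor as the weighted mean of per-gene
log2 expression ratios (M-values) against a reference sample, after trimming
the most extreme M-values and the most extreme average abundances (A-values).
Under the assumption that most genes are not differentially expressed, the
trimmed mean isolates the compositional offset between libraries. Factors are
rescaled so their geometric mean is 1, making effective library sizes
N_s * f_s comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM factors (geometric mean 1) and raw library sizes."""

    factors: pd.Series
    library_sizes: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise NormalizationError("all factors must be positive")
        log_mean = np.log(self.factors.to_numpy()).mean()
        if abs(log_mean) > 1e-12:
            raise NormalizationError("factors must have geometric mean 1")
        if (self.library_sizes <= 0).any():
            raise NormalizationError("library sizes must be positive")


def select_reference(counts: CountMatrix) -> str:
    """Sample whose 75th-percentile count fraction is closest to the mean of
    those quantiles across samples; ties broken by sample-id order."""
    if len(counts.sample_ids) < 2:
        raise NormalizationError("reference selection needs >= 2 samples")
    lib = counts.library_sizes
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise NormalizationError(f"all-zero sample(s): {zero}")
    frac = counts.counts.to_numpy(dtype=float) / lib.to_numpy(dtype=float)
    q75 = np.percentile(frac, 75, axis=0)
    dist = np.abs(q75 - q75.mean())
    order = sorted(range(len(dist)), key=lambda i: (dist[i], counts.sample_ids[i]))
    return counts.sample_ids[order[0]]


def _trim_survivors(values: np.ndarray, ids: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping the central (1 - 2*trim) of `values`.

    Exactly floor(trim * n) entries are dropped from each tail; boundary ties
    are resolved by a stable sort on (value, gene id) for determinism.
    """
    n = values.size
    k = int(np.floor(trim * n))
    order = np.lexsort((ids, values))
    keep = np.zeros(n, dtype=bool)
    keep[order[k:n - k if k > 0 else n]] = True
    return keep


def tmm_factor(sample_counts: np.ndarray, ref_counts: np.ndarray,
               gene_ids=None, trim_m: float = 0.30, trim_a: float = 0.05,
               lib_sample: float | None = None, lib_ref: float | None = None,
               sample_name: str = "sample") -> float:
    """Unscaled TMM factor of one sample against the reference.

    M_g = log2((y_gs/N_s)/(y_gr/N_r)), A_g = 0.5*log2((y_gs/N_s)*(y_gr/N_r))
    over genes positive in both samples; the top and bottom trim_m of M and
    trim_a of A are dropped; the factor is 2 to the precision-weighted mean of
    the surviving M, with weights the inverse of
    (N_s - y_gs)/(N_s y_gs) + (N_r - y_gr)/(N_r y_gr).
    """
    y_s = np.asarray(sample_counts, dtype=float)
    y_r = np.asarray(ref_counts, dtype=float)
    if y_s.shape != y_r.shape:
        raise NormalizationError("sample and reference vectors differ in length")
    n_s = float(y_s.sum()) if lib_sample is None else float(lib_sample)
    n_r = float(y_r.sum()) if lib_ref is None else float(lib_ref)
    if n_s <= 0 or n_r <= 0:
        raise NormalizationError("library sizes must be positive")
    if gene_ids is None:
        gene_ids = np.arange(y_s.size)
    gene_ids = np.asarray(gene_ids)

    pos = (y_s > 0) & (y_r > 0)
    y_s, y_r, gids = y_s[pos], y_r[pos], gene_ids[pos]
    if y_s.size == 0:
        raise NormalizationError(f"no genes usable for TMM in sample {sample_name!r}")

    m = np.log2((y_s / n_s) / (y_r / n_r))
    a = 0.5 * np.log2((y_s / n_s) * (y_r / n_r))
    keep = _trim_survivors(m, gids, trim_m) & _trim_survivors(a, gids, trim_a)
    if not keep.any():
        raise NormalizationError(f"no genes survive trimming in sample {sample_name!r}")

    var = (n_s - y_s[keep]) / (n_s * y_s[keep]) + (n_r - y_r[keep]) / (n_r * y_r[keep])
    # counts equal to the whole library (var 0) would get infinite weight;
    # they cannot occur together with other genes, so guard explicitly
    var = np.maximum(var, 1e-300)
    w = 1.0 / var
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """TMM factors for every sample, rescaled to geometric mean 1."""
    ref = select_reference(counts)
    lib = counts.library_sizes.astype(float)
    genes = np.asarray(counts.gene_ids)
    y_ref = counts.counts[ref].to_numpy(dtype=float)
    raw = {}
    for sid in counts.sample_ids:
        if sid == ref:
            raw[sid] = 1.0
        else:
            raw[sid] = tmm_factor(
                counts.counts[sid].to_numpy(dtype=float), y_ref, gene_ids=genes,
                trim_m=trim_m, trim_a=trim_a,
                lib_sample=lib[sid], lib_ref=lib[ref], sample_name=sid,
            )
    factors = pd.Series(raw, name="tmm_factor").reindex(counts.sample_ids)
    factors /= np.exp(np.log(factors.to_numpy()).mean())
    return NormalizationFactors(factors=factors, library_sizes=counts.library_sizes,
                                reference_sample=ref)


def log2_cpm(counts: CountMatrix, factors: NormalizationFactors,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) with TMM-adjusted effective library sizes."""
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    if set(factors.factors.index) != set(counts.sample_ids):
        raise NormalizationError("factor sample set does not match count matrix")
    eff = (factors.library_sizes.astype(float)
           * factors.factors).reindex(counts.sample_ids)
    cpm = counts.counts.to_numpy(dtype=float) / eff.to_numpy() * 1e6
    out = pd.DataFrame(np.log2(cpm + pseudocount),
                       index=counts.counts.index, columns=counts.sample_ids)
    out.index.name = "gene_id"
    return out


def cpm(counts: CountMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """Linear-scale CPM on TMM-adjusted library sizes (no pseudocount)."""
    eff = (factors.library_sizes.astype(float)
           * factors.factors).reindex(counts.sample_ids)
    out = counts.counts.astype(float) / eff * 1e6
    out.index.name = "gene_id"
    return out
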