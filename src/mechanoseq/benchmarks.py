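"""Calibration and recovery benchmarks computed from seeded simulations.

These are the package's headline self-checks: family-wise error control of
the interaction screen under the global null, recovery of planted
mechanosensitivity classes, closed-form agreement of the FWHM estimator, the
ddCT identity, and the published control-cell spreading ratio between stiff
and soft substrates.
"""

from __future__ import annotations

import numpy as np

from .interaction import interaction_screen
from .mechano import mechano_table
from .morphoqc import ddct_table, fwhm, load_morphometry_summary
from .normalize import log2_cpm, tmm_factors
from .simulate import (class_recovery_scenario, null_scenario, simulate_counts,
                       simulate_qpcr, simulate_zprofiles)

PLANTED_CLASSES = ("gained", "lost", "reversed")


def _screen(counts, design, alpha_fwer=0.05):
    factors = tmm_factors(counts)
    norm = log2_cpm(counts, factors)
    hits, table = interaction_screen(norm, design, counts, factors,
                                     alpha_fwer=alpha_fwer)
    return hits, table, norm


def fwer_null_rate(seed: int, n_sims: int = 200, n_genes: int = 2000) -> dict:
    """Fraction of global-null simulations with any Bonferroni-significant
    interaction (the family-wise error rate of the screen)."""
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    with_hits = 0
    for s in sim_seeds:
        counts, design, _ = simulate_counts(null_scenario(int(s), n_genes=n_genes))
        hits, _, _ = _screen(counts, design)
        with_hits += bool(hits)
    rate = with_hits / n_sims
    return {
        "rate": rate,
        "n_sims": n_sims,
        "bound": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / n_sims)),
    }


def class_recovery(seed: int, n_per_class: int = 300, n_null: int = 1100) -> dict:
    """Recovery of planted gained/lost/reversed classes by the full screen +
    classification pipeline.

    Returns the fraction of recovered (screen-significant) planted genes whose
    assigned class matches truth, and the recall of planted reversed genes
    (detected AND classified reversed).
    """
    cfg = class_recovery_scenario(seed, n_per_class=n_per_class, n_null=n_null)
    counts, design, truth = simulate_counts(cfg)
    truth = truth.set_index("gene_id")
    hits, table, norm = _screen(counts, design)
    mech = mechano_table(norm, design, gene_subset=hits)
    joined = mech.join(truth["true_class"])
    recovered = joined[joined["true_class"].isin(PLANTED_CLASSES)]
    accuracy = float((recovered["ms_class"] == recovered["true_class"]).mean()) \
        if len(recovered) else float("nan")
    reversed_ids = truth.index[truth["true_class"] == "reversed"]
    hit_set = set(hits)
    recalled = sum(
        1 for g in reversed_ids
        if g in hit_set and mech.loc[g, "ms_class"] == "reversed"
    )
    return {
        "class_accuracy": accuracy,
        "reversed_recall": recalled / len(reversed_ids),
        "n_recovered_planted": int(len(recovered)),
        "n_hits": len(hits),
        "n_planted": 3 * n_per_class,
    }


def fwhm_gaussian_check(sigma: float = 1.0, grid_step: float = 0.01) -> dict:
    """FWHM of a noise-free Gaussian against the closed form 2 sqrt(2 ln 2) sigma."""
    (profile,) = simulate_zprofiles(1, sigma_range=(sigma, sigma),
                                    grid_step=grid_step, noise_sd=0.0, seed=0)
    measured = fwhm(profile)
    return {
        "measured": measured,
        "closed_form": profile.true_fwhm,
        "abs_error": abs(measured - profile.true_fwhm),
        "grid_step": grid_step,
    }


def ddct_identity_check() -> dict:
    """Fold changes recovered from noise-free CT tables at ddCT = 0 and 1."""
    folds = ddct_table(simulate_qpcr([1.0, 0.5], noise_sd=0.0))
    return {
        "fold_at_ddct_0": float(folds["fold"].iloc[0]),
        "fold_at_ddct_1": float(folds["fold"].iloc[1]),
    }


def spreading_ratio_kdel() -> dict:
    """Ratio of mean control-cell spreading areas, stiff (308 kPa) over soft
    (1 kPa), from the published morphometric summary."""
    table = load_morphometry_summary().set_index(
        ["measure", "genotype", "rigidity_kpa"])
    stiff = float(table.loc[("cell_spreading_area_um2", "KDEL", 308), "mean"])
    soft = float(table.loc[("cell_spreading_area_um2", "KDEL", 1), "mean"])
    return {"ratio": stiff / soft, "rounded": round(stiff / soft)}
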