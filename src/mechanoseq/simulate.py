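"""Negative-binomial factorial count simulator with planted mechanosensitivity.

Emulates a balanced 2x2 bulk RNA-seq design — substrate rigidity (soft 1 kPa /
stiff 308 kPa) crossed with genotype (KDEL control / SUN1L LINC disruption) —
with a configurable number of replicates per cell. Each gene carries a known
log2-scale effect structure:

    log2 mu proportional to  b0 + beta_rig*[stiff] + beta_gen*[SUN1L]
                                + beta_int*[stiff]*[SUN1L]

from which its true mechanosensitivity in each genotype and hence its true
class (gained / lost / reversed / rigidity_only / null) follows.  Truth is
assigned before any count is drawn, so recovery scoring is unambiguous.

Counts are gamma-Poisson (negative binomial) with per-gene dispersion phi:
Var = mu + phi * mu^2.  Library sizes are log-normal, which makes TMM
normalization non-trivial.  Optional treatment arms add blebbistatin and
Y27632 samples (myosin / Rho-kinase inhibition of KDEL cells on the stiff
substrate) whose planted effects overlap the SUN1L-responsive genes by an
exact, deterministic fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigurationError, CountMatrix, DesignTable

CLASSES = ("null", "gained", "lost", "reversed", "rigidity_only")

DEFAULT_PROPORTIONS = {
    "null": 0.85,
    "gained": 0.04,
    "lost": 0.04,
    "reversed": 0.04,
    "rigidity_only": 0.03,
}


def signed_fold(log2_effect: float) -> float:
    """Map a log2 effect to the signed fold-change convention (|.| >= 1)."""
    fc = 2.0 ** log2_effect
    return fc if fc >= 1.0 else -1.0 / fc


def class_from_effects(beta_rig: float, beta_int: float,
                       effect_floor: float = 1.0) -> str:
    """Mechanosensitivity class implied by the planted log2 effects.

    The class compares the gene's rigidity response in the control genotype
    (beta_rig) with its response after LINC disruption (beta_rig + beta_int):
    opposite signs with both magnitudes at or above the effect floor is
    "reversed"; the same sign with a larger / smaller disrupted magnitude is
    "gained" / "lost"; no interaction term is "rigidity_only"; no effect at
    all is "null".
    """
    sun = beta_rig + beta_int
    if beta_rig == 0.0 and beta_int == 0.0:
        return "null"
    if beta_int == 0.0:
        return "rigidity_only"
    if np.sign(beta_rig) != np.sign(sun):
        if min(abs(beta_rig), abs(sun)) >= effect_floor:
            return "reversed"
        raise ConfigurationError(
            "sign change with a magnitude below the effect floor has no class"
        )
    return "gained" if abs(sun) > abs(beta_rig) else "lost"


@dataclass(frozen=True)
class GeneEffectSpec:
    """Planted per-gene effect sizes (all on the log2 scale) and true class."""

    gene_id: str
    b0: float
    beta_rig: float
    beta_gen: float
    beta_int: float
    dispersion: float
    true_class: str

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.true_class not in CLASSES:
            raise ConfigurationError(f"unknown class {self.true_class!r}")
        implied = class_from_effects(self.beta_rig, self.beta_int,
                                     effect_floor=min(1.0, abs(self.beta_rig) or 1.0))
        if implied != self.true_class:
            raise ConfigurationError(
                f"true_class {self.true_class!r} inconsistent with effects "
                f"(implied {implied!r})"
            )

    @property
    def ms_kdel(self) -> float:
        return signed_fold(self.beta_rig)

    @property
    def ms_sun1l(self) -> float:
        return signed_fold(self.beta_rig + self.beta_int)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_floor: float = 1.0
    effect_window: float = 1.5
    n_reps: int = 3
    mean_lib_size: float = 1e6
    lib_size_cv: float = 0.2
    dispersion_range: tuple = (0.05, 0.5)
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    planted_b0_range: tuple | None = None
    include_myosin_arms: bool = False
    myosin_overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2 (ANOVA needs residual df)")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions sum to {total}, not 1")
        unknown = sorted(set(self.class_proportions) - set(CLASSES))
        if unknown:
            raise ConfigurationError(f"unknown classes in proportions: {unknown}")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ConfigurationError("dispersion_range must satisfy 0 < low <= high")
        if self.effect_floor <= 0 or self.effect_window <= 0:
            raise ConfigurationError("effect_floor and effect_window must be positive")
        if not 0 <= self.myosin_overlap_fraction <= 1:
            raise ConfigurationError("myosin_overlap_fraction must be in [0, 1]")


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of genes to classes."""
    props = {c: config.class_proportions.get(c, 0.0) for c in CLASSES}
    raw = {c: config.n_genes * p for c, p in props.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    by_remainder = sorted(CLASSES, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _draw_effects(cls: str, floor: float, window: float, rng: np.random.Generator):
    """(beta_rig, beta_int) consistent with the class's definition.

    Non-null magnitudes are uniform on [floor, floor + window]; signs are
    random subject to the class constraint on sign(beta_rig) versus
    sign(beta_rig + beta_int).
    """
    if cls == "null":
        return 0.0, 0.0
    sign = rng.choice([-1.0, 1.0])
    m_kdel = rng.uniform(floor, floor + window)
    if cls == "rigidity_only":
        return sign * m_kdel, 0.0
    if cls == "reversed":
        m_sun = rng.uniform(floor, floor + window)
        return sign * m_kdel, -sign * (m_kdel + m_sun)
    # gained / lost: same sign, strictly ordered magnitudes
    m_sun = rng.uniform(floor, floor + window)
    while m_sun == m_kdel:  # pragma: no cover - measure zero
        m_sun = rng.uniform(floor, floor + window)
    lo, hi = sorted((m_kdel, m_sun))
    if cls == "gained":
        return sign * lo, sign * (hi - lo)
    return sign * hi, sign * (lo - hi)


def _build_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = _class_counts(config)
    labels: list[str] = []
    for cls in CLASSES:
        labels.extend([cls] * counts[cls])
    rng.shuffle(labels)

    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(n)]
    lo_d, hi_d = config.dispersion_range
    dispersions = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), size=n))

    rows = []
    for gid, cls, phi in zip(gene_ids, labels, dispersions):
        if cls == "null" or config.planted_b0_range is None:
            b0 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
        else:
            b0 = rng.uniform(*config.planted_b0_range)
        beta_rig, beta_int = _draw_effects(
            cls, config.effect_floor, config.effect_window, rng
        )
        rows.append((gid, b0, beta_rig, 0.0, beta_int, phi, cls))
    truth = pd.DataFrame(
        rows,
        columns=["gene_id", "b0", "beta_rig", "beta_gen", "beta_int",
                 "dispersion", "true_class"],
    ).set_index("gene_id")
    truth["true_ms_kdel"] = [signed_fold(x) for x in truth["beta_rig"]]
    truth["true_ms_sun1l"] = [
        signed_fold(x) for x in truth["beta_rig"] + truth["beta_int"]
    ]
    truth["true_ratio"] = truth["true_ms_sun1l"] / truth["true_ms_kdel"]
    return truth


def _assign_myosin_effects(truth: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Plant blebbistatin/Y27632 effects on an exact fraction of the genes
    that respond to SUN1L on the stiff substrate (deterministic: first k in
    gene-id order)."""
    stiff_genotype_effect = truth["beta_gen"] + truth["beta_int"]
    eligible = truth.index[np.abs(stiff_genotype_effect) > 1e-12].sort_values()
    k = int(round(config.myosin_overlap_fraction * len(eligible)))
    chosen = set(eligible[:k])
    beta_treat = np.zeros(len(truth))
    for i, gid in enumerate(truth.index):
        if gid in chosen:
            sign = np.sign(stiff_genotype_effect.loc[gid])
            mag = rng.uniform(config.effect_floor,
                              config.effect_floor + config.effect_window)
            beta_treat[i] = sign * mag
    truth = truth.copy()
    truth["beta_bleb"] = beta_treat
    truth["beta_y27"] = beta_treat  # same planted response to both inhibitors
    truth["myosin_dependent"] = truth.index.isin(chosen)
    return truth


def _design_rows(config: SimulationConfig):
    rows = []
    for genotype in ("KDEL", "SUN1L"):
        for rigidity in ("soft", "stiff"):
            for rep in range(1, config.n_reps + 1):
                rows.append((f"{genotype}_{rigidity}_r{rep}",
                             rigidity, genotype, "none", rep))
    if config.include_myosin_arms:
        for treatment, tag in (("blebbistatin", "bleb"), ("Y27632", "y27")):
            for rep in range(1, config.n_reps + 1):
                rows.append((f"KDEL_stiff_{tag}_r{rep}",
                             "stiff", "KDEL", treatment, rep))
    return rows


def _log2_means(truth: pd.DataFrame, rigidity: str, genotype: str,
                treatment: str) -> np.ndarray:
    eta = truth["b0"].to_numpy().copy()
    if rigidity == "stiff":
        eta = eta + truth["beta_rig"].to_numpy()
    if genotype == "SUN1L":
        eta = eta + truth["beta_gen"].to_numpy()
        if rigidity == "stiff":
            eta = eta + truth["beta_int"].to_numpy()
    if treatment == "blebbistatin":
        eta = eta + truth["beta_bleb"].to_numpy()
    elif treatment == "Y27632":
        eta = eta + truth["beta_y27"].to_numpy()
    return eta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson sample with mean mu and Var = mu + phi mu^2 (phi=0 -> Poisson)."""
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mu[~pois] * phi[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(config: SimulationConfig):
    """Simulate (CountMatrix, DesignTable, truth table) from a seeded config.

    Per sample s in condition cell c, the expected count of gene g is
    mu_gs = L_s * p_g(c) with p_g(c) the gene's relative abundance
    2^eta_g(c) normalized over genes, L_s the sample's library size.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config, rng)
    if config.include_myosin_arms:
        truth = _assign_myosin_effects(truth, config, rng)

    design_rows = _design_rows(config)
    n_samples = len(design_rows)
    sigma2 = math.log(1.0 + config.lib_size_cv ** 2)
    lib_sizes = rng.lognormal(
        math.log(config.mean_lib_size) - sigma2 / 2.0,
        math.sqrt(sigma2),
        size=n_samples,
    )

    phi = truth["dispersion"].to_numpy()
    columns = {}
    for (sample_id, rigidity, genotype, treatment, _rep), lib in zip(
        design_rows, lib_sizes
    ):
        eta = _log2_means(truth, rigidity, genotype, treatment)
        rel = np.exp2(eta)
        p = rel / rel.sum()
        mu = lib * p
        columns[sample_id] = _nb_draw(rng, mu, phi)

    counts = pd.DataFrame(columns, index=truth.index)
    counts.index.name = "gene_id"
    design = DesignTable(pd.DataFrame(
        design_rows,
        columns=["sample_id", "rigidity", "genotype", "treatment", "replicate"],
    ))
    return CountMatrix(counts), design, truth.reset_index()


# ---------------------------------------------------------------------------
# Auxiliary fixtures: confocal z-profiles and qPCR CT tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZProfile:
    """Axial intensity profile of a nucleus: positions (um) and intensities."""

    positions: np.ndarray
    intensities: np.ndarray
    true_fwhm: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.size < 3:
            raise ValueError("profile needs >= 3 points")
        if inten.shape != pos.shape:
            raise ValueError("positions and intensities differ in length")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.nanmax(inten) <= 0:
            raise ValueError("max intensity must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)


GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548... x sigma


def simulate_zprofiles(n: int, sigma_range=(0.8, 2.5), grid_step: float = 0.05,
                       noise_sd: float = 0.0, seed: int = 0,
                       span_sigmas: float = 5.0) -> list[ZProfile]:
    """Gaussian axial profiles with recorded true FWHM = 2*sqrt(2 ln 2)*sigma."""
    lo, hi = sigma_range
    if lo <= 0 or hi < lo:
        raise ValueError("sigma_range must be positive and ordered")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n):
        sigma = lo if hi == lo else rng.uniform(lo, hi)
        half_span = span_sigmas * sigma
        z = np.arange(-half_span, half_span + grid_step / 2, grid_step)
        intensity = np.exp(-0.5 * (z / sigma) ** 2)
        if noise_sd > 0:
            intensity = np.clip(intensity + rng.normal(0, noise_sd, z.size), 0, None)
        profiles.append(ZProfile(z, intensity, true_fwhm=GAUSSIAN_FWHM_FACTOR * sigma))
    return profiles


def simulate_qpcr(fold_changes, ct_reference: float = 18.0,
                  ct_target_calibrator: float = 24.0,
                  noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """CT tables realizing known fold changes under the 2^-ddCT model.

    Each requested fold F gets a sample whose target CT is shifted by
    -log2(F) relative to the calibrator, plus optional Gaussian CT noise.
    """
    folds = list(fold_changes)
    if any(f <= 0 for f in folds):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = [("calibrator", "calibrator", ct_target_calibrator, ct_reference, 1.0)]
    for i, f in enumerate(folds, 1):
        ct_t = ct_target_calibrator - math.log2(f)
        if noise_sd > 0:
            ct_t += rng.normal(0, noise_sd)
        ct_r = ct_reference + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((f"sample_{i}", "sample", ct_t, ct_r, f))
    return pd.DataFrame(
        rows, columns=["sample_id", "role", "ct_target", "ct_reference", "true_fold"]
    )


# ---------------------------------------------------------------------------
# Named scenarios used by the acceptance analyses
# ---------------------------------------------------------------------------

def null_scenario(seed: int, n_genes: int = 2000, n_reps: int = 3) -> SimulationConfig:
    """Global null: every gene flat across the 2x2 design."""
    return SimulationConfig(
        n_genes=n_genes,
        class_proportions={"null": 1.0},
        n_reps=n_reps,
        dispersion_range=(0.05, 0.5),
        seed=seed,
    )


def class_recovery_scenario(seed: int, n_per_class: int = 300,
                            n_null: int = 1100) -> SimulationConfig:
    """Planted gained/lost/reversed genes under strong, well-measured effects.

    Effects of at least 1.5 log2 units in each genotype arm, dispersions at
    most 0.05, and planted baseline abundances high enough that every planted
    gene has mean CPM >= 100 — conditions under which the interaction screen
    and the mechanosensitivity classifier are expected to recover truth.
    """
    n_genes = 3 * n_per_class + n_null
    frac = n_per_class / n_genes
    return SimulationConfig(
        n_genes=n_genes,
        class_proportions={
            "null": n_null / n_genes,
            "gained": frac,
            "lost": frac,
            "reversed": frac,
        },
        effect_floor=1.5,
        effect_window=1.5,
        n_reps=3,
        dispersion_range=(0.01, 0.05),
        planted_b0_range=(7.0, 10.0),
        seed=seed,
    )
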