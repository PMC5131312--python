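"""Morphometric and qPCR auxiliary computations.

Nuclear height from axial intensity profiles by full width at half maximum
(FWHM), nuclear aspect ratios, per-condition summaries (mean +/- s.e.m. with
pairwise one-way ANOVA flags), and relative qPCR quantification by the
2^-ddCT method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ZProfile  # shared profile container


class ProfileError(ValueError):
    pass


def fwhm(profile: ZProfile) -> float:
    """Full width at half maximum of an intensity profile.

    The half-max level is max/2; crossings are located by linear interpolation
    between bracketing samples, and the width spans the outermost ascending
    crossing (left of the peak) to the outermost descending crossing (right).
    """
    z = profile.positions
    y = profile.intensities
    peak = int(np.argmax(y))
    if peak == 0 or peak == len(y) - 1:
        raise ProfileError("profile maximum lies on the boundary")
    half = y[peak] / 2.0

    below_left = np.flatnonzero(y[:peak] < half)
    below_right = np.flatnonzero(y[peak + 1:] < half)
    if below_left.size == 0 or below_right.size == 0:
        raise ProfileError("unbounded peak: intensity never falls below half max")

    # outermost ascending crossing: first rise through half anywhere left of peak
    i = int(below_left[0])  # leftmost sample below half, ascending after it
    while y[i + 1] < half:
        i += 1
    left = _interp_crossing(z[i], y[i], z[i + 1], y[i + 1], half)

    # outermost descending crossing: last fall through half right of the peak
    j = peak + 1 + int(below_right[-1])  # rightmost sample below half
    while y[j - 1] < half:
        j -= 1
    right = _interp_crossing(z[j - 1], y[j - 1], z[j], y[j], half)
    return float(right - left)


def _interp_crossing(z0, y0, z1, y1, level) -> float:
    if y1 == y0:
        return float(z0)
    return float(z0 + (level - y0) * (z1 - z0) / (y1 - y0))


@dataclass(frozen=True)
class NucleusShape:
    height: float
    major_axis: float
    minor_axis: float
    rigidity: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if min(self.height, self.major_axis, self.minor_axis) <= 0:
            raise ValueError("all lengths must be positive")
        if self.minor_axis > self.major_axis:
            raise ValueError("minor axis exceeds major axis")

    @property
    def xz_aspect(self) -> float:
        return self.height / self.major_axis

    @property
    def xy_aspect(self) -> float:
        return self.minor_axis / self.major_axis


def aspect_ratios(height: float, major_axis: float, minor_axis: float):
    """(x-z, x-y) nuclear aspect ratios: height/major and minor/major.

    The x-z convention (height over the in-plane major axis) is a package
    choice; it is self-consistent with published summary magnitudes but the
    in-plane denominator is not uniquely determined by them.
    """
    shape = NucleusShape(height, major_axis, minor_axis)
    return shape.xz_aspect, shape.xy_aspect


def group_summary(values_by_condition: dict, compare: list | None = None,
                  alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition (n, mean, s.e.m.) plus pairwise one-way ANOVA flags.

    `compare` lists (condition_a, condition_b) pairs to test; by default all
    pairs. A two-group one-way ANOVA is an F test with df (1, n_a + n_b - 2).
    Conditions with n < 2 are summarized but never flagged.
    """
    summary_rows = []
    for cond in values_by_condition:
        v = np.asarray(values_by_condition[cond], dtype=float)
        sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size >= 2 else np.nan
        summary_rows.append((cond, v.size, float(v.mean()), sem))
    summary = pd.DataFrame(
        summary_rows, columns=["condition", "n", "mean", "sem"]
    ).set_index("condition")

    if compare is None:
        conds = list(values_by_condition)
        compare = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    pair_rows = []
    for a, b in compare:
        va = np.asarray(values_by_condition[a], dtype=float)
        vb = np.asarray(values_by_condition[b], dtype=float)
        if va.size < 2 or vb.size < 2:
            pair_rows.append((a, b, np.nan, np.nan, False))
            continue
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0 and va.mean() == vb.mean():
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(va, vb)
        pair_rows.append((a, b, float(f_stat), float(p), bool(p < alpha)))
    pairs = pd.DataFrame(
        pair_rows, columns=["condition_a", "condition_b", "F", "p", "significant"]
    )
    return summary, pairs


@dataclass(frozen=True)
class QpcrMeasurement:
    """CT of a target gene and of the endogenous reference in one sample."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (np.isfinite(v) and v > 0):
                raise ValueError("CT values must be positive and finite")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression by 2^-ddCT.

    ddCT = (CT_target - CT_reference)_sample - (CT_target - CT_reference)_calibrator.
    """
    ddct = sample.dct - calibrator.dct
    return float(2.0 ** (-ddct))


def ddct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Fold changes for every 'sample' row against the 'calibrator' row.

    Expects columns sample_id, role, ct_target, ct_reference with exactly one
    calibrator.
    """
    cal_rows = ct_table[ct_table["role"] == "calibrator"]
    if len(cal_rows) != 1:
        raise ValueError("CT table must contain exactly one calibrator row")
    cal = QpcrMeasurement(float(cal_rows["ct_target"].iloc[0]),
                          float(cal_rows["ct_reference"].iloc[0]))
    rows = []
    for _, r in ct_table[ct_table["role"] == "sample"].iterrows():
        m = QpcrMeasurement(float(r["ct_target"]), float(r["ct_reference"]))
        rows.append((r["sample_id"], m.dct - cal.dct, ddct_fold(m, cal)))
    return pd.DataFrame(rows, columns=["sample_id", "ddct", "fold"])


def load_morphometry_summary() -> pd.DataFrame:
    """Published group summaries (mean, s.e.m.) of nuclear shape and cell
    spreading for KDEL/SUN1L fibroblasts on 1 and 308 kPa substrates."""
    ref = resources.files("mechanoseq.data").joinpath("morphometry_summary.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
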