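"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a statistic by direct enumeration or spreadsheet-style
arithmetic, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tmm_factor_brute(y_s, y_r, trim_m=0.30, trim_a=0.05):
    """Spreadsheet-style TMM: explicit per-gene table, sorted trims, weighted mean."""
    y_s = [float(v) for v in y_s]
    y_r = [float(v) for v in y_r]
    n_s, n_r = sum(y_s), sum(y_r)
    table = []
    for idx, (a, b) in enumerate(zip(y_s, y_r)):
        if a > 0 and b > 0:
            m = math.log2((a / n_s) / (b / n_r))
            av = 0.5 * math.log2((a / n_s) * (b / n_r))
            w = 1.0 / ((n_s - a) / (n_s * a) + (n_r - b) / (n_r * b))
            table.append((idx, m, av, w))
    k_m = math.floor(trim_m * len(table))
    k_a = math.floor(trim_a * len(table))
    by_m = sorted(table, key=lambda t: (t[1], t[0]))
    by_a = sorted(table, key=lambda t: (t[2], t[0]))
    keep_m = {t[0] for t in by_m[k_m:len(by_m) - k_m]}
    keep_a = {t[0] for t in by_a[k_a:len(by_a) - k_a]}
    kept = [t for t in table if t[0] in keep_m and t[0] in keep_a]
    num = sum(t[3] * t[1] for t in kept)
    den = sum(t[3] for t in kept)
    return 2.0 ** (num / den)


def bh_brute(p_values):
    """BH step-up by direct enumeration: q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def anova_2x2_brute(cells):
    """Two-way balanced ANOVA from first principles on a dict
    (rigidity, genotype) -> list of replicate values."""
    order = [("soft", "KDEL"), ("soft", "SUN1L"), ("stiff", "KDEL"), ("stiff", "SUN1L")]
    data = {k: [float(v) for v in cells[k]] for k in order}
    r = len(data[order[0]])
    all_vals = [v for k in order for v in data[k]]
    n = len(all_vals)
    grand = sum(all_vals) / n
    cell_mean = {k: sum(v) / r for k, v in data.items()}

    def level_mean(factor, level):
        vals = [v for k, vs in data.items() for v in vs
                if (k[0] if factor == "rigidity" else k[1]) == level]
        return sum(vals) / len(vals)

    ss_rig = sum(2 * r * (level_mean("rigidity", lv) - grand) ** 2
                 for lv in ("soft", "stiff"))
    ss_gen = sum(2 * r * (level_mean("genotype", lv) - grand) ** 2
                 for lv in ("KDEL", "SUN1L"))
    ss_int = sum(
        r * (cell_mean[k] - level_mean("rigidity", k[0])
             - level_mean("genotype", k[1]) + grand) ** 2
        for k in order
    )
    ss_res = sum((v - cell_mean[k]) ** 2 for k, vs in data.items() for v in vs)
    ss_tot = sum((v - grand) ** 2 for v in all_vals)
    df_res = n - 4
    ms_res = ss_res / df_res
    from scipy.stats import f as fdist
    out = {}
    for name, ss in (("rigidity", ss_rig), ("genotype", ss_gen),
                     ("interaction", ss_int)):
        f_stat = ss / ms_res
        out[f"F_{name}"] = f_stat
        out[f"p_{name}"] = float(fdist.sf(f_stat, 1, df_res))
    out["ss_total"] = ss_tot
    out["ss_parts"] = ss_rig + ss_gen + ss_int + ss_res
    return out


def spearman_brute(x, y):
    """Rank correlation with midranks, via explicit rank tables and Pearson."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def hypergeom_upper_brute(k, population, successes, draws):
    """P(X >= k) by exhaustive enumeration of draws from the population."""
    pop = list(range(population))
    succ = set(pop[:successes])
    total = 0
    at_least = 0
    for combo in itertools.combinations(pop, draws):
        total += 1
        if len(succ.intersection(combo)) >= k:
            at_least += 1
    return at_least / total


def welch_z_brute(a, b):
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    z = (ma - mb) / math.sqrt(va / na + vb / nb)
    from scipy.stats import norm
    return z, 2 * float(norm.sf(abs(z)))


def fwhm_brute(z, y):
    """All half-max crossings by dense linear interpolation; outermost span."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    half = y.max() / 2.0
    crossings = []
    for i in range(len(z) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - half) * (y1 - half) < 0:
            crossings.append(z[i] + (half - y0) * (z[i + 1] - z[i]) / (y1 - y0))
        elif y0 == half:
            crossings.append(z[i])
    if y[-1] == half:
        crossings.append(z[-1])
    peak = z[np.argmax(y)]
    left = [c for c in crossings if c < peak]
    right = [c for c in crossings if c > peak]
    return max(right) - min(left)
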