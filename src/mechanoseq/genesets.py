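"""Directional gene-list intersections, Venn region counts, and hypergeometric
over-representation of annotation sets.

The over-representation test is a desk-scale stand-in for web annotation
services: upper-tail hypergeometric p for the overlap between a query list and
each annotation term against a finite gene universe, BH-adjusted across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class SignedGeneList:
    """A labeled perturbation response: gene id -> signed fold change."""

    label: str
    entries: dict

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.entries.items() if abs(v) < 1.0}
        if bad:
            raise ValueError(f"|signed_fc| must be >= 1; offending: {bad}")


def signed_list_from_de(label: str, de: pd.DataFrame,
                        significant_only: bool = True) -> SignedGeneList:
    sub = de[de["significant"]] if significant_only else de
    return SignedGeneList(label, dict(zip(sub.index, sub["signed_fc"])))


def directional_intersection(lists, fc_min: float = 2.0) -> pd.DataFrame:
    """Genes responding the same way to every perturbation.

    A gene qualifies when it appears in every list with |signed_fc| >= fc_min
    and the same sign throughout — the "similar in direction and a minimum
    magnitude" rule.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("directional intersection needs >= 2 lists")
    if fc_min < 1.0:
        raise ValueError("fc_min must be >= 1")
    labels = [lst.label for lst in lists]
    if len(set(labels)) != len(labels):
        raise ValueError("list labels must be unique")
    common = set(lists[0].entries)
    for lst in lists[1:]:
        common &= set(lst.entries)
    rows = []
    for gene in sorted(common):
        vals = [lst.entries[gene] for lst in lists]
        if all(abs(v) >= fc_min for v in vals) and len({np.sign(v) for v in vals}) == 1:
            rows.append([gene] + vals)
    return pd.DataFrame(rows, columns=["gene_id"] + labels).set_index("gene_id")


def venn_counts(*sets):
    """Region counts of a 2- or 3-set Venn diagram.

    Two sets: (|A only|, |A and B|, |B only|). Three sets: dict keyed by
    membership pattern '100', '110', ... (A, B, C order), 7 regions.
    """
    sets = [set(s) for s in sets]
    if len(sets) == 2:
        a, b = sets
        return (len(a - b), len(a & b), len(b - a))
    if len(sets) == 3:
        a, b, c = sets
        regions = {}
        for pattern in ("100", "010", "001", "110", "101", "011", "111"):
            inc = [s for s, bit in zip(sets, pattern) if bit == "1"]
            exc = [s for s, bit in zip(sets, pattern) if bit == "0"]
            region = set.intersection(*inc) - set().union(*exc)
            regions[pattern] = len(region)
        return regions
    raise ValueError("venn_counts supports 2 or 3 sets")


def overrepresentation(query, annotations: dict, universe,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query set.

    p = P(X >= k) with population |universe|, successes |term|, draws |query|;
    BH-adjusted q across terms. Terms are restricted to the universe before
    testing; the query must lie inside the universe.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    rows = []
    m = len(universe)
    n_query = len(query)
    for term in sorted(annotations):
        members = set(annotations[term]) & universe
        if len(set(annotations[term])) > m:
            raise ValueError(f"term {term!r} larger than the universe")
        k = len(members & query)
        expected = n_query * len(members) / m
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        rows.append((term, len(members), k, expected, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "expected", "p"]
    ).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.sort_values(["p", "term"])
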