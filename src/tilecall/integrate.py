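"""Crossing bound-gene and differential-expression lists, plus gene-set
over-representation with hypergeometric tests and BH correction."""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["harmonize_gene_id", "venn2", "cross_bound_and_regulated",
           "GeneSetCollection", "set_enrichment"]


def harmonize_gene_id(gene_id: str) -> str:
    """Case-fold and strip a trailing version suffix (``Gene.2`` -> ``gene``)."""
    return re.sub(r"\.\d+$", "", str(gene_id).strip()).casefold()


def _unique_harmonized(genes, label: str) -> set:
    harmonized = [harmonize_gene_id(g) for g in genes]
    out = set(harmonized)
    if len(out) < len(harmonized):
        warnings.warn(f"duplicate gene ids collapsed in {label}")
    return out


def venn2(list_a, list_b) -> tuple[int, int, int]:
    """Two-way Venn partition counts: (|A∩B|, |A only|, |B only|)."""
    a = _unique_harmonized(list_a, "list A")
    b = _unique_harmonized(list_b, "list B")
    return len(a & b), len(a - b), len(b - a)


def cross_bound_and_regulated(bound_genes, up_list, down_list) -> pd.DataFrame:
    """Cross a bound-gene list with up/down expression calls.

    Returns one row per gene appearing in any input, with columns
    ``gene_id``, ``bound`` and ``call``; summary counts are stored in
    ``attrs["summary"]`` (bound_and_up, bound_and_down, bound_only,
    up_only, down_only).

    Raises
    ------
    ValueError
        If a gene appears in both the up and down lists.
    """
    bound = _unique_harmonized(bound_genes, "bound list")
    up = _unique_harmonized(up_list, "up list")
    down = _unique_harmonized(down_list, "down list")
    both = up & down
    if both:
        raise ValueError(f"gene(s) in both up and down lists: {sorted(both)[:5]}")
    rows = []
    for g in sorted(bound | up | down):
        call = "up" if g in up else ("down" if g in down else "unchanged")
        rows.append(dict(gene_id=g, bound=g in bound, call=call))
    out = pd.DataFrame(rows, columns=["gene_id", "bound", "call"])
    out.attrs["summary"] = dict(
        bound_and_up=len(bound & up),
        bound_and_down=len(bound & down),
        bound_only=len(bound - up - down),
        up_only=len(up - bound),
        down_only=len(down - bound),
    )
    return out


class GeneSetCollection:
    """Named gene sets over a common gene universe.

    Members outside the universe are dropped (with a warning) so that the
    hypergeometric model's sampling frame is consistent.
    """

    def __init__(self, sets: dict, universe):
        self.universe = _unique_harmonized(universe, "universe")
        if not self.universe:
            raise ValueError("gene universe must be non-empty")
        self.sets = {}
        for set_id, members in sets.items():
            harmonized = _unique_harmonized(members, f"set {set_id}")
            outside = harmonized - self.universe
            if outside:
                warnings.warn(f"{len(outside)} member(s) of {set_id} outside "
                              "the universe were dropped")
            self.sets[set_id] = harmonized & self.universe

    @classmethod
    def from_gmt(cls, path, universe=None):
        from .io import read_gmt
        sets = read_gmt(path)
        if universe is None:
            universe = sorted({g for members in sets.values() for g in members})
        return cls(sets, universe)


def set_enrichment(query, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided over-representation test of a query list against each set.

    For each set, with N = |universe|, m = |set|, n = |query| and
    k = |query ∩ set|, the p value is the hypergeometric upper tail
    P[X >= k]; Benjamini–Hochberg correction is applied across sets.
    Query genes outside the universe are dropped with a warning.

    Returns a table sorted by adjusted p with columns set_id, k, m, n, N,
    p_value, bh_adjusted_p.
    """
    q = _unique_harmonized(query, "query")
    outside = q - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe "
                      "were dropped")
        q &= collection.universe
    N, n = len(collection.universe), len(q)
    rows = []
    for set_id, members in collection.sets.items():
        m = len(members)
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, N, m, n))  # P[X >= k]
        rows.append(dict(set_id=set_id, k=k, m=m, n=n, N=N,
                         p_value=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("bh_adjusted_p", kind="mergesort").reset_index(drop=True)
    else:
        out["bh_adjusted_p"] = []
    return out
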