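"""Bench-validation statistics: qPCR relative expression, ChIP-qPCR
relative recruitment and an exact Mann–Whitney U test.

qPCR quantification assumes a fixed amplification efficiency of 2 per
cycle (the delta-delta-Ct model) unless another efficiency is given.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["relative_expression", "chip_relative_recruitment",
           "mann_whitney_exact", "EXACT_ENUMERATION_LIMIT"]

#: exact null enumeration is used while n_a * n_b does not exceed this
EXACT_ENUMERATION_LIMIT = 64


def relative_expression(measurements: pd.DataFrame, control_group: str,
                        efficiency: float = 2.0) -> pd.DataFrame:
    """Per-sample fold change of a target gene over a reference gene.

    dCt = target_ct - reference_ct per sample; fold =
    efficiency**-(dCt - mean dCt of the control group), so the control
    group's mean log-fold is 0 and its geometric-mean fold is exactly 1.
    Samples missing a reference Ct are excluded with a warning.  Group
    mean ± SD of the folds is stored in ``attrs["group_stats"]``.
    """
    df = measurements.copy()
    missing = df["reference_ct"].isna() | df["target_ct"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} sample(s) without complete Ct "
                      "values were excluded")
        df = df.loc[~missing]
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    dct = df["target_ct"].to_numpy(float) - df["reference_ct"].to_numpy(float)
    control_mean = dct[(df["group"] == control_group).to_numpy()].mean()
    df["delta_ct"] = dct
    df["fold"] = efficiency ** -(dct - control_mean)
    stats = df.groupby("group")["fold"].agg(["mean", "std"])
    df.attrs["group_stats"] = {g: (float(r["mean"]), float(r["std"]))
                               for g, r in stats.iterrows()}
    return df


def chip_relative_recruitment(measurements: pd.DataFrame,
                              igg_label: str = "IgG") -> pd.DataFrame:
    """Fold recruitment over the nonspecific-antibody control, per locus.

    Each row's percent input is bound_signal / input_signal; relative
    recruitment divides it by the IgG row's percent input at the same
    locus, so the IgG control is exactly 1 in every calculation.
    """
    df = measurements.copy()
    if (df["input_signal"] <= 0).any():
        raise ValueError("input_signal must be positive")
    df["percent_input"] = df["bound_signal"] / df["input_signal"]
    igg = df[df["antibody"] == igg_label].set_index("locus_id")["percent_input"]
    rel = []
    for row in df.itertuples(index=False):
        if row.locus_id not in igg.index:
            raise ValueError(f"locus {row.locus_id!r} has no {igg_label} row")
        denom = igg.loc[row.locus_id]
        if denom == 0:
            raise ValueError(
                f"{igg_label} percent input is 0 at locus {row.locus_id!r}; "
                "relative recruitment undefined")
        rel.append(row.percent_input / denom)
    df["relative_recruitment"] = rel
    return df


def mann_whitney_exact(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U with an exact two-sided p for small samples.

    Returns ``(U, p)`` where U = min(U_a, U_b).  While n_a·n_b <= 64 the
    null distribution is enumerated over all C(n, n_a) assignments of the
    pooled mid-ranks (so ties are handled exactly as a permutation test);
    beyond that a normal approximation with tie correction and continuity
    correction is used.  Two-sided p = min(1, 2·one-sided), symmetric in
    the two groups.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    ua = ranks[:na].sum() - na * (na + 1) / 2
    ub = na * nb - ua
    u = min(ua, ub)

    if na * nb <= EXACT_ENUMERATION_LIMIT:
        n = na + nb
        offset = na * (na + 1) / 2
        le = ge = total = 0
        for idx in itertools.combinations(range(n), na):
            ua_perm = ranks[list(idx)].sum() - offset
            # tolerance guards float rank sums at ties
            if ua_perm <= ua + 1e-9:
                le += 1
            if ua_perm >= ua - 1e-9:
                ge += 1
            total += 1
        one_sided = min(le, ge) / total
    else:
        mean = na * nb / 2
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        var = na * nb / 12 * (n + 1 - tie_term)
        if var == 0:
            return float(u), 1.0
        one_sided = float(norm.cdf((u + 0.5 - mean) / np.sqrt(var)))
    return float(u), float(min(1.0, 2 * one_sided))
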