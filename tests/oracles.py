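"""Independent brute-force oracles the test suite checks the pipeline
against.  Everything here applies the published rules literally and
naively; nothing is shared with the implementation under test."""

import itertools

import numpy as np
from scipy.stats import norm


def stouffer_oracle_mpmath(p1, p2, p3, dps=50):
    """Arbitrary-precision Stouffer combination via mpmath."""
    from mpmath import mp, erfinv, ncdf, sqrt
    with mp.workdps(dps):
        zs = [sqrt(2) * erfinv(1 - 2 * mp.mpf(p)) for p in (p1, p2, p3)]
        return float(1 - ncdf(sum(zs) / sqrt(3)))


def bound_regions_oracle(scores, max_gap=1000):
    """Enumerate every 3-consecutive-probe window, apply both filter rules
    literally, and union the intervals of passing windows.

    ``scores`` must be sorted by (chrom, start).  Returns a set of
    (chrom, start, end) tuples.
    """
    chrom = list(scores["chrom"])
    start = list(scores["start"])
    end = list(scores["end"])
    p = list(scores["p_single"])
    n = len(scores)

    def window_ok(i):  # window centered on probe i
        if i - 1 < 0 or i + 1 >= n:
            return False
        if chrom[i - 1] != chrom[i] or chrom[i] != chrom[i + 1]:
            return False
        if start[i] - end[i - 1] > max_gap or start[i + 1] - end[i] > max_gap:
            return False
        return True

    def combined(i):
        zs = [norm.isf(max(p[j], 1e-300)) for j in (i - 1, i, i + 1)]
        return max(float(norm.sf(sum(zs) / np.sqrt(3.0))), 1e-300)

    passing = []
    for i in range(n):
        if not window_ok(i):
            continue
        pc, pl, pr = p[i], p[i - 1], p[i + 1]
        comb = combined(i)
        promoter = pc < 0.001 and min(pl, pr) < 0.01 and comb < 0.001
        flank_combs = [combined(j) for j in (i - 1, i + 1) if window_ok(j)]
        transcribed = (pc < 0.005 and comb < 0.0001
                       and any(fc < 0.001 for fc in flank_combs))
        if promoter or transcribed:
            passing.append((chrom[i], start[i - 1], end[i + 1]))

    regions = set()
    for c in sorted({w[0] for w in passing}):
        ivs = sorted((s, e) for cc, s, e in passing if cc == c)
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_s is not None and s < cur_e:
                cur_e = max(cur_e, e)
            else:
                if cur_s is not None:
                    regions.add((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            regions.add((c, cur_s, cur_e))
    return regions


def random_score_table(rng, max_probes=500):
    """A random probe-score table exercising gaps, chromosomes and the
    full range of P values around the filter thresholds."""
    import pandas as pd
    n = int(rng.integers(3, max_probes + 1))
    n_chrom = int(rng.integers(1, 4))
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=n))
    pos = np.zeros(n, dtype=int)
    for c in np.unique(chroms):
        sel = chroms == c
        gaps = rng.choice([150, 400, 900, 1500, 5000], size=int(sel.sum()),
                          p=[0.55, 0.2, 0.1, 0.1, 0.05])
        pos[sel] = np.cumsum(gaps)
    mix = rng.random(n)
    p = np.where(mix < 0.6, rng.random(n), 10.0 ** -(rng.random(n) * 6))
    return pd.DataFrame(dict(
        probe_id=[f"p{i}" for i in range(n)],
        chrom=[f"chr{c}" for c in chroms],
        start=pos, end=pos + 50,
        A=10.0, ratio_log2=rng.normal(0, 1, size=n),
        p_single=np.maximum(p, 1e-300),
    ))


def hypergeom_enumeration_oracle(universe_size, set_size, query_size, k):
    """P[X >= k] by exhaustive enumeration of all draws of ``query_size``
    elements from a universe whose first ``set_size`` elements are the set."""
    hits = total = 0
    for draw in itertools.combinations(range(universe_size), query_size):
        total += 1
        if sum(1 for x in draw if x < set_size) >= k:
            hits += 1
    return hits / total


def mwu_oracle(a, b):
    """Exact Mann–Whitney (U, two-sided p) by enumerating group
    assignments and counting pairs directly (no rank sums)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(idx):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        gt = (ga[:, None] > gb[None, :]).sum()
        eq = (ga[:, None] == gb[None, :]).sum()
        return gt + 0.5 * eq

    ua_obs = u_stat(range(na))
    le = ge = total = 0
    for idx in itertools.combinations(range(n), na):
        u = u_stat(idx)
        if u <= ua_obs + 1e-9:
            le += 1
        if u >= ua_obs - 1e-9:
            ge += 1
        total += 1
    ub_obs = na * (len(b)) - ua_obs
    one_sided = min(le, ge) / total
    return min(ua_obs, ub_obs), min(1.0, 2 * one_sided)
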