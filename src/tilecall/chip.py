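"""ChIP-on-chip bound-region calling from IP-vs-input tiling arrays.

The procedure scores each probe with a single-point confidence value from
a whole-array error model, slides a 3-probe window along each chromosome,
applies two filter rules on the single-point and combined P values, and
collapses overlapping passing windows into bound regions that are then
assigned to their nearest gene.

Error model
-----------
The normalized log2(IP/input) ratios are grouped into intensity bins
(deciles of mean log intensity, bins with fewer than 20 probes merged into
a neighbor).  Within a bin the null location and scale are estimated
robustly as the median and 1.4826x the median absolute deviation, so that
enriched probes do not inflate the null.  The single-point P value is the
upper-tail normal probability of the resulting z score: small p means the
probe's ratio is high for its intensity class.

Filter rules (strict inequalities throughout)
---------------------------------------------
*Promoter filter*: center probe p < 0.001, at least one flanking probe
p < 0.01, combined P < 0.001.

*Transcribed-region filter* (for broad binding spanning several probes):
center probe p < 0.005, combined P < 0.0001, and at least one flanking
probe whose own 3-probe window has combined P < 0.001.  At array edges,
where a flanking probe has no window of its own, that clause fails.

A window passing either rule counts as bound.  Combined P values use
Stouffer's equal-weight method.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

from .expression import lowess_normalize

__all__ = [
    "score_probes", "combine_probe_set", "build_probe_sets",
    "apply_promoter_filter", "apply_transcribed_filter",
    "collapse_bound_regions", "assign_closest_orf",
    "cluster_binding_profiles", "ChipBindingModel", "ChipBindingResults",
]

P_FLOOR = 1e-300

PROMOTER_FILTER = dict(center=1e-3, flank_single=1e-2, combined=1e-3)
TRANSCRIBED_FILTER = dict(center=5e-3, combined=1e-4, flank_combined=1e-3)


def _merge_small_bins(bin_idx: np.ndarray, n_bins: int, min_count: int):
    """Merge adjacent intensity bins until each holds >= min_count probes."""
    edges = list(range(n_bins))  # bin labels in intensity order
    groups = [[b] for b in edges]
    counts = [int(np.sum(bin_idx == b)) for b in edges]
    merged = False
    while len(groups) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        j = i - 1 if i > 0 else i + 1
        groups[j] = groups[j] + groups[i]
        counts[j] += counts[i]
        del groups[i], counts[i]
        merged = True
    if merged:
        warnings.warn("intensity bins with < %d probes were merged" % min_count)
    relabel = np.empty(n_bins, dtype=int)
    for g, members in enumerate(groups):
        for b in members:
            relabel[b] = g
    return relabel[bin_idx]


def score_probes(spots: pd.DataFrame, n_bins: int = 10,
                 lowess_frac: float = 0.3, min_bin_count: int = 20) -> pd.DataFrame:
    """Score QC-passed probes with normalized ratios and confidence values.

    Returns a probe-score table sorted by (chrom, start) with columns
    probe_id, chrom, start, end, A, ratio_log2, p_single.
    """
    if len(spots) < 500:
        raise ValueError(
            f"error-model estimation needs >= 500 probes, got {len(spots)}")
    norm_tab = lowess_normalize(spots, frac=lowess_frac)
    scores = pd.DataFrame(dict(
        probe_id=spots["probe_id"].to_numpy(),
        chrom=spots["chrom"].to_numpy(),
        start=spots["start"].to_numpy(int),
        end=spots["end"].to_numpy(int),
        A=norm_tab["A"].to_numpy(),
        ratio_log2=norm_tab["M_norm"].to_numpy(),
    ))
    if scores.duplicated(["chrom", "start"]).any():
        raise ValueError("duplicate probe coordinates in spot table")

    A = scores["A"].to_numpy()
    quantiles = np.quantile(A, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(quantiles, A, side="right") - 1,
                      0, n_bins - 1)
    bin_idx = _merge_small_bins(bin_idx, n_bins, min_bin_count)

    m = scores["ratio_log2"].to_numpy()
    z = np.empty_like(m)
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        med = np.median(m[sel])
        mad = np.median(np.abs(m[sel] - med))
        scale = 1.4826 * mad
        if scale <= 0:
            scale = max(np.std(m[sel]), 1e-9)
        z[sel] = (m[sel] - med) / scale
    scores["p_single"] = np.maximum(norm.sf(z), P_FLOOR)
    scores = scores.sort_values(["chrom", "start"], kind="mergesort")
    return scores.reset_index(drop=True)


def combine_probe_set(p_center, p_flank1, p_flank2):
    """Combine three single-point P values by Stouffer's method.

    z_i = Phi^{-1}(1 - p_i); combined P = 1 - Phi((z1+z2+z3)/sqrt(3)).
    Symmetric in its arguments; inputs of exactly 0 are clamped to 1e-300
    with a warning.  Accepts scalars or arrays.
    """
    p = np.stack(np.broadcast_arrays(np.asarray(p_center, float),
                                     np.asarray(p_flank1, float),
                                     np.asarray(p_flank2, float)))
    if np.any(p == 0):
        warnings.warn("P value of 0 clamped to 1e-300 before combining")
        p = np.maximum(p, P_FLOOR)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    z = np.sort(norm.isf(p), axis=0)  # fixed order => exact symmetry
    combined = np.maximum(norm.sf(z.sum(axis=0) / np.sqrt(3.0)), P_FLOOR)
    return float(combined) if combined.ndim == 0 else combined


def build_probe_sets(scores: pd.DataFrame, max_gap: int = 1000) -> pd.DataFrame:
    """Slide a 3-probe window (stride 1) along each chromosome.

    A window exists for every probe whose two neighbors lie on the same
    chromosome with an inter-probe gap (end of one to start of the next)
    of at most ``max_gap``.  Chromosomes with fewer than 3 probes yield no
    windows.

    Returns a probe-set table with columns chrom, start, end, center_index
    (row index of the center probe in ``scores``), p_center, p_flank1,
    p_flank2, p_combined.
    """
    chrom = scores["chrom"].to_numpy()
    start = scores["start"].to_numpy()
    end = scores["end"].to_numpy()
    p = scores["p_single"].to_numpy()
    n = len(scores)
    if n < 3:
        return _empty_sets()

    same = (chrom[:-1] == chrom[1:]) & (start[1:] - end[:-1] <= max_gap)
    # window centered at i needs links (i-1,i) and (i,i+1)
    ok = same[:-1] & same[1:]
    centers = np.flatnonzero(ok) + 1
    if centers.size == 0:
        return _empty_sets()
    sets = pd.DataFrame(dict(
        chrom=chrom[centers],
        start=start[centers - 1],
        end=end[centers + 1],
        center_index=centers,
        p_center=p[centers],
        p_flank1=p[centers - 1],
        p_flank2=p[centers + 1],
    ))
    sets["p_combined"] = combine_probe_set(
        sets["p_center"], sets["p_flank1"], sets["p_flank2"])
    return sets


def _empty_sets() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "center_index",
                                 "p_center", "p_flank1", "p_flank2",
                                 "p_combined"])


def apply_promoter_filter(sets: pd.DataFrame,
                          thresholds: dict = PROMOTER_FILTER) -> np.ndarray:
    """Boolean mask of windows passing the promoter-binding rule."""
    return (
        (sets["p_center"].to_numpy() < thresholds["center"])
        & (np.minimum(sets["p_flank1"], sets["p_flank2"]).to_numpy()
           < thresholds["flank_single"])
        & (sets["p_combined"].to_numpy() < thresholds["combined"])
    )


def apply_transcribed_filter(sets: pd.DataFrame,
                             thresholds: dict = TRANSCRIBED_FILTER) -> np.ndarray:
    """Boolean mask of windows passing the transcribed-region rule.

    The flanking clause asks for the combined P of the window *centered on
    a flanking probe*; a flank with no window of its own (array edge or a
    gap) fails the clause.
    """
    by_center = pd.Series(sets["p_combined"].to_numpy(),
                          index=sets["center_index"].to_numpy())
    centers = sets["center_index"].to_numpy()
    left = by_center.reindex(centers - 1).to_numpy()
    right = by_center.reindex(centers + 1).to_numpy()
    flank_comb = np.fmin(left, right)  # NaN-tolerant; both missing -> NaN
    flank_ok = np.where(np.isnan(flank_comb), False,
                        flank_comb < thresholds["flank_combined"])
    return (
        (sets["p_center"].to_numpy() < thresholds["center"])
        & (sets["p_combined"].to_numpy() < thresholds["combined"])
        & flank_ok
    )


def collapse_bound_regions(passing_sets: pd.DataFrame,
                           scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping passing windows into disjoint bound regions.

    Each region is the interval union of its member windows' probe spans
    and reports the number of member windows, the maximum enrichment
    (linear fold, ``2**max(ratio_log2)`` over member probes) and the best
    combined P value.  Idempotent: collapsing a set of already-disjoint
    windows returns them unchanged.
    """
    cols = ["chrom", "start", "end", "n_probe_sets", "max_enrichment", "best_p"]
    if len(passing_sets) == 0:
        return pd.DataFrame(columns=cols)
    ratio = scores["ratio_log2"].to_numpy()
    sets = passing_sets.sort_values(["chrom", "start", "end"], kind="mergesort")
    regions = []
    cur = None
    for row in sets.itertuples(index=False):
        c = int(row.center_index)
        max_ratio = float(np.max(ratio[c - 1:c + 2]))
        if cur is not None and row.chrom == cur["chrom"] and row.start < cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["n_probe_sets"] += 1
            cur["max_ratio"] = max(cur["max_ratio"], max_ratio)
            cur["best_p"] = min(cur["best_p"], row.p_combined)
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(chrom=row.chrom, start=int(row.start), end=int(row.end),
                       n_probe_sets=1, max_ratio=max_ratio,
                       best_p=float(row.p_combined))
    regions.append(cur)
    out = pd.DataFrame(regions)
    out["max_enrichment"] = 2.0 ** out.pop("max_ratio")
    return out[cols]


def assign_closest_orf(regions: pd.DataFrame, annotation: pd.DataFrame,
                       mode: str = "tss") -> pd.DataFrame:
    """Assign each bound region to its closest gene.

    By default distance is from the region midpoint to the gene TSS
    (``mode="tss"``); ``mode="orf"`` measures to the nearest ORF boundary
    instead (zero inside the ORF).  Ties prefer the + strand, then the
    lexicographically smaller gene id.  ``tss_distance`` is signed in the
    gene's reading direction: negative values lie upstream of the TSS.
    """
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    if mode not in ("tss", "orf"):
        raise ValueError("mode must be 'tss' or 'orf'")
    out = regions.copy()
    gene_ids, tss_dists = [], []
    ann_by_chrom = dict(tuple(annotation.groupby("chrom")))
    for row in regions.itertuples(index=False):
        mid = 0.5 * (row.start + row.end)
        ann = ann_by_chrom.get(row.chrom)
        if ann is None:
            gene_ids.append(None)
            tss_dists.append(np.nan)
            continue
        if mode == "tss":
            dist = np.abs(mid - ann["tss"].to_numpy(float))
        else:
            lo = ann["orf_start"].to_numpy(float)
            hi = ann["orf_end"].to_numpy(float)
            dist = np.where((mid >= lo) & (mid < hi), 0.0,
                            np.minimum(np.abs(mid - lo), np.abs(mid - hi)))
        order = np.lexsort((ann["gene_id"].to_numpy(),
                            (ann["strand"] != "+").to_numpy(), dist))
        best = ann.iloc[order[0]]
        gene_ids.append(best["gene_id"])
        signed = mid - best["tss"] if best["strand"] == "+" else best["tss"] - mid
        tss_dists.append(float(signed))
    out["gene_id"] = gene_ids
    out["tss_distance"] = tss_dists
    return out


def cluster_binding_profiles(scores: pd.DataFrame, regions: pd.DataFrame,
                             annotation: pd.DataFrame, k: int = 5,
                             n_bins: int = 20, seed: int = 0,
                             window: int = 2000) -> pd.Series:
    """Group bound genes by the shape of binding along their promoter.

    For each gene with at least one bound region, the normalized probe
    ratios across its promoter window are interpolated onto ``n_bins``
    positions relative to the TSS (strand-oriented, so profiles from +
    and - strand genes align) and standardized per gene.  Profiles are
    clustered by k-means (10 restarts, fixed seed) and labels are
    renumbered by descending cluster size, so the largest cluster is
    always 0.

    Returns a Series mapping gene_id -> cluster label.
    """
    bound = [g for g in regions["gene_id"].dropna().unique()]
    if len(bound) < k:
        raise ValueError(f"need >= k={k} bound genes, got {len(bound)}")
    ann = annotation.set_index("gene_id")
    has_window = {"promoter_start", "promoter_end"}.issubset(annotation.columns)
    profiles = []
    for g in bound:
        info = ann.loc[g]
        tss = float(info["tss"])
        if has_window:
            lo, hi = float(info["promoter_start"]), float(info["promoter_end"])
        elif info["strand"] == "+":
            lo, hi = tss - window, tss
        else:
            lo, hi = tss, tss + window
        sel = scores[(scores["chrom"] == info["chrom"])
                     & (scores["start"] < hi) & (scores["end"] > lo)]
        mids = 0.5 * (sel["start"].to_numpy(float) + sel["end"].to_numpy(float))
        # upstream distance from the TSS, in reading orientation
        rel = (tss - mids) if info["strand"] == "+" else (mids - tss)
        order = np.argsort(rel)
        rel, vals = rel[order], sel["ratio_log2"].to_numpy()[order]
        grid = np.linspace(0, hi - lo, n_bins)
        prof = (np.interp(grid, rel, vals) if len(rel)
                else np.zeros(n_bins))
        # scale floor: profiles flatter than 0.25 log2 units are shapeless;
        # dividing by their tiny sd would amplify noise into spurious shape
        profiles.append((prof - prof.mean()) / max(prof.std(), 0.25))
    X = np.asarray(profiles)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="mergesort")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return pd.Series(relabel[km.labels_], index=pd.Index(bound, name="gene_id"),
                     name="cluster")


class ChipBindingModel:
    """Bound-region calling model for one pooled IP-vs-input tiling array.

    Parameters
    ----------
    spots : spot table (QC-passed; background subtraction applied if the
        net-intensity columns are absent)
    annotation : gene annotation table
    max_gap : maximum inter-probe gap inside a 3-probe window, bp
    n_bins : intensity bins for the error model
    assign_mode : "tss" (default) or "orf" for closest-gene assignment

    The error model is re-estimated per array, so arrays from different
    conditions get their own null location and scale.
    """

    def __init__(self, spots, annotation, max_gap: int = 1000,
                 n_bins: int = 10, lowess_frac: float = 0.3,
                 assign_mode: str = "tss"):
        self.spots = spots
        self.annotation = annotation
        self.max_gap = max_gap
        self.n_bins = n_bins
        self.lowess_frac = lowess_frac
        self.assign_mode = assign_mode

    def fit(self) -> "ChipBindingResults":
        scores = score_probes(self.spots, n_bins=self.n_bins,
                              lowess_frac=self.lowess_frac)
        sets = build_probe_sets(scores, max_gap=self.max_gap)
        if len(sets):
            sets = sets.copy()
            sets["passes_promoter_filter"] = apply_promoter_filter(sets)
            sets["passes_transcribed_filter"] = apply_transcribed_filter(sets)
            passing = sets[sets["passes_promoter_filter"]
                           | sets["passes_transcribed_filter"]]
        else:
            sets["passes_promoter_filter"] = []
            sets["passes_transcribed_filter"] = []
            passing = sets
        regions = collapse_bound_regions(passing, scores)
        if len(regions):
            regions = assign_closest_orf(regions, self.annotation,
                                         mode=self.assign_mode)
        else:
            regions["gene_id"] = []
            regions["tss_distance"] = []
        return ChipBindingResults(self, scores, sets, regions)


class ChipBindingResults:
    """Probe scores, probe sets and bound regions from a fitted array."""

    def __init__(self, model, probe_scores, probe_sets, regions):
        self.model = model
        self.probe_scores = probe_scores
        self.probe_sets = probe_sets
        self.regions = regions

    @property
    def bound_genes(self) -> list:
        return sorted(self.regions["gene_id"].dropna().unique())

    def cluster_profiles(self, k: int = 5, n_bins: int = 20,
                         seed: int = 0) -> pd.Series:
        return cluster_binding_profiles(self.probe_scores, self.regions,
                                        self.model.annotation, k=k,
                                        n_bins=n_bins, seed=seed)

    def summary(self) -> str:
        r = self.regions
        lines = [
            "ChIP-on-chip bound-region calling",
            "=" * 54,
            f"probes scored: {len(self.probe_scores)}",
            f"3-probe windows: {len(self.probe_sets)}",
            f"  passing promoter filter: "
            f"{int(self.probe_sets['passes_promoter_filter'].sum())}",
            f"  passing transcribed filter: "
            f"{int(self.probe_sets['passes_transcribed_filter'].sum())}",
            f"bound regions: {len(r)}",
            f"bound genes: {len(self.bound_genes)}",
        ]
        if len(r):
            lines.append(f"median region width: "
                         f"{int(np.median(r['end'] - r['start']))} bp")
            lines.append(f"max enrichment (fold): "
                         f"{r['max_enrichment'].max():.2f}")
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        from .io import write_bed
        write_bed(self.regions, path)

    def to_tsv(self, path) -> None:
        cols = ["gene_id", "chrom", "start", "end", "best_p",
                "max_enrichment", "tss_distance"]
        self.regions[cols].to_csv(path, sep="\t", index=False)
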