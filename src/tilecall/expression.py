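"""Two-color expression analysis: LOWESS normalization, dye-swap merging
and fold-change differential-expression calls.

The selection rule is fold-change-only: a gene is called up when its
replicate-averaged normalized log2 ratio is >= +0.25 and down when it is
<= -0.25 (inclusive, thresholds configurable).  A plain per-gene t
statistic is reported as annotation only; it plays no part in the calls.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .io import background_subtract

__all__ = [
    "lowess_normalize", "merge_dye_swap_replicates", "call_differential",
    "TwoColorExpressionModel", "ExpressionResults",
]

UP_THRESHOLD = 0.25
DOWN_THRESHOLD = -0.25


class InsufficientDataError(ValueError):
    pass


def _ensure_net(spots: pd.DataFrame) -> pd.DataFrame:
    if "ch1_net" not in spots.columns:
        spots = background_subtract(spots)
    return spots


def lowess_normalize(spots: pd.DataFrame, frac: float = 0.3,
                     iterations: int = 3) -> pd.DataFrame:
    """Remove the intensity-dependent trend from per-spot log ratios.

    Computes M = log2(ch1/ch2) and A = mean log2 intensity from the
    background-subtracted channels, fits a single global LOWESS of M on A
    (span ``frac``, ``iterations`` robustness passes), and returns
    ``M_norm = M_raw - fit(A)``.

    Returns a table with columns probe_id, A, M_raw, M_norm.

    Raises
    ------
    InsufficientDataError
        With fewer than 50 spots the trend fit is not meaningful.
    """
    spots = _ensure_net(spots)
    if len(spots) < 50:
        raise InsufficientDataError(
            f"LOWESS normalization needs >= 50 QC-passed spots, got {len(spots)}")
    l1 = np.log2(spots["ch1_net"].to_numpy(float))
    l2 = np.log2(spots["ch2_net"].to_numpy(float))
    A = 0.5 * (l1 + l2)
    M = l1 - l2
    span = float(np.ptp(A))
    fit = sm_lowess(M, A, frac=frac, it=iterations, delta=0.005 * span,
                    return_sorted=False)
    out = pd.DataFrame(dict(probe_id=spots["probe_id"].to_numpy(),
                            A=A, M_raw=M, M_norm=M - fit))
    out.attrs = dict(spots.attrs)
    return out


def default_probe_to_gene(probe_id: str) -> str:
    """Strip a trailing ``:<n>`` replicate-probe suffix from a probe id."""
    return re.sub(r":\d+$", "", probe_id)


def merge_dye_swap_replicates(tables, swapped, probe_to_gene=None,
                              min_replicates: int = 2) -> pd.DataFrame:
    """Average normalized ratios across replicates with dye-swap correction.

    Parameters
    ----------
    tables : sequence of normalized-ratio tables (from :func:`lowess_normalize`)
    swapped : sequence of bool, one per table
        Swapped arrays contribute ``-M_norm``, undoing the physical dye
        exchange so all replicates estimate the same signed effect.
    probe_to_gene : callable, optional
        Probe id -> gene id; defaults to stripping a ``:<n>`` suffix.
        Probes of a gene are summarized by their median before averaging
        across arrays.
    min_replicates : int
        Genes measured on fewer arrays are dropped (reported in
        ``attrs["dropped_genes"]``).

    Returns a table with gene_id, mean_log2fc, n_replicates, sd, t_stat.
    """
    if len(tables) != len(swapped):
        raise ValueError("one swapped flag per table required")
    mapper = probe_to_gene or default_probe_to_gene
    per_array = []
    for i, (tab, sw) in enumerate(zip(tables, swapped)):
        genes = tab["probe_id"].map(mapper)
        m = tab["M_norm"].groupby(genes).median()
        per_array.append(-m if sw else m)
    wide = pd.concat(per_array, axis=1, keys=range(len(per_array)))
    n = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    out = pd.DataFrame(dict(gene_id=wide.index, mean_log2fc=mean.to_numpy(),
                            n_replicates=n.to_numpy(), sd=sd.to_numpy(),
                            t_stat=t.to_numpy()))
    keep = out["n_replicates"] >= min_replicates
    dropped = out.loc[~keep, "gene_id"].tolist()
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) measured on < {min_replicates} "
                      "arrays were dropped")
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["dropped_genes"] = dropped
    return out


def call_differential(gene_table: pd.DataFrame,
                      up_threshold: float = UP_THRESHOLD,
                      down_threshold: float = DOWN_THRESHOLD) -> pd.DataFrame:
    """Call genes up/down/unchanged by inclusive log2 fold-change cutoffs."""
    if not down_threshold < 0 < up_threshold:
        raise ValueError("thresholds must satisfy down < 0 < up")
    fc = gene_table["mean_log2fc"].to_numpy(float)
    call = np.where(fc >= up_threshold, "up",
                    np.where(fc <= down_threshold, "down", "unchanged"))
    out = gene_table.copy()
    out["call"] = call
    return out


class TwoColorExpressionModel:
    """Differential-expression model for a dye-swap two-color experiment.

    Parameters
    ----------
    tables : sequence of spot tables (QC-passed; raw counts accepted, in
        which case background subtraction is applied)
    swapped : sequence of bool or a manifest DataFrame with a ``swapped``
        column, one entry per array
    probe_to_gene : callable, optional
    """

    def __init__(self, tables, swapped, probe_to_gene=None):
        if isinstance(swapped, pd.DataFrame):
            swapped = swapped["swapped"].tolist()
        self.tables = list(tables)
        self.swapped = [bool(s) for s in swapped]
        self.probe_to_gene = probe_to_gene

    def fit(self, frac: float = 0.3, iterations: int = 3,
            min_replicates: int = 2,
            up_threshold: float = UP_THRESHOLD,
            down_threshold: float = DOWN_THRESHOLD) -> "ExpressionResults":
        normalized = [lowess_normalize(t, frac=frac, iterations=iterations)
                      for t in self.tables]
        genes = merge_dye_swap_replicates(normalized, self.swapped,
                                          probe_to_gene=self.probe_to_gene,
                                          min_replicates=min_replicates)
        calls = call_differential(genes, up_threshold, down_threshold)
        return ExpressionResults(self, normalized, calls,
                                 up_threshold, down_threshold)


class ExpressionResults:
    """Fitted per-gene fold changes and the resulting calls."""

    def __init__(self, model, normalized, gene_table, up_threshold, down_threshold):
        self.model = model
        self.normalized = normalized
        self.gene_table = gene_table
        self.up_threshold = up_threshold
        self.down_threshold = down_threshold

    @property
    def up(self) -> list:
        t = self.gene_table
        return t.loc[t["call"] == "up", "gene_id"].tolist()

    @property
    def down(self) -> list:
        t = self.gene_table
        return t.loc[t["call"] == "down", "gene_id"].tolist()

    @property
    def unchanged(self) -> list:
        t = self.gene_table
        return t.loc[t["call"] == "unchanged", "gene_id"].tolist()

    def summary(self) -> str:
        t = self.gene_table
        lines = [
            "Two-color differential expression (fold-change rule)",
            "=" * 54,
            f"arrays: {len(self.model.tables)} "
            f"({sum(self.model.swapped)} dye-swapped)",
            f"genes retained: {len(t)}"
            + (f" (dropped: {len(t.attrs.get('dropped_genes', []))})"
               if t.attrs.get("dropped_genes") else ""),
            f"thresholds: up >= {self.up_threshold:+.2f}, "
            f"down <= {self.down_threshold:+.2f} (log2)",
            f"called up: {len(self.up)}    called down: {len(self.down)}    "
            f"unchanged: {len(self.unchanged)}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["gene_id", "mean_log2fc", "n_replicates", "call"]
        self.gene_table[cols].to_csv(path, sep="\t", index=False,
                                     float_format="%.4f")
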