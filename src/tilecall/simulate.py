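"""Synthetic two-color array generator with known ground truth.

Emulates an Agilent-style promoter tiling design (45–60 bp probes tiling
fixed promoter windows, pooled IP vs input labeled Cy5/Cy3) and a two-color
expression design with dye-swap replicates.  Every downstream stage of the
pipeline can therefore be tested against spiked-in truth: bound promoter
regions of known fold enrichment and differentially expressed genes of
known log2 fold change.

Intensity model
---------------
Per spot and channel, background is log-normal and foreground is
background + signal.  The true hybridization signal is shared between
channels; each channel multiplies it by ``2**eps`` with
``eps ~ N(0, noise_sd/sqrt(2))``, so the background-subtracted log2 ratio
carries Gaussian noise of standard deviation ``noise_sd``.  Dye bias is
injected into the Cy5 channel as a quadratic function of log signal
strength (amplitude in log2 units), so intensity-dependent normalization
is exercised non-trivially.  Foregrounds are clipped at the 16-bit
saturation level and a fraction of spots is flagged, as a scanner would.

Spiked bound regions always span at least three consecutive probes —
the probe-set filters cannot detect shorter events by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd

from .io import DEFAULT_SATURATION

__all__ = [
    "SimulationConfig", "GroundTruth", "generate_annotation",
    "simulate_chip_array", "simulate_expression_arrays",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the simulated array study.

    Defaults describe a desk-scale promoter tiling study: 1,000 promoters
    of 10 probes at 200 bp spacing, 5% of promoters carrying a 4-fold
    spiked binding event, log2-ratio noise of 0.35, and a 3-replicate
    dye-swap expression design with true effects of 1 log2 unit.
    """

    n_promoters: int = 1000
    probes_per_promoter: int = 10
    probe_spacing_bp: int = 200
    spike_fraction: float = 0.05
    enrichment_fold: float = 4.0
    noise_sd: float = 0.35
    dye_bias_amplitude: float = 0.3
    flag_fraction: float = 0.02
    saturation_level: int = DEFAULT_SATURATION
    n_genes: int = 2000
    de_fraction: float = 0.05
    effect_size_log2: float = 1.0
    n_replicates: int = 3
    dye_swap: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("spike_fraction", "de_fraction", "flag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_fold < 1:
            raise ConfigurationError("enrichment_fold must be >= 1")
        if self.probes_per_promoter < 3:
            raise ConfigurationError("probes_per_promoter must be >= 3")
        for name in ("n_promoters", "probe_spacing_bp", "n_genes",
                     "n_replicates", "saturation_level"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd < 0 or self.dye_bias_amplitude < 0:
            raise ConfigurationError("noise_sd and dye_bias_amplitude must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        kwargs = {}
        known = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ConfigurationError(f"unknown config key {key!r}")
                val = val.strip()
                if key == "dye_swap":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif key in ("spike_fraction", "enrichment_fold", "noise_sd",
                             "dye_bias_amplitude", "flag_fraction",
                             "de_fraction", "effect_size_log2"):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = int(val)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @property
    def promoter_length(self) -> int:
        return self.probes_per_promoter * self.probe_spacing_bp


@dataclass
class GroundTruth:
    """Spiked truth a simulation run commits to.

    ``bound_regions`` has columns chrom, start, end, gene_id, true_fold;
    ``de_genes`` maps gene_id -> true (unswapped) log2 fold change.
    """

    bound_regions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "gene_id", "true_fold"]))
    de_genes: dict = field(default_factory=dict)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.bound_regions.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}"
                         f"\t0\t+\t{r.true_fold}\n")


_PROMOTERS_PER_CHROM = 100
_ORF_LENGTH = 1500
_INTERGENIC_GAP = 1000


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay out one gene per promoter on synthetic chromosomes.

    Returns an annotation table with the standard columns plus
    ``promoter_start``/``promoter_end`` giving the tiled window.  Windows
    are disjoint by construction; strands alternate deterministically
    under the configured seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.promoter_length
    slot = L + _ORF_LENGTH + _INTERGENIC_GAP
    strands = rng.choice(["+", "-"], size=config.n_promoters)
    rows = []
    for i in range(config.n_promoters):
        chrom = f"chr{i // _PROMOTERS_PER_CHROM + 1}"
        offset = (i % _PROMOTERS_PER_CHROM) * slot
        strand = strands[i]
        if strand == "+":
            p_start, p_end = offset, offset + L
            orf_start, orf_end = p_end, p_end + _ORF_LENGTH
            tss = orf_start
        else:
            orf_start, orf_end = offset, offset + _ORF_LENGTH
            p_start, p_end = orf_end, orf_end + L
            tss = orf_end
        rows.append(dict(gene_id=f"g{i + 1:05d}", chrom=chrom, strand=strand,
                         tss=tss, orf_start=orf_start, orf_end=orf_end,
                         promoter_start=p_start, promoter_end=p_end))
    return pd.DataFrame(rows)


def _dye_bias(log2_signal: np.ndarray, amplitude: float) -> np.ndarray:
    # quadratic in standardized log intensity, clipped at |z| = 2 so the
    # amplitude really is the maximum bias magnitude (real dye bias is a
    # bounded ~1 log2-unit effect, not an unbounded parabola)
    if amplitude == 0:
        return np.zeros_like(log2_signal)
    z = (log2_signal - np.mean(log2_signal)) / max(np.std(log2_signal), 1e-9)
    z = np.clip(z, -2.0, 2.0)
    return amplitude * (z ** 2 / 2.0 - 1.0)


def _render_channels(rng, n, true_log2_ratio, config):
    """Shared two-color intensity machinery for both array types."""
    log2_bg = rng.normal(np.log2(100.0), 0.7, size=(n, 2))
    bg = 2.0 ** log2_bg
    log2_signal = rng.normal(np.log2(800.0), 1.0, size=n)
    signal = 2.0 ** log2_signal
    bias = _dye_bias(log2_signal, config.dye_bias_amplitude)
    eps = rng.normal(0.0, config.noise_sd / np.sqrt(2.0), size=(n, 2))
    sig1 = signal * 2.0 ** (true_log2_ratio + bias + eps[:, 0])
    sig2 = signal * 2.0 ** eps[:, 1]
    ch1_fg = np.minimum(bg[:, 0] + sig1, config.saturation_level)
    ch2_fg = np.minimum(bg[:, 1] + sig2, config.saturation_level)
    flag = rng.random(n) < config.flag_fraction
    return (np.round(ch1_fg, 1), np.round(bg[:, 0], 1),
            np.round(ch2_fg, 1), np.round(bg[:, 1], 1), flag)


def simulate_chip_array(config: SimulationConfig,
                        annotation: pd.DataFrame) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one pooled IP-vs-input tiling array.

    Probes tile each promoter window at the configured spacing.  A
    ``spike_fraction`` of promoters receives a bound region spanning 3–5
    consecutive probes whose IP/input log2 ratio is centered at
    log2(enrichment_fold); all other probes are centered at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ppp, spacing = config.probes_per_promoter, config.probe_spacing_bp
    n_probes = config.n_promoters * ppp

    probe_len = rng.integers(45, 61, size=n_probes)
    gene_idx = np.repeat(np.arange(config.n_promoters), ppp)
    within = np.tile(np.arange(ppp), config.n_promoters)
    p_start = annotation["promoter_start"].to_numpy()[gene_idx] + within * spacing
    p_end = p_start + probe_len
    chrom = annotation["chrom"].to_numpy()[gene_idx]

    n_spikes = int(round(config.spike_fraction * config.n_promoters))
    if n_spikes == 0 and config.spike_fraction > 0:
        warnings.warn("spike_fraction x n_promoters < 1; simulating zero spikes")
    spiked_promoters = np.sort(rng.choice(config.n_promoters, size=n_spikes,
                                          replace=False))
    mu = np.zeros(n_probes)
    gt_rows = []
    for g in spiked_promoters:
        run = int(rng.integers(3, min(5, ppp) + 1))
        start_probe = int(rng.integers(0, ppp - run + 1))
        lo, hi = g * ppp + start_probe, g * ppp + start_probe + run
        mu[lo:hi] = np.log2(config.enrichment_fold)
        gt_rows.append(dict(
            chrom=annotation["chrom"].iloc[g],
            start=int(p_start[lo]), end=int(p_end[hi - 1]),
            gene_id=annotation["gene_id"].iloc[g],
            true_fold=config.enrichment_fold))

    ch1_fg, ch1_bg, ch2_fg, ch2_bg, flag = _render_channels(rng, n_probes, mu, config)
    spots = pd.DataFrame(dict(
        probe_id=[f"chip_{i:06d}" for i in range(n_probes)],
        chrom=chrom, start=p_start, end=p_end,
        ch1_fg=ch1_fg, ch1_bg=ch1_bg, ch2_fg=ch2_fg, ch2_bg=ch2_bg,
        flag=flag))
    spots.attrs["channel_roles"] = {"ch1": "IP", "ch2": "input"}
    truth = GroundTruth(bound_regions=pd.DataFrame(
        gt_rows, columns=["chrom", "start", "end", "gene_id", "true_fold"]))
    return spots, truth


def simulate_expression_arrays(config: SimulationConfig
                               ) -> tuple[list[pd.DataFrame], GroundTruth, pd.DataFrame]:
    """Simulate ``n_replicates`` two-color expression arrays.

    One probe per gene.  A ``de_fraction`` of genes carries a true log2
    fold change of ±``effect_size_log2`` (sign random).  With
    ``dye_swap``, the second half of the replicates has its raw ratios
    sign-inverted, as physical dye exchange would do; the dye bias itself
    stays attached to the Cy5 channel.

    Returns the list of spot tables, the ground truth, and a manifest
    table with columns ``array_id`` and ``swapped``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]

    n_de = int(round(config.de_fraction * n))
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_fc = np.zeros(n)
    true_fc[de_idx] = signs * config.effect_size_log2
    de_genes = {genes[i]: float(true_fc[i]) for i in de_idx}

    n_swapped = config.n_replicates // 2 if config.dye_swap else 0
    tables, manifest = [], []
    for r in range(config.n_replicates):
        swapped = r >= config.n_replicates - n_swapped
        sign = -1.0 if swapped else 1.0
        ch1_fg, ch1_bg, ch2_fg, ch2_bg, flag = _render_channels(
            rng, n, sign * true_fc, config)
        t = pd.DataFrame(dict(
            probe_id=[f"{g}:1" for g in genes],
            chrom="array", start=np.arange(n) * 100, end=np.arange(n) * 100 + 60,
            ch1_fg=ch1_fg, ch1_bg=ch1_bg, ch2_fg=ch2_fg, ch2_bg=ch2_bg,
            flag=flag))
        t.attrs["channel_roles"] = {"ch1": "sample", "ch2": "reference"}
        tables.append(t)
        manifest.append(dict(array_id=f"rep{r + 1}", swapped=swapped))

    return tables, GroundTruth(de_genes=de_genes), pd.DataFrame(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(orient="records"), fh, indent=2)
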