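import numpy as np
import pandas as pd
import pytest

from tilecall.io import background_subtract, qc_filter_spots
from tilecall.simulate import (SimulationConfig, generate_annotation,
                               simulate_chip_array, simulate_expression_arrays)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def chip_simulation(default_config):
    """One simulated ChIP array with ground truth (QC-passed spots)."""
    ann = generate_annotation(default_config)
    spots, truth = simulate_chip_array(default_config, ann)
    qc = background_subtract(qc_filter_spots(spots))
    return dict(config=default_config, annotation=ann, spots=spots,
                qc_spots=qc, truth=truth)


@pytest.fixture(scope="session")
def null_chip_simulation():
    """A spike-free ChIP array: every probe is null."""
    cfg = SimulationConfig(spike_fraction=0.0, seed=7)
    ann = generate_annotation(cfg)
    spots, truth = simulate_chip_array(cfg, ann)
    qc = background_subtract(qc_filter_spots(spots))
    return dict(config=cfg, annotation=ann, qc_spots=qc, truth=truth)


@pytest.fixture(scope="session")
def expression_simulation():
    cfg = SimulationConfig(seed=13)
    tables, truth, manifest = simulate_expression_arrays(cfg)
    qc = [background_subtract(qc_filter_spots(t)) for t in tables]
    return dict(config=cfg, tables=qc, truth=truth, manifest=manifest)


def make_spot_frame(rows):
    """Build a spot table from (probe_id, chrom, start, end, c1f, c1b, c2f,
    c2b, flag) tuples."""
    cols = ["probe_id", "chrom", "start", "end", "ch1_fg", "ch1_bg",
            "ch2_fg", "ch2_bg", "flag"]
    return pd.DataFrame(rows, columns=cols)


def make_score_frame(p_values, chrom="chr1", spacing=200, probe_len=50,
                     ratios=None):
    """Build a probe-score table with evenly spaced probes."""
    n = len(p_values)
    starts = np.arange(n) * spacing
    return pd.DataFrame(dict(
        probe_id=[f"p{i}" for i in range(n)],
        chrom=chrom, start=starts, end=starts + probe_len,
        A=10.0, ratio_log2=(np.zeros(n) if ratios is None
                            else np.asarray(ratios, float)),
        p_single=np.asarray(p_values, float),
    ))
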