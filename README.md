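# tilecall

Bound-region calling from two-color ChIP-on-chip promoter tiling arrays,
dye-swap differential expression for two-color expression arrays, and
integration of the two — the analysis chain used to ask which genes a
chromatin-associated protein both binds and regulates, for example a
kinase recruited to promoters as muscle progenitor cells switch from
proliferation to differentiation.

The package is aimed at computational biologists who need a transparent,
fully specified implementation of this classic tiling-array workflow —
either to reanalyze legacy Agilent-style promoter array data or to study
the statistical behavior of the probe-set filters themselves.  A
spike-in simulator with known ground truth makes every stage testable.

## The model

**ChIP enrichment.**  For each probe the normalized log2 ratio of
immunoprecipitated to input DNA, *M* = log2(IP/input), is scored against
a whole-array error model: probes are grouped into deciles of mean log
intensity *A*, and within each bin

&nbsp;&nbsp;&nbsp;&nbsp;*z* = (*M* − median) / (1.4826 · MAD),&nbsp;&nbsp;&nbsp;&nbsp;*p* = 1 − Φ(*z*),

a robust upper-tail single-point P value that adapts to
intensity-dependent variance.  Sliding windows of three consecutive
probes are scored with Stouffer's combined P value,

&nbsp;&nbsp;&nbsp;&nbsp;*p*₍comb₎ = 1 − Φ( (*z*₁ + *z*₂ + *z*₃) / √3 ),

and a window is called bound if it passes either of two rules (strict
inequalities):

* **promoter rule** — center *p* < 0.001, one flanking *p* < 0.01,
  combined *P* < 0.001;
* **transcribed-region rule** — center *p* < 0.005, combined
  *P* < 0.0001, and one flanking probe whose own window has combined
  *P* < 0.001.

Overlapping passing windows are collapsed into bound regions, each
reported with its maximum enrichment (2^max *M*), best combined *P*, and
closest gene (nearest TSS to the region midpoint).

**Differential expression.**  Expression log ratios are normalized by a
global LOWESS fit of *M* on *A*; dye-swap replicates contribute −*M*;
per-gene means are thresholded at an inclusive log2 fold change of
±0.25.

**Integration and validation.**  Bound and regulated gene lists are
crossed (2-way Venn partitions), gene-set over-representation uses the
hypergeometric upper tail with Benjamini–Hochberg correction, and bench
validation helpers implement ΔΔCt relative expression, ChIP-qPCR fold
over IgG (IgG ≡ 1), and an exact Mann–Whitney U test.

## Worked example

```python
from tilecall import ChipBindingModel, SimulationConfig
from tilecall.simulate import generate_annotation, simulate_chip_array
from tilecall.io import qc_filter_spots, background_subtract

config = SimulationConfig(seed=5)          # 1,000 promoters x 10 probes,
annotation = generate_annotation(config)   # 50 spiked 4-fold regions
spots, truth = simulate_chip_array(config, annotation)
spots = background_subtract(qc_filter_spots(spots))

results = ChipBindingModel(spots, annotation).fit()
print(results.summary())
```

```
ChIP-on-chip bound-region calling
======================================================
probes scored: 9674
3-probe windows: 7674
  passing promoter filter: 158
  passing transcribed filter: 160
bound regions: 48
bound genes: 48
median region width: 1045 bp
max enrichment (fold): 8.37
```

Of the 10,000 simulated probes, 9,674 pass spot QC (twice above
background, unsaturated, unflagged).  The filters fire on 48 of the 50
spiked regions' windows and on no null windows, so the 48 bound regions
are all true spike-ins; each row of `results.regions` carries the
interval, the peak enrichment and the nearest gene:

```
chrom  start    end  n_probe_sets  max_enrichment       best_p gene_id  tss_distance
 chr1  40500  41346             3        5.502931 4.043070e-21  g00010       -1577.0
 chr1 124200 124848             2        5.711547 3.945186e-25  g00028       -1524.0
```

The same workflow is available from the shell:

```bash
tilecall simulate chip --seed 5 --out-dir chip
tilecall chip-call --spots chip/chip_spots.tsv --annotation chip/genes.bed \
    --out bound.bed --report bound.tsv
tilecall diff-expr --arrays expr/manifest.tsv --out calls.tsv
tilecall integrate --bound bound.tsv --up up.txt --down down.txt --out crossed.tsv
```

## Layout

| module | contents |
| --- | --- |
| `tilecall.simulate` | spike-in array simulator, `SimulationConfig`, `GroundTruth` |
| `tilecall.io` | spot-table/BED/GFF-lite/GMT readers and writers, spot QC |
| `tilecall.chip` | error model, probe sets, filters, `ChipBindingModel` |
| `tilecall.expression` | LOWESS, dye-swap merging, `TwoColorExpressionModel` |
| `tilecall.integrate` | Venn partitions, bound×regulated crossing, set enrichment |
| `tilecall.validation` | ΔΔCt, fold over IgG, exact Mann–Whitney U |

See `docs/methods.md` for the statistical details and design choices.
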