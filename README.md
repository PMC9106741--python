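# hashladder

Spike-in normalization for combinatorial-indexing single-cell RNA-seq using a
**hash ladder**: a mixture of polyadenylated single-stranded DNA oligos spiked
into nuclei at known, distinct concentrations. Each nucleus traps hash
molecules roughly in proportion to their concentration, so the observed
per-species UMI counts form a per-cell dilution standard. From it the package
builds per-cell calibration curves, QC scores, and size factors that — unlike
total-count ("library size") factors — preserve *global* shifts in
transcriptional output through normalization and differential expression.

Intended users: computational biologists analyzing sci-RNA-seq / sci-Plex
style experiments with hash ladders (or evaluating whether to add one), and
methods developers who want a fully simulated test bed for external-standard
normalization.

## The model

For cell *i* with observed ladder counts *y<sub>ij</sub>* and expected
molecules per nucleus *E<sub>j</sub>* (spiked amount × N<sub>A</sub> / number
of nuclei), a negative-binomial GLM with log link is fit per cell:

```
log E[y_ij] = b_i + m_i · log(E_j)
```

The slope *m<sub>i</sub>* (≈1 for proportional uptake) and intercept
*b<sub>i</sub>* (log capture efficiency, negative) summarize the cell's
library efficiency; a deviance-based pseudo-R² of the fit is the QC score
(cells with pseudo-R² < 0.7, fewer than 100 ladder UMIs, or fewer than 10
detected species are discarded). Size factors:

- conventional: `f_i ∝ x_i` (total RNA UMIs), unit geometric mean;
- hash ladder:  `f'_i ∝ ln(z_i / h_i) · m_i / (−b_i) · r_i`, with
  *z<sub>i</sub>* total ladder UMIs and *h<sub>i</sub>*, *r<sub>i</sub>* the
  hash/RNA duplication rates (reads per UMI).

Downstream, per-gene NB GLMs with `ln f` offsets (binary treatment or 3-df
natural-spline pseudotime designs), likelihood-ratio tests with BH control,
and pseudotime "onset" estimation (first persistent upward zero-crossing of
the centered, z-scaled fitted curve) are provided, along with a
sample-demultiplexing module for ID hashes (Levenshtein barcode matching,
Poisson background filtering, enrichment-ratio cutoff) and a full synthetic
experiment generator with ground truth.

## Worked example

```python
import numpy as np
import hashladder as hl

# simulate: 500 control cells + 500 cells with a 2x global repression
cfg = hl.SimConfig(
    seed=4, n_genes=200,
    conditions=[hl.Condition("control", 1.0, 500),
                hl.Condition("treated", 0.5, 500, treated=True)],
)
sim = hl.simulate_experiment(cfg)

# per-cell calibration curves + QC
res = hl.CalibrationModel(sim.hash_counts, sim.ladder).fit()
print(res.summary())

# both size-factor families
md = sim.metadata
norms = hl.build_cell_normalization(
    md.cell_barcode, md.rna_umis, md.rna_reads, md.hash_umis, md.hash_reads,
    res.table.slope, res.table.intercept)
keep = (res.table.qc_pass & norms.included).to_numpy()

# group means of normalized totals: only hash factors see the global shift
labels = sim.truth.cells.label.to_numpy()[keep]
x = md.rna_umis.to_numpy()[keep]
for name, f in [("hash", norms.f_hash), ("conventional", norms.f_conventional)]:
    agg = hl.aggregate_totals_by_group(x, f[keep].to_numpy(), labels)
    print(f"{name:>12}: treated/control = {agg['treated']/agg['control']:.3f}")
```

Output:

```
Hash-ladder calibration
========================================
cells fit:            1000
cells passing QC:     1000 (100.0%)
QC: r2 >= 0.7, ladder UMIs >= 100, species >= 10
median pseudo-R2:     0.956
median slope:         0.981
median intercept:     -5.195
median ladder UMIs:   2510
        hash: treated/control = 0.506
conventional: treated/control = 1.000
```

The calibration lines are tight (median pseudo-R² 0.95, slope ≈ 1) and the
hash-normalized group totals recover the true 0.5× global repression, while
conventional normalization — which assumes equal totals — reports none.

The same pipeline is scriptable stage by stage:

```
hashladder simulate --seed 4 --conditions control:1.0:500,treated:0.5:500:treated --out sim/
hashladder calibrate --hash-counts sim/hash_counts --ladder sim/ladder.tsv --out calib.tsv
hashladder normalize --calibration calib.tsv --metadata sim/metadata.tsv --out factors.tsv
```

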