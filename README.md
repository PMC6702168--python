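# actseq

A computational toolkit for **indexed antibody-guided chromatin tagmentation**
(ACT-seq / iACT-seq) single-cell data: simulation with ground truth,
combinatorial-barcode demultiplexing, barcode-collision doublet QC,
island-style peak calling, and the bulk/single-cell enrichment metrics used
to evaluate such experiments.

## The problem

In indexed tagmentation assays, cells are first labelled in bulk wells with
one of 96 transposase-loaded 5′/3′ *complex-barcode* combinations, pooled,
and FACS-sorted at 18 cells into each well of a second 96-well plate, where a
per-well PCR *library index* is added. An apparent single cell is a
(library well, combo) pair. Two cells that land in the same well with the
same combo **collide** into one apparent barcode — a doublet. With *n* cells
drawing uniformly from *B* barcodes, the expected doublet fraction among
occupied barcodes is

```
collision rate = (E[occupied] − E[singleton]) / E[occupied]
E[occupied]  = B (1 − (1 − 1/B)^n)
E[singleton] = n (1 − 1/B)^(n−1)
```

which is 8.65% at n=18, B=96. Because doublets carry roughly double read
depth, the standard QC removes the top ~8% of apparent cells per well by
depth, then drops libraries with fewer than 500 unique reads; this package
quantifies the doublets that *survive* that filter by Monte-Carlo simulation
of the full plate geometry.

Downstream, peaks are called with a SICER-style window/gap island scheme
(200 bp windows, 200 bp gap, Poisson background), optionally FDR-filtered
against a nonspecific-accessibility control, and per-cell quality is
summarized as **precision** (fraction of a cell's fragments inside bulk
peaks) and **sensitivity** (fraction of bulk peaks hit by the cell).

## Worked example

Run an end-to-end synthetic experiment (8 library wells × 18 cells, 96
combos, ~2500 unique fragments per cell, FRiP 0.6, 200 true 1 kb peaks on a
10 Mb genome):

```python
from actseq.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="demo_run", seed=1,
    genome=dict(n_chroms=1, chrom_size=10_000_000, n_peaks=200,
                peak_width=1000, n_tss=500),
    sim=dict(n_wells=8, cells_per_well_sorted=18, n_combos=96,
             mean_unique_reads=2500.0, frip=0.6),
    qc_params=dict(cells_per_well=18, n_combos=96, top_percent=8.0,
                   min_reads=500),
)
report = run_pipeline(cfg)
```

The report (also written to `demo_run/report.json`) contains, for this seed:

```
simulate:  144 true cells -> 134 apparent cells, 345,617 fragments, 200 true peaks
qc:        collision_rate 0.0865; 134 cells -> 118 after top-8% + min-500 filters
callpeaks: 198 islands covering 237,600 bp
metrics:   mean precision 0.610, mean sensitivity 0.991 over 118 cells
```

Mean precision ≈ 0.61 is the configured FRiP of 0.6 plus the background
fragments that fall into peak regions by chance; sensitivity saturates near
1 here because 2500 fragments easily hit most of only 200 peaks (real
experiments have tens of thousands of peaks, which pushes sensitivity to the
few-percent range predicted by the occupancy law `1 − (1 − 1/P)^(frip·n)`).
The called islands recover all 200 true peaks with no false islands.

The same stages are available from the shell:

```bash
actseq simulate --out demo --seed 1 --fastq
actseq demux --r1 demo/reads_R1.fastq.gz --r2 demo/reads_R2.fastq.gz \
             --manifest demo/manifest.tsv --out fragments.tsv.gz --stats stats.json
actseq collision-rate --cells 18 --barcodes 96 --mc-reps 100000
actseq qc --fragments fragments.tsv.gz --report qc.json
actseq callpeaks --fragments fragments.tsv.gz --chrom-sizes sizes.tsv --out peaks.bed
actseq scmetrics --fragments fragments.tsv.gz --peaks peaks.bed --out metrics.tsv
```

## Layout

| module | contents |
| --- | --- |
| `actseq.io` | fragment/BED/bedGraph/manifest readers and writers (0-based half-open everywhere) |
| `actseq.simulate` | synthetic genomes, plate geometry, fragment and FASTQ emission, ground truth |
| `actseq.demux` | barcode matching (Hamming ≤ 1 with ambiguity rejection), pair assignment, deduplication |
| `actseq.qc` | collision rate (closed form + MC), two-stage cell filter, residual-doublet estimator |
| `actseq.islands` | window counts, Poisson eligibility, island calling, FDR control filter, peak comparison |
| `actseq.metrics` | TSS metagene profiles, enhancer classification, pseudo-bulk, precision/sensitivity |
| `actseq.pipeline` / `actseq.cli` | YAML-driven orchestration and the `actseq` command |
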