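# Methods

## Model of the indexed-tagmentation experiment

The simulator reproduces the combinatorial-indexing geometry of an indexed
antibody-guided tagmentation (iACT-seq-style) experiment. Physical cells are
labelled with one of `n_combos` 5′/3′ complex-barcode combinations (default
96, one per first-plate well), pooled, and sorted at
`cells_per_well_sorted` cells (default 18) into each of `n_wells` library
wells (default 96). Because pooling mixes the first-plate wells at equal
density, each sorted cell's combo is modelled as uniform over the 96
combinations. An *apparent cell* is an occupied (library well, combo) pair;
apparent cells with two or more members are doublets. Doublets arise only
through barcode collision — co-sorted physical doublets (two cells in one
FACS droplet) are not modelled.

### Collision rate

For `n` cells drawing uniformly from `B` barcodes,
`E[occupied] = B(1−(1−1/B)^n)` and `E[singleton] = n(1−1/B)^(n−1)`; the
collision rate is defined as the ratio of expectations
`(E[occupied]−E[singleton])/E[occupied]` — the predicted fraction of
apparent cell barcodes that are doublets. At the default geometry (18, 96)
this is 0.0865. A vectorized Monte-Carlo mode draws whole wells and reports
total multi-occupied over total occupied barcodes, the direct analogue of
the ratio of expectations; closed form and simulation agree within sampling
error (tested on a grid of geometries).

### Per-cell read counts

Unique-fragment counts per physical cell follow a negative binomial with
mean `mean_unique_reads` (default 2500) and shape `r`
(`read_count_dispersion`; variance μ + μ²/r), clamped to ≥ 1 so every cell
is observable. Real per-cell read-count distributions are empirical and
assay-specific; the NB is the standard overdispersed stand-in and the shape
is an explicit parameter.

**Calibration of the default dispersion.** The residual-doublet estimate
after depth filtering depends strongly on `r`: the more the singleton and
doublet count distributions overlap, the more doublets escape the top-depth
cut. A grid scan over r ∈ {0.5, 1, 1.5, 2, 3, 4, 6, 10, 20} (96 wells × 18
cells, 96 combos, mean 2500, top-8% + min-500 filtering, 200 replicates)
gave residual doublet fractions from 9.9% (r=0.5) down to 1.4% (r=20). The
default `r = 4.0` was chosen because it places the filtered geometry at the
residual doublet rate of ~4.3% (≈59 residual doublets among ≈1379 retained
cells) reported for this assay class, and it is documented here precisely
because the estimate inherits this assumption. Any analysis of a real
experiment should re-estimate the dispersion from its own count table.

### Fragment placement

Each fragment's **midpoint** is drawn uniformly inside a true peak with
probability `frip` (peaks weighted by width) and uniformly over the genome
otherwise; lengths are uniform in `fragment_length_range` (default
100–400 bp, a typical tagmentation insert range), truncated at chromosome
edges. Members of a collision emit fragments under the shared apparent
cell_id, so a doublet's fragment count is the sum of its members' draws.
Defining placement by midpoint makes the realized in-peak fraction equal
`frip` by construction and is consistent with midpoint-based window
assignment and peak membership downstream.

When FASTQ is requested, read 1 carries the 5′ complex barcode and read 2
the 3′ barcode (per-base substitution errors at `barcode_error_rate`),
followed by random filler sequence; the well library index is written into
the read-name index field and the fragment coordinates into the read name.
The pipeline is alignment-free: coordinates travel with the reads, standing
in for an external aligner. Sequencing errors are applied only to barcode
bases since genomic sequence fidelity has no downstream effect here.

### What the simulator does not emulate

Nucleosome positioning, GC and mappability bias, PCR duplication structure
beyond a `duplicate_count`, chromatin-state-dependent background, empirical
read-count distributions, and co-sorting doublets. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and its behavior
under the stated generative model — not robustness to the full complexity of
real libraries.

## Demultiplexing

The well index must match a manifest library index exactly: it selects a
physical PCR well, so an error there is unrecoverable by design. Complex
barcodes are matched with up to `max_mismatch` (default 1) substitutions
against their whitelists; a tie at the minimal distance is ambiguous and the
pair is discarded rather than guessed. Generated manifests enforce pairwise
Hamming distance ≥ 3 within each set, which makes distance-1 correction
unambiguous by construction. A pair is assigned iff both barcodes resolve
and the resolved (5′, 3′) pair is a manifest combo. Matching uses a
precomputed distance-1 neighborhood table, so throughput is O(1) per read.
The optional Tn5 +4/−5 end shift is not applied by default. Duplicates are
collapsed on exact (cell_id, chrom, start, end) identity.

## Cell filtering and residual doublets

Stage 1 removes, within each library well, the top
`ceil(top_percent/100 × well_size)` apparent cells by unique-fragment count
(default 8%, motivated by the ~8.6% collision rate); ties at the cut are
broken by removing the lexicographically smallest cell_id so results are
reproducible. `ceil` means any positive `top_percent` removes at least one
cell per non-empty well. The well size used is the *apparent* cell count of
that well, not the number of sorted cells. Stage 2 removes cells with fewer
than `min_reads` (default 500, strict inequality) unique fragments. The
stage order follows the workflow the thresholds come from: depth filter
first, then the read floor.

`estimate_residual_doublets` repeats the whole generative process
(plate → collisions → NB counts → summed doublet counts → two-stage filter)
and reports the mean residual doublet fraction and count over replicates
with their spread. With filtering disabled it reduces to the collision rate
(tested); its absolute level at the default filter depends on the calibrated
dispersion as discussed above.

## Island peak calling

Chromosomes are tiled into `window_size` (200 bp) windows from coordinate 0;
fragments are assigned to windows by midpoint, which conserves counts and
needs no read-shift convention. The background rate per window λ defaults to
`total_fragments × window_size / (effective_genome_fraction × genome_size)`;
`effective_genome_fraction` defaults to 1.0 because synthetic genomes are
fully mappable (use ~0.74–0.8 for human-like genomes). A window is
*eligible* when its count reaches the smallest k with Poisson tail
P(X ≥ k | λ) < `eligibility_p` (default 0.2, the conventional island-calling
choice). Eligible windows chain into islands across internal non-eligible
runs of total length ≤ `gap_size` (default 200 bp = one window); the island
score is Σ −ln P(X ≥ count | λ) over eligible member windows.

`island_score_threshold` defaults to 10: under a Poisson background a single
minimally eligible window scores ≈ 2.5 and chance pairs ≈ 5–7, so a
threshold of 10 suppresses isolated background fluctuations while true
enriched regions (many windows, counts far above λ) score in the hundreds.
The original E-value machinery and random-background iteration of the
published island caller are deliberately not reproduced; with window and gap
both 200 bp this simplified scorer recovers simulated true peaks essentially
completely (tested: ≥ 95% recovery with ≤ 5% false islands at
20 × 2500-fragment cells on a 10 Mb genome with 200 true peaks).

### Control-based FDR filtering

Against a nonspecific-accessibility control, each island gets a one-sided
binomial test of its treatment midpoint count k against
Binomial(N_treatment, c/N_control), followed by Benjamini–Hochberg
adjustment; islands with q < α (default 0.05) are retained. A control count
of zero yields p = 0 for any enriched island (p = 1 when the treatment count
is also zero). The binomial/BH combination is a minimal standard enrichment
test, chosen because the comparison it implements is otherwise
underspecified; it is reported as such in the output.

## Profiles and per-cell metrics

Metagene profiles count fragment midpoints in `bin_size` bins within
±`extent` of each anchor (defaults 50 bp, ±2000 bp — figure-conventional
values, both exposed as flags), flip the bin axis for minus-strand anchors
so downstream is always right, and scale per anchor per million library
fragments; a fragment near two anchors contributes to both, so profile mass
equals fragment–anchor co-occurrences.

Enhancer classification keeps peaks with no TSS within
±`tss_exclusion_window` (default 1000 bp; 0 reproduces literal overlap) and
returns the TSS-proximal complement, a disjoint partition of the input.

Per-cell **precision** is the fraction of the cell's unique fragments whose
midpoint lies in a bulk peak; **sensitivity** is the fraction of bulk peaks
containing at least one of the cell's fragment midpoints. These are the
definitions consistent with the magnitudes conventionally reported for
single-cell chromatin profiling (precision ≈ 0.6, sensitivity ≈ 0.05 at
~2500 reads/cell against tens of thousands of peaks); upstream variants
(e.g. mark-unified peak sets) exist, so the adopted reading is stated here
rather than asserted as the only one. Sensitivity at P equal-width peaks and
n fragments follows the occupancy law `1 − (1 − 1/P)^(frip·n)`
(`expected_sensitivity`), which the simulation matches. At desk scale
(hundreds of peaks) sensitivity saturates near 1; the few-percent values of
real experiments arise from peak counts in the tens of thousands and are not
independently reproducible without the corresponding datasets.

Quartile summaries report min, Q1, median, Q3, max per metric (linear
interpolation for quartiles).

## Pipeline and reproducibility

One global seed expands into per-stage seeds via
`numpy.random.SeedSequence([seed, stage_index])` with the fixed stage order
(simulate, demux, qc, callpeaks, metrics), so stages re-run independently
yet reproducibly; identical config + seed produces byte-identical fragment,
peak and report files (timing lives in the log, not the report). Invalid
configurations fail before any stage executes.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data chosen
to exercise every code path at comfortable desk scale: 10 Mb single-chromosome
genomes with 200 true 1 kb peaks, plates of 2–96 wells, ~10⁵ read pairs for
demultiplexing checks, 100,000 simulated wells for the Monte-Carlo collision
rate, and 500 replicates for the residual-doublet estimate. These sizes give
Monte-Carlo standard errors well below the tolerances being checked.

## Known limitations

* Doublet modelling is purely collisional; physical co-sorting doublets and
  ambient contamination are out of scope.
* The island caller is a simplified re-implementation (single-library
  Poisson background, score threshold) — island boundaries and borderline
  calls can differ from the original E-value-based caller.
* The residual-doublet percentage is conditional on the NB dispersion
  calibration described above.
* No BAM/SAM input; pre-aligned data must be exported to the fragment TSV
  dialect. bigWig output is not supported (bedGraph only).
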