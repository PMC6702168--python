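"""Synthetic indexed-tagmentation (iACT-seq-style) experiments with ground truth.

The generator reproduces the combinatorial-indexing geometry of an indexed
antibody-guided tagmentation experiment: cells are first barcoded in bulk
wells with one of ``n_combos`` 5'/3' complex-barcode combinations, pooled,
then FACS-sorted at ``cells_per_well_sorted`` cells into each of ``n_wells``
library wells.  An *apparent cell* is a (library well, combo) pair; two
physical cells landing in the same well with the same combo collide into a
single apparent barcode (a doublet).

Per-cell unique-fragment counts follow a negative binomial with mean
``mean_unique_reads`` and shape ``read_count_dispersion`` (variance
mu + mu^2/r).  A ``frip`` fraction of each cell's fragments is centred inside
the genome's true peak regions; the remainder is uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gzip
import numpy as np
import pandas as pd

from .io import BarcodeManifest, GenomicInterval

__all__ = [
    "SimGenome",
    "SimConfig",
    "GroundTruth",
    "make_sim_genome",
    "make_manifest",
    "simulate_cells",
    "simulate_fragments",
    "write_ground_truth",
    "read_ground_truth",
    "cell_label",
]

#: Default NB shape r; calibrated so the standard filter geometry (18 cells/well,
#: 96 combos, top-8% per-well removal, min 500 reads) leaves a residual doublet
#: fraction matching the ~4.3% reported for this assay class (see docs/methods.md).
DEFAULT_READ_COUNT_DISPERSION = 4.0


@dataclass
class SimGenome:
    """A synthetic reference: chromosome sizes, true peaks and TSS anchors."""

    chrom_sizes: dict[str, int]
    true_peaks: list[GenomicInterval]
    tss_list: list[tuple[str, int, str]]  # (chrom, position, strand)

    def __post_init__(self) -> None:
        for pk in self.true_peaks:
            if pk.chrom not in self.chrom_sizes or pk.end > self.chrom_sizes[pk.chrom]:
                raise ValueError(f"peak {pk} outside chromosome bounds")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for pk in self.true_peaks:
            by_chrom.setdefault(pk.chrom, []).append(pk)
        for peaks in by_chrom.values():
            peaks = sorted(peaks, key=lambda p: p.start)
            for a, b in zip(peaks, peaks[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping true peaks {a} / {b}")

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class SimConfig:
    """Parameters of one simulated experiment (defaults: the standard design)."""

    n_wells: int = 96
    cells_per_well_sorted: int = 18
    n_combos: int = 96
    mean_unique_reads: float = 2500.0
    read_count_dispersion: float = DEFAULT_READ_COUNT_DISPERSION
    frip: float = 0.6
    fragment_length_range: tuple[int, int] = (100, 400)
    barcode_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frip <= 1.0):
            raise ValueError("frip must lie in [0, 1]")
        for name in ("n_wells", "cells_per_well_sorted", "n_combos"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mean_unique_reads <= 0 or self.read_count_dispersion <= 0:
            raise ValueError("mean_unique_reads and read_count_dispersion must be positive")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError("fragment_length_range must satisfy 0 < min <= max")
        if not (0.0 <= self.barcode_error_rate < 1.0):
            raise ValueError("barcode_error_rate must lie in [0, 1)")


def cell_label(well: int, combo: int) -> str:
    """Canonical apparent-cell identifier for a (library well, combo) pair."""
    return f"W{well:03d}+C{combo:03d}"


@dataclass
class GroundTruth:
    """True cells and the apparent barcodes they collapse into.

    ``cells`` has one row per *physical* cell (well, combo, n_fragments,
    cell_id); ``apparent`` aggregates by (well, combo): member count, summed
    fragment count, and a doublet flag for >= 2 members.
    """

    cells: pd.DataFrame
    config: SimConfig

    @property
    def apparent(self) -> pd.DataFrame:
        grp = (
            self.cells.groupby(["well", "combo"], sort=True)
            .agg(n_members=("cell_id", "size"), n_fragments=("n_fragments", "sum"))
            .reset_index()
        )
        grp["cell_id"] = [cell_label(w, c) for w, c in zip(grp["well"], grp["combo"])]
        grp["is_doublet"] = grp["n_members"] >= 2
        return grp[["cell_id", "well", "combo", "n_members", "n_fragments", "is_doublet"]]


def make_sim_genome(
    n_chroms: int = 1,
    chrom_size: int = 10_000_000,
    n_peaks: int = 200,
    peak_width: int = 1000,
    n_tss: int = 500,
    seed: int = 0,
) -> SimGenome:
    """Place disjoint uniform peaks and random-strand TSS anchors.

    Peaks are distributed round-robin over chromosomes; within a chromosome,
    disjoint placement uses the classic trick of sampling starts in the
    length-reduced space and re-inflating by cumulative peak widths, which is
    uniform over all disjoint configurations.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    per_chrom = [n_peaks // n_chroms + (1 if i < n_peaks % n_chroms else 0)
                 for i in range(n_chroms)]
    peaks: list[GenomicInterval] = []
    for (chrom, size), k in zip(chrom_sizes.items(), per_chrom):
        if k * peak_width > size:
            raise ValueError(
                f"cannot pack {k} peaks of {peak_width} bp into {chrom} ({size} bp)"
            )
        reduced = size - k * peak_width
        starts = np.sort(rng.integers(0, reduced + 1, size=k))
        starts = starts + np.arange(k) * peak_width
        peaks.extend(
            GenomicInterval(chrom, int(s), int(s) + peak_width) for s in starts
        )
    chrom_names = list(chrom_sizes)
    tss_chroms = rng.integers(0, n_chroms, size=n_tss)
    tss: list[tuple[str, int, str]] = []
    for ci in tss_chroms:
        chrom = chrom_names[ci]
        pos = int(rng.integers(0, chrom_sizes[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append((chrom, pos, strand))
    return SimGenome(chrom_sizes=chrom_sizes, true_peaks=peaks, tss_list=tss)


def _random_codes(rng: np.random.Generator, n: int, length: int,
                  min_distance: int, max_tries: int = 200_000) -> list[str]:
    """Greedy random barcode set with pairwise Hamming distance >= min_distance."""
    alphabet = np.array(list("ACGT"))
    codes: list[np.ndarray] = []
    tries = 0
    while len(codes) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build {n} codes of length {length} at distance {min_distance}"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in codes):
            codes.append(cand)
    return ["".join(alphabet[c]) for c in codes]


def make_manifest(
    n_combos: int = 96,
    n_wells: int = 96,
    barcode_length: int = 8,
    min_distance: int = 3,
    seed: int = 0,
) -> BarcodeManifest:
    """Generate a random manifest whose sets support distance-1 error correction.

    Pairwise Hamming distance >= 3 within each set guarantees that a single
    substitution never makes a barcode ambiguous between two whitelist entries.
    Combo i pairs the i-th 5' and i-th 3' sequence (one combination per
    first-plate well).
    """
    rng = np.random.default_rng(seed)
    set5 = _random_codes(rng, n_combos, barcode_length, min_distance)
    set3 = _random_codes(rng, n_combos, barcode_length, min_distance)
    wells = _random_codes(rng, n_wells, barcode_length, min_distance)
    combos = list(zip(set5, set3))
    return BarcodeManifest(set5=set5, set3=set3, combos=combos, well_indexes=wells)


def simulate_cells(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sort cells into library wells and assign combos and read counts.

    Each of ``n_wells`` library wells receives exactly
    ``cells_per_well_sorted`` physical cells; each cell's complex-barcode
    combo is uniform over ``n_combos`` (the pooled first plate mixes combos
    uniformly).  Unique-read counts are negative binomial, clamped to >= 1 so
    every physical cell is observable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cells = config.n_wells * config.cells_per_well_sorted
    wells = np.repeat(np.arange(config.n_wells), config.cells_per_well_sorted)
    combos = rng.integers(0, config.n_combos, size=n_cells)
    r = config.read_count_dispersion
    p = r / (r + config.mean_unique_reads)
    counts = np.maximum(rng.negative_binomial(r, p, size=n_cells), 1)
    cells = pd.DataFrame(
        {
            "well": wells,
            "combo": combos,
            "n_fragments": counts,
            "cell_id": [cell_label(w, c) for w, c in zip(wells, combos)],
        }
    )
    return GroundTruth(cells=cells, config=config)


def _phred_line(length: int) -> str:
    return "I" * length


def _add_substitutions(seqs: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitution errors to an (n, L) uint8 base-index array."""
    if rate <= 0:
        return seqs
    mask = rng.random(seqs.shape) < rate
    shift = rng.integers(1, 4, size=seqs.shape)
    return np.where(mask, (seqs + shift) % 4, seqs)


def simulate_fragments(
    truth: GroundTruth,
    genome: SimGenome,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    fastq_prefix: str | Path | None = None,
    manifest: BarcodeManifest | None = None,
    read_length: int = 30,
) -> pd.DataFrame:
    """Emit per-fragment coordinates (and optionally paired FASTQ).

    For each physical cell, a ``frip`` fraction of fragments has its midpoint
    uniform inside a true peak (peaks weighted by width); the rest are uniform
    over the genome.  Fragment lengths are uniform in
    ``fragment_length_range``.  Fragments carry the *apparent* cell_id, so
    members of a barcode collision are indistinguishable downstream.

    With ``fastq_prefix`` and ``manifest``, gzipped paired FASTQ is written:
    read 1 starts with the cell's 5' complex barcode, read 2 with its 3'
    barcode (both with ``barcode_error_rate`` substitutions), each followed by
    ``read_length`` random genomic filler bases; the well library index is
    carried in the read-name index field and the fragment coordinates in the
    read name itself (the pipeline is alignment-free).
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cells = truth.cells
    n_frags_per_cell = cells["n_fragments"].to_numpy()
    total = int(n_frags_per_cell.sum())
    cell_idx = np.repeat(np.arange(len(cells)), n_frags_per_cell)

    chrom_names = list(genome.chrom_sizes)
    chrom_len = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    chrom_cum = np.concatenate([[0], np.cumsum(chrom_len)])

    in_peak = rng.random(total) < config.frip
    mids = np.empty(total, dtype=np.int64)
    chrom_of = np.empty(total, dtype=np.int64)

    n_in = int(in_peak.sum())
    if n_in and not genome.true_peaks:
        raise ValueError("frip > 0 requires a genome with true peaks")
    if n_in:
        widths = np.array([len(p) for p in genome.true_peaks], dtype=np.int64)
        pk = rng.choice(len(widths), size=n_in, p=widths / widths.sum())
        starts = np.array([p.start for p in genome.true_peaks])[pk]
        offset = (rng.random(n_in) * widths[pk]).astype(np.int64)
        mids[in_peak] = starts + offset
        chrom_index = {c: i for i, c in enumerate(chrom_names)}
        chrom_of[in_peak] = np.array(
            [chrom_index[p.chrom] for p in genome.true_peaks]
        )[pk]
    n_bg = total - n_in
    if n_bg:
        flat = (rng.random(n_bg) * chrom_cum[-1]).astype(np.int64)
        ci = np.searchsorted(chrom_cum, flat, side="right") - 1
        chrom_of[~in_peak] = ci
        mids[~in_peak] = flat - chrom_cum[ci]

    lo, hi = config.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=total)
    starts = mids - lengths // 2
    ends = starts + lengths
    sizes = chrom_len[chrom_of]
    starts = np.clip(starts, 0, None)
    ends = np.minimum(ends, sizes)
    starts = np.minimum(starts, ends - 1)  # degenerate clamp at chromosome edges

    frags = pd.DataFrame(
        {
            "chrom": np.array(chrom_names, dtype=object)[chrom_of],
            "start": starts,
            "end": ends,
            "cell_id": cells["cell_id"].to_numpy()[cell_idx],
            "duplicate_count": 1,
        }
    )

    if fastq_prefix is not None:
        if manifest is None:
            raise ValueError("FASTQ output requires a barcode manifest")
        _write_fastq(frags, cells, cell_idx, manifest, config, rng,
                     Path(fastq_prefix), read_length)
    return frags


def _write_fastq(
    frags: pd.DataFrame,
    cells: pd.DataFrame,
    cell_idx: np.ndarray,
    manifest: BarcodeManifest,
    config: SimConfig,
    rng: np.random.Generator,
    prefix: Path,
    read_length: int,
) -> None:
    base_chars = np.array(list("ACGT"))
    code = {c: i for i, c in enumerate("ACGT")}

    def encode(seqs: Sequence[str]) -> np.ndarray:
        return np.array([[code[b] for b in s] for s in seqs], dtype=np.int8)

    bc5 = encode([manifest.combos[c][0] for c in cells["combo"]])[cell_idx]
    bc3 = encode([manifest.combos[c][1] for c in cells["combo"]])[cell_idx]
    bc5 = _add_substitutions(bc5, config.barcode_error_rate, rng)
    bc3 = _add_substitutions(bc3, config.barcode_error_rate, rng)
    well_seq = np.array(
        [manifest.well_indexes[w] for w in cells["well"]], dtype=object
    )[cell_idx]

    n = len(frags)
    filler1 = rng.integers(0, 4, size=(n, read_length))
    filler2 = rng.integers(0, 4, size=(n, read_length))
    qual = _phred_line(bc5.shape[1] + read_length)

    chroms = frags["chrom"].to_numpy()
    starts = frags["start"].to_numpy()
    ends = frags["end"].to_numpy()

    def seq_str(mat: np.ndarray) -> list[str]:
        return ["".join(row) for row in base_chars[mat]]

    r1_seqs = seq_str(np.concatenate([bc5, filler1], axis=1))
    r2_seqs = seq_str(np.concatenate([bc3, filler2], axis=1))

    with gzip.open(prefix.with_name(prefix.name + "_R1.fastq.gz"), "wt") as f1, \
            gzip.open(prefix.with_name(prefix.name + "_R2.fastq.gz"), "wt") as f2:
        for i in range(n):
            name = f"F{i}:{chroms[i]}:{starts[i]}:{ends[i]}"
            f1.write(f"@{name} 1:N:0:{well_seq[i]}\n{r1_seqs[i]}\n+\n{qual}\n")
            f2.write(f"@{name} 2:N:0:{well_seq[i]}\n{r2_seqs[i]}\n+\n{qual}\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the apparent-barcode table (member counts and doublet flags)."""
    truth.apparent.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"cell_id": str, "well": int, "combo": int,
               "n_members": int, "n_fragments": int, "is_doublet": bool},
    )
    expected = ["cell_id", "well", "combo", "n_members", "n_fragments", "is_doublet"]
    if list(df.columns) != expected:
        raise ValueError(f"ground-truth file must have columns {expected}")
    return df
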