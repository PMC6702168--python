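"""Window/gap island peak calling with a Poisson background, FDR control
filtering, and peak-set comparison utilities.

The caller tiles each chromosome into fixed windows, marks windows whose
fragment count clears a Poisson upper-tail threshold as *eligible*, and
chains eligible windows into islands, tolerating internal runs of
non-eligible windows up to ``gap_size`` in total length.  The island score
aggregates -ln of the Poisson tail probability over its eligible member
windows; islands below a minimum score are dropped.  This is the classic
island-calling scheme for broad histone-modification enrichment, in a
simplified single-library form (Poisson background estimated from the
library itself; a score threshold in place of the original E-value
machinery).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

__all__ = [
    "IslandParams",
    "Island",
    "window_counts",
    "eligible_threshold",
    "call_islands",
    "fdr_filter_vs_control",
    "overlap_sets",
    "peak_cpm_correlation",
]


@dataclass
class IslandParams:
    window_size: int = 200
    gap_size: int = 200
    eligibility_p: float = 0.2
    island_score_threshold: float = 10.0
    effective_genome_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gap_size < 0 or self.gap_size % self.window_size != 0:
            raise ValueError("gap_size must be a non-negative multiple of window_size")
        if not (0 < self.eligibility_p < 1):
            raise ValueError("eligibility_p must lie in (0, 1)")
        if not (0 < self.effective_genome_fraction <= 1):
            raise ValueError("effective_genome_fraction must lie in (0, 1]")


@dataclass
class Island:
    """A called peak: chained eligible windows with an aggregate tail score."""

    interval: GenomicInterval
    score: float
    read_count: int
    qvalue: float | None = None


def midpoints(fragments: pd.DataFrame) -> np.ndarray:
    return ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2)


def window_counts(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int,
) -> dict[str, np.ndarray]:
    """Count fragment midpoints per consecutive window from coordinate 0.

    The final partial window of each chromosome is kept.  Each fragment is
    counted exactly once, in the window containing its midpoint.
    """
    counts = {
        chrom: np.zeros(-(-size // window_size), dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    if fragments.empty:
        return counts
    mids = midpoints(fragments)
    for chrom, idx in fragments.groupby("chrom", sort=False).indices.items():
        if chrom not in counts:
            raise ValueError(f"fragment chromosome {chrom!r} absent from chrom_sizes")
        w = mids[idx] // window_size
        counts[chrom] += np.bincount(w, minlength=len(counts[chrom]))
    return counts


def eligible_threshold(lambda_bg: float, eligibility_p: float) -> int:
    """Smallest count k >= 1 with Poisson upper tail P(X >= k) < eligibility_p."""
    if lambda_bg < 0:
        raise ValueError("lambda_bg must be non-negative")
    k = 1
    while stats.poisson.sf(k - 1, lambda_bg) >= eligibility_p:
        k += 1
    return k


def call_islands(
    counts: dict[str, np.ndarray],
    params: IslandParams,
    lambda_bg: float | None = None,
) -> list[Island]:
    """Chain eligible windows into scored islands.

    ``lambda_bg`` (expected fragments per window under background) defaults
    to total fragments * window_size / (effective_genome_fraction * genome
    size).  Island score = sum over eligible member windows of
    -ln P(X >= count | Poisson(lambda_bg)); islands scoring below
    ``island_score_threshold`` are dropped.  Returned islands are disjoint
    and sorted by (chrom, start).
    """
    n_windows = sum(len(c) for c in counts.values())
    total = sum(int(c.sum()) for c in counts.values())
    if lambda_bg is None:
        if n_windows == 0:
            raise ValueError("empty genome")
        lambda_bg = total / (params.effective_genome_fraction * n_windows)
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be positive")
    k_min = eligible_threshold(lambda_bg, params.eligibility_p)
    max_gap_windows = params.gap_size // params.window_size
    w = params.window_size

    islands: list[Island] = []
    for chrom in sorted(counts):
        c = counts[chrom]
        eligible = np.flatnonzero(c >= k_min)
        if eligible.size == 0:
            continue
        # group eligible windows whose internal non-eligible run <= gap
        breaks = np.flatnonzero(np.diff(eligible) - 1 > max_gap_windows)
        starts_grp = np.concatenate([[0], breaks + 1])
        ends_grp = np.concatenate([breaks, [eligible.size - 1]])
        chrom_end = len(c) * w
        for g0, g1 in zip(starts_grp, ends_grp):
            first, last = int(eligible[g0]), int(eligible[g1])
            members = eligible[g0:g1 + 1]
            # logsf avoids log(0) underflow for strongly enriched windows
            terms = -stats.poisson.logsf(c[members] - 1, lambda_bg)
            score = float(np.minimum(terms, 1e6).sum())
            if score < params.island_score_threshold:
                continue
            read_count = int(c[first:last + 1].sum())
            islands.append(
                Island(
                    interval=GenomicInterval(
                        chrom, first * w, min((last + 1) * w, chrom_end)
                    ),
                    score=score,
                    read_count=read_count,
                )
            )
    return islands


def _count_in_intervals(fragments: pd.DataFrame,
                        intervals: list[GenomicInterval]) -> np.ndarray:
    """Midpoint counts per interval (intervals may overlap; each counted)."""
    out = np.zeros(len(intervals), dtype=np.int64)
    if fragments.empty or not intervals:
        return out
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    mids = midpoints(fragments)
    groups = fragments.groupby("chrom", sort=False).indices
    for chrom, items in by_chrom.items():
        idx = groups.get(chrom)
        if idx is None:
            continue
        m = np.sort(mids[idx])
        for i, iv in items:
            lo = np.searchsorted(m, iv.start, side="left")
            hi = np.searchsorted(m, iv.end, side="left")
            out[i] = hi - lo
    return out


def fdr_filter_vs_control(
    islands: list[Island],
    treatment_fragments: pd.DataFrame,
    control_fragments: pd.DataFrame,
    alpha: float = 0.05,
) -> list[Island]:
    """Keep islands enriched in treatment over a nonspecific control.

    Per island, a one-sided binomial test of the treatment midpoint count
    against the expectation from the control density in the same interval
    (library-size scaled): k_i ~ Binomial(N_treat, c_i / N_control) under the
    null.  Benjamini-Hochberg adjustment across islands; islands with
    q < alpha are returned with their q-values attached.
    """
    if len(control_fragments) == 0:
        raise ValueError("empty control library")
    if not islands:
        return []
    ivs = [isl.interval for isl in islands]
    k = _count_in_intervals(treatment_fragments, ivs)
    c = _count_in_intervals(control_fragments, ivs)
    n_t = len(treatment_fragments)
    n_c = len(control_fragments)
    pvals = np.empty(len(islands))
    for i in range(len(islands)):
        p0 = c[i] / n_c
        if p0 == 0.0:
            pvals[i] = 0.0 if k[i] > 0 else 1.0
        elif p0 >= 1.0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.binomtest(int(k[i]), n_t, p0, alternative="greater").pvalue
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    retained = []
    for isl, q, rej in zip(islands, qvals, reject):
        isl.qvalue = float(q)
        if rej and q < alpha:
            retained.append(isl)
    return retained


def overlap_sets(
    peaks_a: list[GenomicInterval],
    peaks_b: list[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval],
           list[GenomicInterval], list[GenomicInterval]]:
    """Split two peak sets by >= 1 bp overlap with the other set.

    Returns (a_only, b_only, a_overlapping, b_overlapping); the counts of
    these four lists are the Venn-diagram quantities reported from each side.
    """
    trees_b: dict[str, IntervalTree] = {}
    for iv in peaks_b:
        trees_b.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    trees_a: dict[str, IntervalTree] = {}
    for iv in peaks_a:
        trees_a.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def split(peaks, trees):
        only, overlapping = [], []
        for iv in peaks:
            tree = trees.get(iv.chrom)
            if tree is not None and tree.overlaps(iv.start, iv.end):
                overlapping.append(iv)
            else:
                only.append(iv)
        return only, overlapping

    a_only, a_over = split(peaks_a, trees_b)
    b_only, b_over = split(peaks_b, trees_a)
    return a_only, b_only, a_over, b_over


def peak_cpm_correlation(
    fragments_a: pd.DataFrame,
    fragments_b: pd.DataFrame,
    shared_peaks: list[GenomicInterval],
) -> float:
    """Spearman correlation of per-peak CPM between two libraries.

    Counts per peak are scaled to counts per million of each library's total
    fragment count; ties receive average ranks (scipy convention).
    """
    if len(shared_peaks) < 2:
        raise ValueError("need at least 2 shared peaks")
    ka = _count_in_intervals(fragments_a, shared_peaks)
    kb = _count_in_intervals(fragments_b, shared_peaks)
    cpm_a = ka * 1e6 / len(fragments_a)
    cpm_b = kb * 1e6 / len(fragments_b)
    rho, _ = stats.spearmanr(cpm_a, cpm_b)
    return float(rho)
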