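"""Combinatorial-barcode demultiplexing of paired reads into per-cell fragments.

Read layout: the 5' complex barcode opens read 1 and the 3' complex barcode
opens read 2 (offsets configurable); the per-well library index travels in
the Illumina read-name index field and is matched exactly, since it selects
a physical PCR well and an error there is unrecoverable by design.  Complex
barcodes are matched against the manifest whitelists with up to
``max_mismatch`` substitutions; a tie at the minimal distance is ambiguous
and the pair is discarded.

Fragment coordinates are taken from the read names (``F<i>:<chrom>:<start>:<end>``
as emitted by the simulator, or equivalently by an external aligner's
name-annotation step); the pipeline itself performs no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .io import BarcodeManifest, _open_text
from .simulate import cell_label

__all__ = [
    "UNASSIGNED",
    "DemuxStats",
    "match_barcode",
    "demultiplex",
    "deduplicate",
    "cell_table",
]

#: Sentinel returned when a barcode cannot be resolved uniquely.
UNASSIGNED = None


@dataclass
class DemuxStats:
    total_read_pairs: int = 0
    assigned: int = 0
    unassigned_no_combo: int = 0
    unassigned_ambiguous: int = 0
    corrected: int = 0
    unique_fragments_after_dedup: int = 0

    def validate(self) -> None:
        if self.assigned + self.unassigned_no_combo + self.unassigned_ambiguous \
                != self.total_read_pairs:
            raise AssertionError("demux accounting does not balance")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_barcode(observed: str, whitelist: list[str], max_mismatch: int = 1):
    """Resolve an observed sequence against a whitelist.

    Returns the unique whitelist entry within Hamming distance
    ``max_mismatch``; :data:`UNASSIGNED` if none qualifies or if two entries
    tie at the minimal distance.
    """
    if not whitelist:
        return UNASSIGNED
    if len(observed) != len(whitelist[0]):
        raise ValueError(
            f"observed length {len(observed)} != whitelist length {len(whitelist[0])}"
        )
    best, best_d, tied = UNASSIGNED, max_mismatch + 1, False
    for entry in whitelist:
        d = hamming(observed, entry)
        if d < best_d:
            best, best_d, tied = entry, d, False
        elif d == best_d:
            tied = True
    if best_d > max_mismatch or tied:
        return UNASSIGNED
    return best


_AMBIGUOUS = object()


def _neighbor_lookup(whitelist: list[str], max_mismatch: int) -> dict[str, tuple[int, int]]:
    """Map sequence -> (whitelist index, distance) for all distance<=mm neighbors.

    An entry colliding between two whitelist members at the same distance maps
    to ambiguity (dropped).  Exact whitelist sequences always win over a
    neighbor of another entry (minimal-distance rule).
    """
    table: dict[str, tuple[int, int] | object] = {}
    for i, seq in enumerate(whitelist):
        table[seq] = (i, 0)
    if max_mismatch >= 1:
        for i, seq in enumerate(whitelist):
            for pos in range(len(seq)):
                for base in "ACGT":
                    if base == seq[pos]:
                        continue
                    mut = seq[:pos] + base + seq[pos + 1:]
                    prev = table.get(mut)
                    if prev is None:
                        table[mut] = (i, 1)
                    elif prev is not _AMBIGUOUS and prev[1] == 1 and prev[0] != i:
                        table[mut] = _AMBIGUOUS
    return table  # type: ignore[return-value]


def _parse_coordinates(title: str) -> tuple[str, int, int, str]:
    """Split a read title into (chrom, start, end, index-field sequence)."""
    name, _, desc = title.partition(" ")
    parts = name.split(":")
    if len(parts) < 4:
        raise ValueError(f"read name {name!r} carries no coordinates")
    chrom, start, end = parts[-3], int(parts[-2]), int(parts[-1])
    index_seq = desc.rsplit(":", 1)[-1] if desc else ""
    return chrom, start, end, index_seq


def demultiplex(
    r1_path: str | Path,
    r2_path: str | Path,
    manifest: BarcodeManifest,
    max_mismatch: int = 1,
    barcode5_offset: int = 0,
    barcode3_offset: int = 0,
) -> tuple[pd.DataFrame, DemuxStats]:
    """Assign read pairs to apparent cells and emit deduplicated fragments.

    A pair is assigned iff its well index matches a manifest library index
    exactly, both complex barcodes resolve unambiguously, and the resolved
    (5', 3') pair is one of the manifest's combos.  Returns the deduplicated
    fragment table plus assignment statistics.
    """
    L = manifest.barcode_length
    if not 0 <= max_mismatch <= 1:
        raise ValueError("max_mismatch must be 0 or 1")
    lut5 = _neighbor_lookup(manifest.set5, max_mismatch)
    lut3 = _neighbor_lookup(manifest.set3, max_mismatch)
    combo_of = {
        (manifest.set5.index(b5), manifest.set3.index(b3)): k
        for k, (b5, b3) in enumerate(manifest.combos)
    }
    well_of = {seq: w for w, seq in enumerate(manifest.well_indexes)}

    stats = DemuxStats()
    rows: list[tuple[str, int, int, str]] = []
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (t1, s1, _), (t2, s2, _) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            stats.total_read_pairs += 1
            obs5 = s1[barcode5_offset:barcode5_offset + L]
            obs3 = s2[barcode3_offset:barcode3_offset + L]
            if len(obs5) < L or len(obs3) < L:
                raise ValueError("read shorter than configured barcode region")
            chrom, start, end, index_seq = _parse_coordinates(t1)
            well = well_of.get(index_seq)
            hit5 = lut5.get(obs5)
            hit3 = lut3.get(obs3)
            if hit5 is _AMBIGUOUS or hit3 is _AMBIGUOUS:
                stats.unassigned_ambiguous += 1
                continue
            if well is None or hit5 is None or hit3 is None:
                stats.unassigned_no_combo += 1
                continue
            i5, d5 = hit5  # type: ignore[misc]
            i3, d3 = hit3  # type: ignore[misc]
            combo = combo_of.get((i5, i3))
            if combo is None:
                stats.unassigned_no_combo += 1
                continue
            stats.assigned += 1
            if d5 or d3:
                stats.corrected += 1
            rows.append((chrom, start, end, cell_label(well, combo)))

    raw = pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_id"])
    raw["duplicate_count"] = 1
    frags = deduplicate(raw)
    stats.unique_fragments_after_dedup = len(frags)
    stats.validate()
    return frags, stats


def deduplicate(fragments: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (cell_id, chrom, start, end) rows.

    ``duplicate_count`` of the collapsed row is the summed multiplicity.
    Output is sorted by (chrom, start, end); the operation is idempotent.
    """
    if fragments.empty:
        return fragments.copy()
    out = (
        fragments.groupby(["cell_id", "chrom", "start", "end"], sort=False)
        ["duplicate_count"].sum().reset_index()
    )
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return out[["chrom", "start", "end", "cell_id", "duplicate_count"]]


def cell_table(fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-apparent-cell library table: well, combo, unique fragment count.

    Well and combo are recovered from the canonical cell label where present;
    foreign cell_ids get well/combo -1.
    """
    if fragments.empty:
        return pd.DataFrame(
            columns=["cell_id", "well", "combo", "n_unique_fragments"]
        ).astype({"well": int, "combo": int, "n_unique_fragments": int})
    counts = fragments.groupby("cell_id", sort=True).size().rename("n_unique_fragments")
    table = counts.reset_index()

    def parse(cid: str, which: int) -> int:
        parts = cid.split("+")
        if len(parts) == 2 and parts[0][:1] == "W" and parts[1][:1] == "C":
            try:
                return int(parts[which][1:])
            except ValueError:
                return -1
        return -1

    table["well"] = [parse(c, 0) for c in table["cell_id"]]
    table["combo"] = [parse(c, 1) for c in table["cell_id"]]
    return table[["cell_id", "well", "combo", "n_unique_fragments"]]
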