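"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention), everywhere.
Converting a 1-based inclusive source (e.g. GFF) to this convention is the
caller's responsibility.

Formats
-------
* fragment file: 4-5 column TSV ``chrom  start  end  cell_id  [duplicate_count]``,
  the de-facto single-cell fragments dialect; optionally gzipped.
* BED3 / BED6 interval files.
* bedGraph coverage tracks.
* barcode manifest: sectioned TSV (``set5`` / ``set3`` / ``combo`` / ``well``
  record types in column 1).

Gzip is sniffed from the ``.gz`` extension on every path.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Fragment",
    "BarcodeManifest",
    "read_fragments",
    "write_fragments",
    "load_fragments",
    "save_fragments",
    "read_intervals",
    "write_intervals",
    "write_bedgraph",
    "read_barcode_manifest",
    "write_barcode_manifest",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell_id", "duplicate_count"]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Fragment:
    """One deduplicated tagmentation insertion attributed to a cell barcode."""

    interval: GenomicInterval
    cell_id: str
    duplicate_count: int = 1

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")


@dataclass
class BarcodeManifest:
    """The combinatorial barcode sets of an indexed tagmentation design.

    ``combos`` are the (5', 3') complex-barcode pairs actually loaded into
    transposase complexes (one per first-plate well); ``well_indexes`` are the
    PCR library indexes of the second plate.
    """

    set5: list[str]
    set3: list[str]
    combos: list[tuple[str, str]] = field(default_factory=list)
    well_indexes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def barcode_length(self) -> int:
        return len(self.set5[0]) if self.set5 else 0

    @property
    def well_index_length(self) -> int:
        return len(self.well_indexes[0]) if self.well_indexes else 0

    def validate(self) -> None:
        for name, seqs in (
            ("set5", self.set5),
            ("set3", self.set3),
            ("well_indexes", self.well_indexes),
        ):
            if not seqs:
                continue
            length = len(seqs[0])
            for s in seqs:
                if len(s) != length:
                    raise ValueError(f"{name}: mixed barcode lengths {len(s)} vs {length}")
                if set(s) - set("ACGT"):
                    raise ValueError(f"{name}: non-ACGT characters in {s!r}")
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"{name}: duplicate sequences")
        if len(set(self.combos)) != len(self.combos):
            raise ValueError("duplicate (5',3') combo")
        known5, known3 = set(self.set5), set(self.set3)
        for b5, b3 in self.combos:
            if b5 not in known5 or b3 not in known3:
                raise ValueError(f"combo ({b5},{b3}) uses sequences absent from set5/set3")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# fragment files
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path) -> Iterator[Fragment]:
    """Stream fragments from a 4-5 column TSV, in file order.

    A missing fifth column defaults ``duplicate_count`` to 1.  Malformed
    lines raise :class:`ValueError` naming the 1-based line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise ValueError(
                    f"{path}, line {lineno}: expected 4 or 5 columns, got {len(fields)}"
                )
            try:
                chrom, start, end, cell_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
                dup = int(fields[4]) if len(fields) == 5 else 1
                yield Fragment(GenomicInterval(chrom, start, end), cell_id, dup)
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for frag in fragments:
            iv = frag.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.cell_id}\t{frag.duplicate_count}\n"
            )


def load_fragments(path: str | Path) -> pd.DataFrame:
    """Load a fragment file into the pipeline's in-memory table.

    Columns: chrom, start, end, cell_id, duplicate_count.  This is the fast
    bulk loader; :func:`read_fragments` is the validating streaming reader.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment=None,
        names=FRAGMENT_COLUMNS, dtype={"chrom": str, "cell_id": str},
    )
    if df["duplicate_count"].isna().any():
        df["duplicate_count"] = df["duplicate_count"].fillna(1)
    df["duplicate_count"] = df["duplicate_count"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).idxmax()) + 1
        raise ValueError(f"{path}, line {bad}: start >= end")
    return df


def save_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format: str = "BED6") -> list[GenomicInterval]:
    """Read a BED3 or BED6 file; track/browser/comment lines are skipped.

    BED3 yields unstranded intervals.  A line whose column count does not
    match the declared dialect raises with its line number.
    """
    if format not in ("BED3", "BED6"):
        raise ValueError(f"format must be BED3 or BED6, got {format!r}")
    want = 3 if format == "BED3" else 6
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise ValueError(
                    f"{path}, line {lineno}: {format} requires {want} columns, got {len(fields)}"
                )
            try:
                strand = fields[5] if want == 6 else "."
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path,
                    format: str = "BED6") -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if format == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    """Write a 4-column bedGraph.

    Bins must be sorted and non-overlapping within each chromosome.  Runs of
    equal-valued adjacent bins are merged; zero-valued bins are omitted.
    """
    with _open_text(path, "wt") as fh:
        pending: list | None = None  # [chrom, start, end, value]
        for chrom, start, end, value in track:
            if pending is not None and pending[0] == chrom and start < pending[2]:
                raise ValueError(f"overlapping bins on {chrom} at {start}")
            if (
                pending is not None
                and pending[0] == chrom
                and pending[2] == start
                and pending[3] == value
            ):
                pending[2] = end
                continue
            if pending is not None and pending[3] != 0:
                fh.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")
            pending = [chrom, start, end, value]
        if pending is not None and pending[3] != 0:
            fh.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")


# ---------------------------------------------------------------------------
# barcode manifest
# ---------------------------------------------------------------------------

def read_barcode_manifest(path: str | Path) -> BarcodeManifest:
    """Read the sectioned TSV manifest (set5 / set3 / combo / well records)."""
    set5: list[str] = []
    set3: list[str] = []
    combos: list[tuple[str, str]] = []
    wells: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "set5" and len(fields) == 2:
                set5.append(fields[1])
            elif kind == "set3" and len(fields) == 2:
                set3.append(fields[1])
            elif kind == "combo" and len(fields) == 3:
                combos.append((fields[1], fields[2]))
            elif kind == "well" and len(fields) == 2:
                wells.append(fields[1])
            else:
                raise ValueError(f"{path}, line {lineno}: unrecognized record {line!r}")
    return BarcodeManifest(set5=set5, set3=set3, combos=combos, well_indexes=wells)


def write_barcode_manifest(manifest: BarcodeManifest, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for s in manifest.set5:
            fh.write(f"set5\t{s}\n")
        for s in manifest.set3:
            fh.write(f"set3\t{s}\n")
        for b5, b3 in manifest.combos:
            fh.write(f"combo\t{b5}\t{b3}\n")
        for s in manifest.well_indexes:
            fh.write(f"well\t{s}\n")
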