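"""Readers and writers for the BED-family text formats the pipeline touches.

Supported formats: BED6 / tagAlign for tags (column 5 is taken as MAPQ in
both dialects), BED3+ for region sets, UCSC two-column chrom.sizes for genome
layouts, and bedGraph for binned coverage tracks. All genomic text formats
here are 0-based half-open, matching the in-memory convention, so readers and
writers do no coordinate shifting.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    FormatError,
    GenomeLayout,
    RegionSet,
    TAG_COLUMNS,
    empty_tags,
)

logger = logging.getLogger(__name__)

_TAG_FORMATS = ("bed6", "tagalign")


def read_chrom_sizes(path, species_label: str) -> GenomeLayout:
    """Read a UCSC chrom.sizes file (name TAB length) into a layout."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
            chroms.append((fields[0], length))
    return GenomeLayout(species_label, tuple(chroms))


def write_chrom_sizes(genome: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_tags(path, format: str, genome: GenomeLayout) -> pd.DataFrame:
    """Read aligned tags from a BED6 or tagAlign file.

    Records on chromosomes absent from ``genome`` are dropped; the dropped
    count is logged and stored in ``df.attrs["n_dropped"]``. Coordinates are
    validated against chromosome lengths; a malformed line raises
    :class:`FormatError` naming the line number.
    """
    if format not in _TAG_FORMATS:
        raise ValueError(f"unknown tag format {format!r}; expected one of {_TAG_FORMATS}")
    rows: list[tuple[str, int, int, str, int]] = []
    n_dropped = 0
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                mapq = int(float(fields[4]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if chrom not in lengths:
                n_dropped += 1
                continue
            if not (0 <= start < end <= lengths[chrom]):
                raise FormatError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"{chrom} (length {lengths[chrom]})"
                )
            rows.append((chrom, start, end, strand, mapq))
    if rows:
        df = pd.DataFrame(rows, columns=list(TAG_COLUMNS)).astype(
            {"start": np.int64, "end": np.int64, "mapq": np.int64}
        )
    else:
        df = empty_tags()
    df.attrs["n_dropped"] = n_dropped
    if n_dropped:
        logger.info(
            "%s: dropped %d records on chromosomes absent from the %s layout",
            path, n_dropped, genome.species_label,
        )
    return df


def write_tags(tags: pd.DataFrame, path, name_prefix: str = "t") -> None:
    """Write a tag table as BED6 (name column generated, score column = MAPQ)."""
    with open(path, "w") as fh:
        for i, r in enumerate(tags.itertuples(index=False)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name_prefix}{i}\t{r.mapq}\t{r.strand}\n")


def read_regions(path) -> RegionSet:
    """Read a BED3+ file into a normalized (sorted, merged) region set."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((fields[0], start, end))
    return RegionSet(intervals)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def format_value(value: float, sig_digits: int = 4) -> str:
    """Fixed-decimal representation with at most ``sig_digits`` significant digits."""
    if value == 0:
        return "0"
    return np.format_float_positional(
        value, precision=sig_digits, unique=True, fractional=False, trim="-"
    )


def write_bedgraph(track, path, sig_digits: int = 4) -> None:
    """Write a :class:`~chipspike.preprocess.BinTrack` as bedGraph.

    Zero-valued bins are omitted; runs of identically-formatted adjacent bins
    are merged into one record. Values are quantized to ``sig_digits``
    significant digits, so a read-back reproduces the track at that precision.
    """
    genome = track.genome
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes:
            values = track.values[chrom]
            run_start = None
            run_repr = None
            for i, v in enumerate(values):
                rep = format_value(float(v), sig_digits) if v != 0 else None
                if rep != run_repr:
                    if run_repr is not None:
                        fh.write(f"{chrom}\t{run_start * bw}\t{min(i * bw, length)}\t{run_repr}\n")
                    run_start, run_repr = i, rep
            if run_repr is not None:
                fh.write(f"{chrom}\t{run_start * bw}\t{min(len(values) * bw, length)}\t{run_repr}\n")


def read_bedgraph(path, genome: GenomeLayout, bin_width: int):
    """Read a bedGraph written on a bin grid back into a BinTrack."""
    from .preprocess import BinTrack  # local import to avoid a cycle

    track = BinTrack.zeros(genome, bin_width)
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in lengths:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start % bin_width or (end % bin_width and end != lengths[chrom]):
                raise FormatError(f"{path}:{lineno}: record not aligned to {bin_width}-bp bins")
            b0 = start // bin_width
            b1 = -(-end // bin_width)
            track.values[chrom][b0:b1] = value
    return track


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_islands(islands: Iterable, bed_path, tsv_path=None) -> None:
    """Write called islands as BED5 plus an optional full-precision TSV.

    The BED score column is the island score clipped to the UCSC 0-1000 range.
    """
    islands = list(islands)
    with open(bed_path, "w") as fh:
        for i, isl in enumerate(islands):
            score = int(min(1000, max(0, round(isl.score))))
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland_{i}\t{score}\n")
    if tsv_path is not None:
        df = pd.DataFrame(
            [(isl.chrom, isl.start, isl.end, isl.score, isl.tag_count) for isl in islands],
            columns=["chrom", "start", "end", "score", "tag_count"],
        )
        write_tsv(df, tsv_path, float_format="%.10g")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
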