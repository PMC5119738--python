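"""Core domain types for two-species ChIP-seq tag data.

Coordinates are 0-based half-open (BED-native) everywhere in the library;
conversion to and from text formats lives in :mod:`chipspike.io`.

Bulk tag collections are plain :class:`pandas.DataFrame` objects with the
columns ``chrom, start, end, strand, mapq`` (see :data:`TAG_COLUMNS`); the
:class:`Tag` dataclass exists for record-level construction and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

TAG_COLUMNS = ("chrom", "start", "end", "strand", "mapq")
FRAGMENT_COLUMNS = ("chrom", "start", "end", "strand")

#: delimiter between the species label and the chromosome name in combined
#: (single-file) tag sets, e.g. ``fly_chr2R``.
SPECIES_DELIMITER = "_"


class ChipSpikeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ChipSpikeError):
    """A text input could not be parsed or failed validation."""


@dataclass(frozen=True)
class Tag:
    """One aligned sequence tag.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``'+'`` or ``'-'``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid tag interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths for one species.

    Defines the coordinate space and the species label used to partition
    combined tag sets.
    """

    species_label: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


def empty_tags() -> pd.DataFrame:
    """An empty tag table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "mapq": pd.Series(dtype=np.int64),
        }
    )


def tags_from_records(records: Iterable[Tag]) -> pd.DataFrame:
    """Build a tag table from :class:`Tag` records."""
    rows = [(t.chrom, t.start, t.end, t.strand, t.mapq) for t in records]
    if not rows:
        return empty_tags()
    return pd.DataFrame(rows, columns=list(TAG_COLUMNS)).astype(
        {"start": np.int64, "end": np.int64, "mapq": np.int64}
    )


def tags_to_records(tags: pd.DataFrame) -> list[Tag]:
    return [
        Tag(r.chrom, int(r.start), int(r.end), r.strand, int(r.mapq))
        for r in tags.itertuples(index=False)
    ]


def validate_tags(tags: pd.DataFrame, genome: GenomeLayout) -> None:
    """Check every tag fits inside its chromosome; raise :class:`FormatError`."""
    if tags.empty:
        return
    lengths = genome.lengths
    unknown = set(tags["chrom"]) - set(lengths)
    if unknown:
        raise FormatError(
            f"tags on chromosomes absent from {genome.species_label} layout: "
            f"{sorted(unknown)}"
        )
    chrom_len = tags["chrom"].map(lengths).to_numpy()
    start = tags["start"].to_numpy()
    end = tags["end"].to_numpy()
    bad = (start < 0) | (start >= end) | (end > chrom_len)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"tag {i} has invalid interval [{start[i]}, {end[i]}) on "
            f"{tags['chrom'].iloc[i]} (length {chrom_len[i]})"
        )
    if not tags["strand"].isin(["+", "-"]).all():
        raise FormatError("tag strand must be '+' or '-'")


def five_prime_positions(tags: pd.DataFrame) -> np.ndarray:
    """0-based coordinate of each tag's 5' base: ``start`` on ``+``, ``end-1`` on ``-``."""
    start = tags["start"].to_numpy(np.int64, copy=False)
    end = tags["end"].to_numpy(np.int64, copy=False)
    minus = (tags["strand"] == "-").to_numpy()
    return np.where(minus, end - 1, start)


class RegionSet:
    """A sorted, non-overlapping set of genomic intervals (0-based half-open).

    Construction normalizes the input: intervals are sorted and overlapping or
    book-ended intervals on the same chromosome are merged, which makes
    normalization idempotent.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        merged: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end or start < 0:
                raise ValueError(f"invalid interval [{start}, {end}) on {chrom}")
            if chrom not in by_chrom:
                by_chrom[chrom] = []
                order.append(chrom)
            by_chrom[chrom].append((start, end))
        for chrom in sorted(order):
            ivals = sorted(by_chrom[chrom])
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s <= cur_e:  # overlap or adjacency
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        self._intervals: tuple[tuple[str, int, int], ...] = tuple(merged)

    @property
    def intervals(self) -> tuple[tuple[str, int, int], ...]:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self._intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Map chrom -> (n, 2) array of [start, end) rows."""
        out: dict[str, list[list[int]]] = {}
        for chrom, s, e in self._intervals:
            out.setdefault(chrom, []).append([s, e])
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def contains_points(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorized point-in-region membership test.

        Returns a boolean array: ``True`` where ``positions[i]`` falls inside an
        interval of this set on ``chroms[i]``.
        """
        positions = np.asarray(positions, dtype=np.int64)
        result = np.zeros(len(positions), dtype=bool)
        if not len(self._intervals) or not len(positions):
            return result
        chroms = np.asarray(chroms, dtype=object)
        for chrom, arr in self.by_chrom().items():
            mask = chroms == chrom
            if not mask.any():
                continue
            pos = positions[mask]
            # interval index whose start is the rightmost <= pos
            idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
            inside = (idx >= 0) & (pos < arr[np.clip(idx, 0, None), 1])
            result[mask] = inside
        return result

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self) + list(other))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._intervals, columns=["chrom", "start", "end"])


@dataclass
class SampleLibrary:
    """All tags of one ChIP reaction, partitioned by species.

    ``tags_by_species`` maps a species label (matching a
    :class:`GenomeLayout.species_label`) to a tag table.
    """

    sample_id: str
    treatment: str
    mark: str
    tags_by_species: dict[str, pd.DataFrame] = field(default_factory=dict)

    def n_tags(self, species: str) -> int:
        df = self.tags_by_species.get(species)
        return 0 if df is None else len(df)

    @property
    def total_tags(self) -> int:
        return sum(len(df) for df in self.tags_by_species.values())

    def replace_tags(self, species: str, tags: pd.DataFrame) -> "SampleLibrary":
        new = dict(self.tags_by_species)
        new[species] = tags
        return SampleLibrary(self.sample_id, self.treatment, self.mark, new)


def partition_species(
    tags,
    layouts: Sequence[GenomeLayout],
    mode: str = "prefixed_chroms",
    *,
    sample_id: str = "sample",
    treatment: str = "",
    mark: str = "",
) -> SampleLibrary:
    """Assign tags to species buckets.

    In ``prefixed_chroms`` mode ``tags`` is a single tag table whose chromosome
    names carry a ``<species_label>_`` prefix; the prefix is stripped in the
    output. In ``separate_files`` mode ``tags`` is a mapping
    ``species_label -> tag table`` (one aligned file per species) and the tags
    are validated against the matching layout. Total tag count is conserved.
    """
    by_label = {g.species_label: g for g in layouts}
    if len(by_label) != len(layouts):
        raise ValueError("duplicate species labels among layouts")

    if mode == "separate_files":
        if not isinstance(tags, Mapping):
            raise ValueError("separate_files mode expects a mapping species -> tag table")
        unknown = set(tags) - set(by_label)
        if unknown:
            raise FormatError(f"unknown species labels: {sorted(unknown)}")
        buckets = {label: empty_tags() for label in by_label}
        for label, df in tags.items():
            validate_tags(df, by_label[label])
            buckets[label] = df.reset_index(drop=True)
        return SampleLibrary(sample_id, treatment, mark, buckets)

    if mode != "prefixed_chroms":
        raise ValueError(f"unknown partition mode {mode!r}")

    df = tags
    buckets = {label: empty_tags() for label in by_label}
    if df.empty:
        return SampleLibrary(sample_id, treatment, mark, buckets)

    prefix = df["chrom"].str.split(SPECIES_DELIMITER, n=1, expand=True)
    if prefix.shape[1] < 2 or prefix[1].isna().any() or not prefix[0].isin(by_label).all():
        bad = sorted(set(df["chrom"][~prefix[0].isin(by_label) | prefix[1].isna()]))
        raise FormatError(f"chromosome names with unresolvable species prefix: {bad}")
    total = 0
    for label in by_label:
        sub = df[prefix[0] == label].copy()
        sub["chrom"] = prefix.loc[sub.index, 1]
        sub = sub.reset_index(drop=True)
        validate_tags(sub, by_label[label])
        buckets[label] = sub
        total += len(sub)
    assert total == len(df), "species partition must conserve tag count"
    return SampleLibrary(sample_id, treatment, mark, buckets)
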