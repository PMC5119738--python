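"""Tag-level filtering and the tag -> fragment -> binned-coverage transform.

The preprocessing chain mirrors a conventional broad-mark ChIP-seq workflow:
keep uniquely-mapped tags (MAPQ strictly greater than a threshold), remove
PCR duplicates by their 5' alignment position, extend each tag at its 3' end
to the average fragment length, and accumulate fragment coverage into
fixed-width genomic bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import FRAGMENT_COLUMNS, GenomeLayout, SampleLibrary, five_prime_positions


@dataclass(frozen=True)
class PreprocessParams:
    """Tag-filtering and binning parameters.

    min_mapq_exclusive
        Tags are kept only if ``mapq > min_mapq_exclusive`` (strict).
    extension_length
        Fragment length each tag is extended to at its 3' end, in bp (the
        average genomic fragment length of the library).
    bin_width
        Width of the coverage bins, in bp.
    """

    min_mapq_exclusive: int = 25
    extension_length: int = 200
    bin_width: int = 32

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.extension_length <= 0:
            raise ValueError("extension_length must be positive")


def filter_mapq(tags: pd.DataFrame, min_mapq_exclusive: int = 25) -> pd.DataFrame:
    """Keep tags with ``mapq`` strictly greater than the threshold, order preserved."""
    return tags[tags["mapq"] > min_mapq_exclusive].reset_index(drop=True)


def deduplicate(tags: pd.DataFrame) -> pd.DataFrame:
    """Remove duplicate tags, keeping the first occurrence per duplicate key.

    The key is ``(chrom, 5' position, strand)``: PCR duplicates share the 5'
    alignment coordinate, and single-end tags of one library all have the same
    length, so the 5' position identifies the molecule.
    """
    if tags.empty:
        return tags.reset_index(drop=True)
    key = pd.DataFrame(
        {"chrom": tags["chrom"], "pos": five_prime_positions(tags), "strand": tags["strand"]}
    )
    keep = ~key.duplicated(keep="first")
    return tags[keep.to_numpy()].reset_index(drop=True)


def extend_tags(
    tags: pd.DataFrame, genome: GenomeLayout, extension_length: int = 200
) -> pd.DataFrame:
    """Extend each tag at its 3' end to ``extension_length`` bp.

    A ``+`` tag [s, e) becomes the fragment [s, s+L) and a ``-`` tag [s, e)
    becomes [e-L, e), clipped at chromosome boundaries. One fragment per tag.
    """
    if tags.empty:
        return pd.DataFrame(columns=list(FRAGMENT_COLUMNS))
    lengths = tags["chrom"].map(genome.lengths).to_numpy(np.int64)
    start = tags["start"].to_numpy(np.int64)
    end = tags["end"].to_numpy(np.int64)
    minus = (tags["strand"] == "-").to_numpy()
    frag_start = np.where(minus, np.maximum(0, end - extension_length), start)
    frag_end = np.where(minus, end, np.minimum(lengths, start + extension_length))
    return pd.DataFrame(
        {
            "chrom": tags["chrom"].to_numpy(),
            "start": frag_start,
            "end": frag_end,
            "strand": tags["strand"].to_numpy(),
        }
    )


@dataclass
class BinTrack:
    """Binned fragment coverage for one species.

    ``values[chrom][i]`` is the mean per-bp fragment coverage of bin ``i``
    (fragment bp overlapping the bin divided by the bin's bp), so the mass
    conservation identity Σ(value × bin bp) = Σ fragment lengths holds exactly.
    """

    genome: GenomeLayout
    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, genome: GenomeLayout, bin_width: int) -> "BinTrack":
        values = {
            name: np.zeros(-(-length // bin_width), dtype=np.float64)
            for name, length in genome.chromosomes
        }
        return cls(genome, bin_width, values)

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Actual bp covered by each bin (the last bin may be truncated)."""
        length = self.genome.lengths[chrom]
        n = len(self.values[chrom])
        widths = np.full(n, self.bin_width, dtype=np.int64)
        if n:
            widths[-1] = length - (n - 1) * self.bin_width
        return widths

    @property
    def total_mass(self) -> float:
        """Σ(value × bin bp covered) over the whole genome."""
        return float(
            sum(
                np.dot(self.values[c], self.bin_widths(c))
                for c, _ in self.genome.chromosomes
            )
        )


def bin_coverage(
    fragments: pd.DataFrame, genome: GenomeLayout, bin_width: int = 32
) -> BinTrack:
    """Accumulate fragment coverage into fixed-width bins.

    Each fragment contributes its per-bin overlap in bp, divided by the bin's
    bp, so total mass is conserved: ``track.total_mass`` equals the summed
    fragment lengths.
    """
    track = BinTrack.zeros(genome, bin_width)
    if fragments.empty:
        return track
    for chrom, sub in fragments.groupby("chrom", sort=False):
        length = genome.lengths[chrom]
        # per-bp coverage via a difference array, then per-bin sums
        diff = np.zeros(length + 1, dtype=np.float64)
        np.add.at(diff, sub["start"].to_numpy(np.int64), 1.0)
        np.add.at(diff, sub["end"].to_numpy(np.int64), -1.0)
        cov = np.cumsum(diff[:-1])
        edges = np.arange(0, length, bin_width)
        bin_bp = np.add.reduceat(cov, edges)
        track.values[chrom] = bin_bp / track.bin_widths(chrom)
    return track


def preprocess_tags(tags: pd.DataFrame, params: PreprocessParams) -> pd.DataFrame:
    """MAPQ filter then deduplication, in that fixed order."""
    return deduplicate(filter_mapq(tags, params.min_mapq_exclusive))


def preprocess_library(
    lib: SampleLibrary,
    genomes: Mapping[str, GenomeLayout],
    params: PreprocessParams = PreprocessParams(),
) -> tuple[SampleLibrary, dict[str, pd.DataFrame], pd.DataFrame]:
    """Apply the tag filters identically to every species bucket.

    Returns the filtered library, per-species extended-fragment tables, and a
    per-species report of tag counts after each step.
    """
    new_tags: dict[str, pd.DataFrame] = {}
    fragments: dict[str, pd.DataFrame] = {}
    rows = []
    for species, tags in lib.tags_by_species.items():
        kept = filter_mapq(tags, params.min_mapq_exclusive)
        n_mapq = len(kept)
        kept = deduplicate(kept)
        new_tags[species] = kept
        fragments[species] = extend_tags(kept, genomes[species], params.extension_length)
        rows.append((lib.sample_id, species, len(tags), n_mapq, len(kept)))
    report = pd.DataFrame(
        rows, columns=["sample_id", "species", "n_input", "n_after_mapq", "n_after_dedup"]
    )
    filtered = SampleLibrary(lib.sample_id, lib.treatment, lib.mark, new_tags)
    return filtered, fragments, report
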