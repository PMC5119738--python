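"""Union peak regions, per-region signal, and fold-change summaries.

Peak regions are the union of island intervals across conditions; for each
region and sample the *average signal* is reported as fragment bp overlapping
the region divided by region bp, i.e. mean per-bp fragment coverage, the same
unit as the binned tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_tsv
from .islands import Island
from .model import GenomeLayout, RegionSet


def union_regions(island_sets: Iterable[Sequence[Island]]) -> RegionSet:
    """Merged, sorted, disjoint union of island intervals across samples."""
    intervals = [
        (isl.chrom, isl.start, isl.end) for islands in island_sets for isl in islands
    ]
    return RegionSet(intervals)


def region_signal(
    regions: RegionSet, fragments: pd.DataFrame, genome: GenomeLayout
) -> np.ndarray:
    """Average signal per region: fragment bp overlapping ÷ region bp."""
    values = np.zeros(len(regions), dtype=np.float64)
    if fragments.empty or not len(regions):
        return values
    by_chrom = regions.by_chrom()
    # region index within the full (sorted) set, per chromosome
    offsets: dict[str, int] = {}
    pos = 0
    for chrom, _s, _e in regions:
        offsets.setdefault(chrom, pos)
        pos += 1
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        length = genome.lengths[chrom]
        diff = np.zeros(length + 1, dtype=np.float64)
        np.add.at(diff, sub["start"].to_numpy(np.int64), 1.0)
        np.add.at(diff, sub["end"].to_numpy(np.int64), -1.0)
        prefix = np.concatenate(([0.0], np.cumsum(np.cumsum(diff[:-1]))))
        arr = by_chrom[chrom]
        overlap_bp = prefix[arr[:, 1]] - prefix[arr[:, 0]]
        o = offsets[chrom]
        values[o : o + len(arr)] = overlap_bp / (arr[:, 1] - arr[:, 0])
    return values


@dataclass
class RegionSignalMatrix:
    """Per-region average signal for every sample, plus raw overlap counts.

    ``genome_mean_signal`` records each sample's genome-wide mean per-bp
    coverage (total fragment bp / genome bp), used to set the fold-change
    pseudocount.
    """

    regions: RegionSet
    signals: pd.DataFrame  # one column per sample, one row per region
    genome_mean_signal: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.regions.to_frame()
        return pd.concat([out, self.signals.reset_index(drop=True)], axis=1)


def build_signal_matrix(
    regions: RegionSet,
    fragments_by_sample: Mapping[str, pd.DataFrame],
    genome: GenomeLayout,
) -> RegionSignalMatrix:
    signals = {}
    means = {}
    for sample_id, frags in fragments_by_sample.items():
        signals[sample_id] = region_signal(regions, frags, genome)
        total_bp = float((frags["end"] - frags["start"]).sum()) if len(frags) else 0.0
        means[sample_id] = total_bp / genome.total_length
    return RegionSignalMatrix(regions, pd.DataFrame(signals), means)


def fold_change_summary(
    matrix: RegionSignalMatrix,
    sample_a: str,
    sample_b: str,
    pseudocount: float | None = None,
) -> dict:
    """Per-region ratio summary of sample_a over sample_b.

    A pseudocount is added to numerator and denominator for stability. By
    default each sample gets its own ε = 0.1 × that sample's genome-wide mean
    signal; scaling the prior with the sample's depth (the usual prior-count
    convention in count-based differential analysis) keeps a uniform global
    fold change unshrunken. Passing an explicit ``pseudocount`` uses that
    single value on both sides instead. Returns the median ratio, quartiles
    (box-plot export) and per-region log2 ratios.
    """
    a = matrix.signals[sample_a].to_numpy()
    b = matrix.signals[sample_b].to_numpy()
    if pseudocount is None:
        eps_a = 0.1 * matrix.genome_mean_signal.get(sample_a, 0.0)
        eps_b = 0.1 * matrix.genome_mean_signal.get(sample_b, 0.0)
    else:
        eps_a = eps_b = float(pseudocount)
    pseudocount = (eps_a, eps_b)
    ratios = (a + eps_a) / (b + eps_b)
    log2 = np.log2(ratios)
    q1, med, q3 = (np.quantile(ratios, q) for q in (0.25, 0.5, 0.75)) if len(ratios) else (
        np.nan, np.nan, np.nan)
    return {
        "sample_a": sample_a,
        "sample_b": sample_b,
        "n_regions": len(ratios),
        "pseudocount_a": float(pseudocount[0]),
        "pseudocount_b": float(pseudocount[1]),
        "median_ratio": float(med),
        "q1_ratio": float(q1),
        "q3_ratio": float(q3),
        "ratios": ratios,
        "log2_ratios": log2,
    }


def export_scatter_data(
    matrix: RegionSignalMatrix, sample_a: str, sample_b: str, path
) -> None:
    """TSV with one row per region and both samples' signals (scatter-plot data)."""
    df = matrix.regions.to_frame()
    df[sample_a] = matrix.signals[sample_a].to_numpy()
    df[sample_b] = matrix.signals[sample_b].to_numpy()
    write_tsv(df, path)


def export_boxplot_summary(matrix: RegionSignalMatrix, path) -> None:
    """TSV of per-sample signal quartiles and whiskers (Tukey 1.5 IQR)."""
    rows = []
    for sample_id in matrix.signals.columns:
        v = matrix.signals[sample_id].to_numpy()
        if not len(v):
            rows.append((sample_id, *([np.nan] * 5)))
            continue
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append((sample_id, lo, q1, med, q3, hi))
    write_tsv(
        pd.DataFrame(
            rows, columns=["sample", "whisker_low", "q1", "median", "q3", "whisker_high"]
        ),
        path,
    )
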