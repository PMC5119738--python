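"""Reference-tag counting, correction factors, and downsampling normalization.

The spike-in strategy: every ChIP reaction receives a constant amount of
reference-species chromatin pulled down by a reference-specific antibody
(Drosophila H2Av in the original design). Because the reference recovery is
constant across samples, the per-sample count of reference-species tags is a
between-sample normalization standard: correction factors are the ratio of
the designated reference sample's count to each sample's count, and the
experimental-species tags are rescaled by random tag removal.

Two counting strategies are supported: ``whole_genome`` counts every
reference-species tag, while ``restricted_regions`` counts only tags whose 5'
base falls inside pre-defined reference regions (the H2Av-bound intervals),
which shields the factors from cross-reactive pull-down of reference
chromatin by the experimental antibody.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ChipSpikeError, RegionSet, SampleLibrary, five_prime_positions


@dataclass(frozen=True)
class ReferenceCountingMode:
    """How reference-species tags are counted for the correction factors."""

    mode: str  # "whole_genome" or "restricted_regions"
    regions: RegionSet | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("whole_genome", "restricted_regions"):
            raise ValueError(f"unknown counting mode {self.mode!r}")
        if self.mode == "restricted_regions" and (self.regions is None or len(self.regions) == 0):
            raise ValueError("restricted_regions mode requires a non-empty RegionSet")


@dataclass
class CorrectionTable:
    """Per-sample reference-tag counts and derived scaling factors.

    ``raw_factor`` is reference-sample count / sample count; ``applied_factor``
    rescales the raw factors so the largest is 1, because scaling is realized
    by tag removal only.
    """

    table: pd.DataFrame  # sample_id, reference_tag_count, raw_factor, applied_factor
    reference_sample_id: str
    counting_mode: str

    def factor(self, sample_id: str) -> float:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"no correction factor for sample {sample_id!r}")
        return float(row["applied_factor"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["counting_mode"] = self.counting_mode
        return out


def count_reference_tags(
    lib: SampleLibrary, species: str, mode: ReferenceCountingMode
) -> int:
    """Count one sample's reference-species tags under the given strategy.

    The library must already be preprocessed (MAPQ filter, deduplication)
    identically across the samples being compared. In restricted mode a tag
    counts when its 5' base lies inside a region, a deterministic stand-in for
    mapping against a partial reference built from those regions only.
    """
    if species not in lib.tags_by_species:
        raise ChipSpikeError(
            f"sample {lib.sample_id!r} has no tags for reference species {species!r}"
        )
    tags = lib.tags_by_species[species]
    if mode.mode == "whole_genome":
        return len(tags)
    if tags.empty:
        return 0
    inside = mode.regions.contains_points(
        tags["chrom"].to_numpy(object), five_prime_positions(tags)
    )
    return int(inside.sum())


def compute_correction_factors(
    counts: Mapping[str, int], reference_sample_id: str, counting_mode: str = "whole_genome"
) -> CorrectionTable:
    """Correction factors from per-sample reference-tag counts.

    factor_i = count(reference sample) / count(i); the factors are then
    divided by their maximum so every factor is ≤ 1 (downsampling-only).
    Scale-invariant: multiplying all counts by a constant changes nothing.
    """
    if reference_sample_id not in counts:
        raise KeyError(f"reference sample {reference_sample_id!r} missing from counts")
    bad = [s for s, c in counts.items() if c <= 0]
    if bad:
        raise ChipSpikeError(
            f"zero reference-tag count for sample(s) {bad}; the spike-in yielded "
            "too few tags to normalize — increase the reference chromatin amount "
            "or sequencing depth"
        )
    ref_count = counts[reference_sample_id]
    raw = {s: ref_count / c for s, c in counts.items()}
    top = max(raw.values())
    table = pd.DataFrame(
        {
            "sample_id": list(counts),
            "reference_tag_count": [counts[s] for s in counts],
            "raw_factor": [raw[s] for s in counts],
            "applied_factor": [raw[s] / top for s in counts],
        }
    )
    return CorrectionTable(table, reference_sample_id, counting_mode)


def downsample_tags(
    tags: pd.DataFrame, factor: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Keep a uniform random subset of round(factor × n) tags, order preserved.

    ``round`` is banker's rounding (half to even). Deterministic given the
    seed; ``factor`` must lie in (0, 1].
    """
    if not (0 < factor <= 1):
        raise ValueError(f"downsampling factor must be in (0, 1], got {factor}")
    n = len(tags)
    n_keep = round(factor * n)
    if n_keep == n:
        return tags.reset_index(drop=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    return tags.iloc[keep].reset_index(drop=True)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def standard_normalize(
    samples: Sequence[SampleLibrary], species: str, seed: int = 0
) -> list[SampleLibrary]:
    """Equalize sequencing depth: downsample every sample's experimental-species
    tags to the smallest sample's count.

    This is the conventional normalization; by construction it erases any
    uniform global difference in occupancy between samples.
    """
    if len(samples) < 2:
        raise ValueError("standard_normalize needs at least 2 samples")
    counts = [s.n_tags(species) for s in samples]
    floor = min(counts)
    rngs = _spawn_rngs(seed, len(samples))
    out = []
    for lib, count, rng in zip(samples, counts, rngs):
        if count == floor:
            out.append(lib)
        else:
            out.append(lib.replace_tags(species, downsample_tags(
                lib.tags_by_species[species], floor / count, rng)))
    return out


def spike_normalize(
    samples: Sequence[SampleLibrary],
    species: str,
    table: CorrectionTable,
    seed: int = 0,
) -> list[SampleLibrary]:
    """Apply spike-in correction factors to the experimental-species tags.

    Sample i's experimental tags are downsampled by its applied factor;
    reference-species tags are left untouched.
    """
    rngs = _spawn_rngs(seed, len(samples))
    out = []
    for lib, rng in zip(samples, rngs):
        factor = table.factor(lib.sample_id)  # raises KeyError if missing
        out.append(lib.replace_tags(species, downsample_tags(
            lib.tags_by_species[species], factor, rng)))
    return out
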