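"""End-to-end analysis: preprocess, call islands, normalize, quantify.

This ties the stages into the two analysis paths the method contrasts:
*standard* depth normalization (downsample every sample to the smallest
library) versus *spike-in* normalization (downsample by reference-tag
correction factors). Both paths share preprocessing, island calling on the
pre-normalization fragments, and union-region quantification, so the only
difference the comparison sees is the scaling rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .islands import Island, IslandParams, call_islands
from .model import GenomeLayout, SampleLibrary
from .normalize import (
    CorrectionTable,
    ReferenceCountingMode,
    compute_correction_factors,
    count_reference_tags,
    spike_normalize,
    standard_normalize,
)
from .preprocess import PreprocessParams, extend_tags, preprocess_library
from .quantify import RegionSignalMatrix, build_signal_matrix, fold_change_summary, union_regions


@dataclass
class AnalysisResult:
    """Everything one analysis path produces."""

    method: str
    correction: CorrectionTable | None
    islands: dict[str, list[Island]]
    matrix: RegionSignalMatrix
    summary: dict
    preprocess_report: pd.DataFrame
    normalized: list[SampleLibrary] = field(default_factory=list)


def analyze_experiment(
    samples: Sequence[SampleLibrary],
    genomes: Mapping[str, GenomeLayout],
    experimental_species: str,
    reference_species: str,
    reference_sample_id: str,
    counting: ReferenceCountingMode,
    method: str = "spikein",
    preprocess_params: PreprocessParams = PreprocessParams(),
    island_params: IslandParams = IslandParams(),
    seed: int = 0,
    compare: tuple[str, str] | None = None,
) -> AnalysisResult:
    """Run one full analysis path over a set of samples.

    ``compare`` names the (numerator, denominator) samples of the fold-change
    summary; by default the reference (control) sample over the first other
    sample. Island calling and reference-tag counting both run on the
    preprocessed, pre-downsampling libraries; the correction factors therefore
    reflect the libraries as sequenced.
    """
    if method not in ("standard", "spikein"):
        raise ValueError(f"unknown normalization method {method!r}")
    ids = [s.sample_id for s in samples]
    if reference_sample_id not in ids:
        raise ValueError(f"reference sample {reference_sample_id!r} not among samples")

    clean: list[SampleLibrary] = []
    fragments: dict[str, pd.DataFrame] = {}
    reports = []
    for lib in samples:
        flib, frags, report = preprocess_library(lib, genomes, preprocess_params)
        clean.append(flib)
        fragments[lib.sample_id] = frags[experimental_species]
        reports.append(report)
    report = pd.concat(reports, ignore_index=True)

    exp_genome = genomes[experimental_species]
    islands = {
        lib.sample_id: call_islands(fragments[lib.sample_id], exp_genome, island_params)
        for lib in clean
    }

    correction: CorrectionTable | None = None
    if method == "spikein":
        counts = {
            lib.sample_id: count_reference_tags(lib, reference_species, counting)
            for lib in clean
        }
        correction = compute_correction_factors(
            counts, reference_sample_id, counting.mode
        )
        normalized = spike_normalize(clean, experimental_species, correction, seed)
    else:
        normalized = standard_normalize(clean, experimental_species, seed)

    regions = union_regions(islands.values())
    frag_by_sample = {
        lib.sample_id: extend_tags(
            lib.tags_by_species[experimental_species],
            exp_genome,
            preprocess_params.extension_length,
        )
        for lib in normalized
    }
    matrix = build_signal_matrix(regions, frag_by_sample, exp_genome)

    if compare is None:
        others = [i for i in ids if i != reference_sample_id]
        compare = (reference_sample_id, others[0] if others else reference_sample_id)
    summary = fold_change_summary(matrix, *compare)
    return AnalysisResult(method, correction, islands, matrix, summary, report, normalized)
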