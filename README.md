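# chipspike

Spike-in normalization for ChIP-seq with an exogenous reference genome.

## The problem

ChIP-seq libraries are sequenced to a chosen depth, so tag counts carry no
information about the absolute amount of precipitated chromatin. When a
treatment changes a histone mark **globally** — e.g. an EZH2 inhibitor
depleting H3K27me3 genome-wide — every locus scales by the same factor and
standard depth normalization (downsampling all samples to the smallest
library) reproduces near-identical signal: the change is invisible by
construction. This package is for epigenomics analysts who need to detect
and quantify such global occupancy changes.

## The method

A constant mass of reference-species chromatin (Drosophila) is added to every
reaction alongside an antibody against the reference-specific histone variant
H2Av, which precipitates a constant amount of reference chromatin per
reaction. After sequencing, tags are partitioned by species and each sample's
reference-tag count `c_i` yields a correction factor

```
f_i = c_ref / c_i            (reference sample over sample i)
f_i ← f_i / max_j f_j        (rescaled so scaling is pure tag removal)
```

by which sample *i*'s experimental-species tags are randomly downsampled.
Reference tags are counted either over the whole reference genome or
restricted to the pre-defined H2Av-bound intervals; the restricted mode is
robust to cross-reactive pull-down of reference chromatin by the experimental
antibody, which grows as the target is depleted.

Around this core the package provides the standard broad-mark workflow: tag
filters (MAPQ > 25, 5′-position deduplication), 3′ extension to 200 bp and
32-bp binned coverage (bedGraph output), a SICER-style island caller
(random-background mode, E-value threshold via seeded Monte Carlo,
mark-specific gaps: 600 bp for H3K27me3/H3K9me3, 200 bp for H3K4me3),
union-region quantification with scatter/box/fold-change exports, the
spike-in design arithmetic, and a synthetic two-species generator with known
ground truth. See `docs/methods.md` for the model details.

## Worked example

Simulate a desk-scale experiment with a true 4-fold global loss (200 000 tags
per sample, 5% reference spike-in), then analyze it both ways:

```python
from chipspike import (SimulationConfig, simulate_experiment, ReferenceCountingMode,
                       IslandParams, analyze_experiment)

config = SimulationConfig(sequencing_depth=200_000, global_fold_change=4.0, seed=0)
experiment = simulate_experiment(config)
genomes = {"exp": experiment.structure.exp_genome,
           "spike": experiment.structure.ref_genome}
island_params = IslandParams(gap=600, effective_genome_fraction=1.0,
                             null_mc_draws=2000, seed=0)

for method, counting in [
    ("standard", ReferenceCountingMode("whole_genome")),
    ("spikein", ReferenceCountingMode("restricted_regions",
                                      experiment.structure.h2av_regions)),
]:
    result = analyze_experiment(
        experiment.samples, genomes, "exp", "spike", "control", counting,
        method=method, island_params=island_params, seed=0,
    )
    print(f"{method:8s} median control/treated ratio: "
          f"{result.summary['median_ratio']:.2f}  "
          f"({result.summary['n_regions']} regions)")
    if result.correction is not None:
        print(result.correction.to_frame().to_string(index=False))
```

prints

```
standard median control/treated ratio: 1.00  (60 regions)
spikein  median control/treated ratio: 3.66  (60 regions)
sample_id  reference_tag_count  raw_factor  applied_factor      counting_mode
  control                 9611    1.000000        1.000000 restricted_regions
  treated                31054    0.309493        0.309493 restricted_regions
```

Standard depth normalization reports no change (ratio 1.00) despite the true
4-fold loss. The treated sample carries ~3.2× more reference tags — the
constant spike-in occupies more of the fixed sequencing depth when the
experimental target collapses — so its experimental tags are downsampled to
0.31×, and the per-region median ratio recovers ≈3.7 (slightly under 4
because 5′-position deduplication saturates at this toy scale; see
`docs/methods.md`).

The same analysis runs from the shell:

```
chipspike simulate --out fx --seed 0
chipspike quantify --config fx/config.yaml --method spikein --out results_spike
chipspike quantify --config fx/config.yaml --method standard --out results_std
chipspike design --human-mass 30 --spike-mass 0.75 --depth 50000000
```

Other subcommands (`preprocess`, `callpeaks`, `normalize`) expose the
individual stages; every output directory gets a `provenance.json` with the
config hash and seeds.

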