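"""Synthetic two-species ChIP-seq tag libraries with known ground truth.

The generator emulates the statistical structure a spike-in normalization
experiment assumes: broad enriched domains covering a sizable fraction of the
experimental genome, a uniform multiplicative global occupancy change between
control and treated samples, a constant reference (spike-in) pull-down
landing in pre-defined reference regions, optional cross-reactive pull-down
of reference chromatin that grows as the experimental target is depleted,
and — crucially — a final fixed-depth sequencing step that equalizes library
sizes, which is what structurally erases global changes under standard depth
normalization.

Each sample is drawn in two stages: compartment weights (experimental
domains, experimental background, reference pull-down regions, reference
cross-reactive regions) determine a multinomial split of exactly N tags, and
positions are uniform within each compartment. Ground truth (the injected
fold change, domain coordinates, expected and realized compartment
proportions) is stored alongside every dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as cio
from .model import GenomeLayout, RegionSet, SampleLibrary, TAG_COLUMNS

TRUTH_SCHEMA_VERSION = 1

_COMPARTMENTS = ("exp_domains", "exp_background", "ref_h2av", "ref_cross")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated spike-in experiment.

    The defaults describe a desk-scale analogue of a broad-mark (H3K27me3)
    experiment: a 4 Mb experimental genome a quarter of which lies in broad
    enriched domains, a 200 kb reference genome carrying the pull-down
    regions, and 200 000 sequenced tags per sample.
    """

    exp_species: str = "exp"
    ref_species: str = "spike"
    n_exp_chroms: int = 4
    exp_chrom_length: int = 1_000_000
    n_ref_chroms: int = 2
    ref_chrom_length: int = 100_000

    n_domains: int = 60
    domain_width_range: tuple[int, int] = (2_000, 20_000)
    domain_fraction: float = 0.25  # fraction of the experimental genome in domains

    n_h2av_regions: int = 40
    h2av_width_range: tuple[int, int] = (1_000, 3_000)
    n_cross_regions: int = 20
    cross_width_range: tuple[int, int] = (1_000, 3_000)

    enrichment: float = 10.0  # fold over background inside domains
    global_fold_change: float = 4.0  # F: treated signal = control / F, genome-wide
    spike_fraction: float = 0.05  # reference share of the control pull-down
    cross_reactivity: float = 0.0  # κ: cross pull-down / H2Av pull-down at full depletion

    sequencing_depth: int = 200_000  # N tags per sample, fixed
    tag_length: int = 50
    mapq: int = 60
    duplicate_fraction: float = 0.0
    low_mapq_fraction: float = 0.0

    mark: str = "H3K27me3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.global_fold_change < 1:
            raise ValueError("global_fold_change must be >= 1")
        if not (0 < self.spike_fraction < 1):
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.cross_reactivity < 0:
            raise ValueError("cross_reactivity must be >= 0")
        if not (0 < self.domain_fraction < 1):
            raise ValueError("domain_fraction must be in (0, 1)")
        for frac in (self.duplicate_fraction, self.low_mapq_fraction):
            if not (0 <= frac < 1):
                raise ValueError("injection fractions must be in [0, 1)")


@dataclass
class SimStructure:
    """The fixed genomic scaffold shared by both conditions of one config."""

    exp_genome: GenomeLayout
    ref_genome: GenomeLayout
    domains: RegionSet
    background: RegionSet  # experimental genome minus domains
    h2av_regions: RegionSet
    cross_regions: RegionSet


@dataclass
class TruthRecord:
    """Ground truth stored with each simulated sample."""

    condition: str
    fold_change: float
    expected_proportions: dict[str, float]
    realized_counts: dict[str, int]
    seed: int


@dataclass
class SimulatedExperiment:
    """A paired control/treated dataset plus its scaffold and ground truth."""

    config: SimulationConfig
    structure: SimStructure
    control: SampleLibrary
    treated: SampleLibrary
    truth: dict[str, TruthRecord] = field(default_factory=dict)

    @property
    def samples(self) -> list[SampleLibrary]:
        return [self.control, self.treated]

    @property
    def true_factor(self) -> float:
        """The correction factor that exactly undoes the depth masking.

        Equals the expected control/treated ratio of reference-region tag
        counts; applying it to the treated experimental tags restores the
        injected fold change in expectation.
        """
        pc = self.truth["control"].expected_proportions["ref_h2av"]
        pt = self.truth["treated"].expected_proportions["ref_h2av"]
        return pc / pt


def _layout(species: str, n_chroms: int, length: int, prefix: str) -> GenomeLayout:
    return GenomeLayout(species, tuple((f"{prefix}{i + 1}", length) for i in range(n_chroms)))


def _place_intervals(
    rng: np.random.Generator, genome: GenomeLayout, widths: np.ndarray
) -> list[tuple[str, int, int]]:
    """Place intervals of the given widths without overlap, uniformly at random.

    Intervals are assigned to chromosomes proportionally to length (subject to
    capacity) and placed by stick-breaking: sorted random offsets in the free
    space, stacked with the interval widths. Returned in the order of
    ``widths`` so the caller can split one joint placement into disjoint sets.
    """
    names = genome.names
    lengths = genome.lengths
    widths = np.asarray(widths, dtype=np.int64)
    for _attempt in range(200):
        p = np.array([lengths[c] for c in names], dtype=float)
        p /= p.sum()
        chrom_idx = rng.choice(len(names), size=len(widths), p=p)
        placed: list[tuple[str, int, int] | None] = [None] * len(widths)
        ok = True
        for ci, name in enumerate(names):
            which = np.flatnonzero(chrom_idx == ci)
            if not len(which):
                continue
            w = widths[which]
            free = lengths[name] - int(w.sum())
            if free < 0:
                ok = False
                break
            offsets = np.sort(rng.integers(0, free + 1, size=len(w)))
            starts = offsets + np.concatenate(([0], np.cumsum(w[:-1])))
            for j, s, width in zip(which, starts, w):
                placed[j] = (name, int(s), int(s + width))
        if ok:
            return placed  # type: ignore[return-value]
    raise RuntimeError("could not place regions: total width exceeds a chromosome")


def _complement(genome: GenomeLayout, regions: RegionSet) -> RegionSet:
    out = []
    by_chrom = regions.by_chrom()
    for chrom, length in genome.chromosomes:
        prev = 0
        for s, e in by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if s > prev:
                out.append((chrom, prev, int(s)))
            prev = int(e)
        if prev < length:
            out.append((chrom, prev, length))
    return RegionSet(out)


def build_structure(config: SimulationConfig) -> SimStructure:
    """The deterministic (config-seeded) genomic scaffold for one experiment."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    exp_genome = _layout(config.exp_species, config.n_exp_chroms, config.exp_chrom_length, "expChr")
    ref_genome = _layout(config.ref_species, config.n_ref_chroms, config.ref_chrom_length, "refChr")

    lo, hi = config.domain_width_range
    widths = rng.integers(lo, hi + 1, size=config.n_domains).astype(float)
    # rescale so total domain bp hits the configured genome fraction
    target = config.domain_fraction * exp_genome.total_length
    widths = np.maximum(1, np.round(widths * target / widths.sum())).astype(np.int64)
    domains = RegionSet(_place_intervals(rng, exp_genome, widths))

    # place both reference region sets jointly so they come out disjoint
    lo, hi = config.h2av_width_range
    h2av_w = rng.integers(lo, hi + 1, size=config.n_h2av_regions)
    lo, hi = config.cross_width_range
    cross_w = rng.integers(lo, hi + 1, size=config.n_cross_regions)
    placed = _place_intervals(rng, ref_genome, np.concatenate([h2av_w, cross_w]))
    h2av = RegionSet(placed[: config.n_h2av_regions])
    cross = RegionSet(placed[config.n_h2av_regions :])
    return SimStructure(exp_genome, ref_genome, domains, _complement(exp_genome, domains), h2av, cross)


def compartment_weights(
    config: SimulationConfig, structure: SimStructure, condition: str
) -> dict[str, float]:
    """Pre-sequencing pull-down weight of each compartment.

    Control: domains at ``enrichment`` per bp, background at 1 per bp; the
    reference pull-down weight is set so it is ``spike_fraction`` of the
    control pull-down and is identical in both conditions (constant spike-in).
    Treated: the *entire* experimental signal is scaled by 1/F (a uniform
    global change), and cross-reactive reference pull-down grows linearly
    with the depleted target fraction: κ · (1 − 1/F) · (H2Av weight).
    """
    if condition not in ("control", "treated"):
        raise ValueError(f"unknown condition {condition!r}")
    dom_bp = structure.domains.total_bp
    bg_bp = structure.background.total_bp
    e_dom = dom_bp * config.enrichment
    e_bg = float(bg_bp)
    e_total_control = e_dom + e_bg
    r_h2av = config.spike_fraction / (1 - config.spike_fraction) * e_total_control
    g = 1.0 if condition == "control" else 1.0 / config.global_fold_change
    weights = {
        "exp_domains": e_dom * g,
        "exp_background": e_bg * g,
        "ref_h2av": r_h2av,
        "ref_cross": config.cross_reactivity * (1.0 - g) * r_h2av,
    }
    if sum(weights.values()) <= 0:
        raise ValueError("infeasible configuration: all compartment weights zero")
    return weights


def _region_arrays(regions: RegionSet):
    chroms = np.array([c for c, _, _ in regions], dtype=object)
    starts = np.array([s for _, s, _ in regions], dtype=np.int64)
    ends = np.array([e for _, _, e in regions], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(ends - starts)))
    return chroms, starts, cum


def _sample_positions(rng: np.random.Generator, regions: RegionSet, n: int):
    """n positions uniform over the total bp of a region set."""
    chroms, starts, cum = _region_arrays(regions)
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    pos = starts[idx] + (u - cum[idx])
    return chroms[idx], pos


def _tags_from_positions(
    rng: np.random.Generator,
    chroms: np.ndarray,
    pos: np.ndarray,
    genome: GenomeLayout,
    tag_length: int,
    mapq: int,
) -> pd.DataFrame:
    """Build fixed-length tags whose 5' base sits at each sampled position."""
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    minus = rng.random(len(pos)) < 0.5
    start = np.where(minus, np.maximum(0, pos - tag_length + 1), pos)
    end = np.where(minus, pos + 1, np.minimum(lengths, pos + tag_length))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": np.where(minus, "-", "+"),
            "mapq": np.full(len(pos), mapq, dtype=np.int64),
        }
    )


def simulate_sample(
    config: SimulationConfig,
    condition: str,
    seed: int,
    structure: SimStructure | None = None,
) -> tuple[SampleLibrary, TruthRecord]:
    """Draw one sample: exactly N tags, multinomial over compartments."""
    if structure is None:
        structure = build_structure(config)
    weights = compartment_weights(config, structure, condition)
    total_w = sum(weights.values())
    probs = np.array([weights[c] / total_w for c in _COMPARTMENTS])
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(config.sequencing_depth, probs)
    realized = dict(zip(_COMPARTMENTS, (int(c) for c in counts)))

    compartment_regions = {
        "exp_domains": (structure.domains, structure.exp_genome),
        "exp_background": (structure.background, structure.exp_genome),
        "ref_h2av": (structure.h2av_regions, structure.ref_genome),
        "ref_cross": (structure.cross_regions, structure.ref_genome),
    }
    parts: dict[str, list[pd.DataFrame]] = {config.exp_species: [], config.ref_species: []}
    for comp, n in zip(_COMPARTMENTS, counts):
        if n == 0:
            continue
        regions, genome = compartment_regions[comp]
        chroms, pos = _sample_positions(rng, regions, int(n))
        df = _tags_from_positions(rng, chroms, pos, genome, config.tag_length, config.mapq)
        parts[genome.species_label].append(df)

    tags_by_species = {}
    for species, genome in (
        (config.exp_species, structure.exp_genome),
        (config.ref_species, structure.ref_genome),
    ):
        if parts[species]:
            df = pd.concat(parts[species], ignore_index=True)
        else:
            df = pd.DataFrame(columns=list(TAG_COLUMNS))
        tags_by_species[species] = _inject_noise(rng, df, config)

    lib = SampleLibrary(f"{condition}", condition, config.mark, tags_by_species)
    truth = TruthRecord(
        condition=condition,
        fold_change=config.global_fold_change,
        expected_proportions={c: weights[c] / total_w for c in _COMPARTMENTS},
        realized_counts=realized,
        seed=seed,
    )
    return lib, truth


def _inject_noise(
    rng: np.random.Generator, tags: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Optionally replace tags with PCR duplicates and degrade some MAPQs."""
    n = len(tags)
    if n == 0:
        return tags.reset_index(drop=True)
    tags = tags.reset_index(drop=True)
    if config.duplicate_fraction > 0:
        k = round(config.duplicate_fraction * n)
        if k:
            victims = rng.choice(n, size=k, replace=False)
            donors = rng.choice(n, size=k, replace=True)
            for col in tags.columns:
                vals = tags[col].to_numpy()
                vals[victims] = vals[donors]
                tags[col] = vals
    if config.low_mapq_fraction > 0:
        k = round(config.low_mapq_fraction * n)
        if k:
            rows = rng.choice(n, size=k, replace=False)
            tags.loc[rows, "mapq"] = rng.integers(0, 26, size=k)
    return tags


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedExperiment:
    """Paired control/treated libraries from one config, with linked seeds."""
    if seed is None:
        seed = config.seed
    structure = build_structure(config)
    ss = np.random.SeedSequence(seed).spawn(2)
    control, t_ctrl = simulate_sample(
        config, "control", int(ss[0].generate_state(1)[0] % (2**31)), structure
    )
    treated, t_trt = simulate_sample(
        config, "treated", int(ss[1].generate_state(1)[0] % (2**31)), structure
    )
    return SimulatedExperiment(
        config, structure, control, treated, {"control": t_ctrl, "treated": t_trt}
    )


def write_fixture(experiment: SimulatedExperiment, directory) -> dict[str, str]:
    """Write a complete, self-contained pipeline input directory.

    Emits per-sample per-species BED6 tag files, chrom.sizes for both
    species, the reference pull-down region BED, a versioned truth JSON and a
    ready-to-run pipeline config. Byte-identical when regenerated with the
    same config and seed.
    """
    import os

    cio.ensure_dir(directory)
    cfg = experiment.config
    paths: dict[str, str] = {}

    for lib in experiment.samples:
        for species, tags in lib.tags_by_species.items():
            p = os.path.join(directory, f"tags_{lib.sample_id}_{species}.bed")
            cio.write_tags(tags, p)
            paths[f"tags_{lib.sample_id}_{species}"] = p
    for key, genome in (("exp", experiment.structure.exp_genome),
                        ("ref", experiment.structure.ref_genome)):
        p = os.path.join(directory, f"{genome.species_label}.chrom.sizes")
        cio.write_chrom_sizes(genome, p)
        paths[f"{key}_chrom_sizes"] = p
    p = os.path.join(directory, "h2av_regions.bed")
    cio.write_regions(experiment.structure.h2av_regions, p)
    paths["h2av_regions"] = p
    p = os.path.join(directory, "cross_regions.bed")
    cio.write_regions(experiment.structure.cross_regions, p)
    paths["cross_regions"] = p

    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "fold_change": cfg.global_fold_change,
        "spike_fraction": cfg.spike_fraction,
        "cross_reactivity": cfg.cross_reactivity,
        "true_factor": experiment.true_factor,
        "domains": [list(iv) for iv in experiment.structure.domains],
        "samples": {c: asdict(t) for c, t in experiment.truth.items()},
    }
    p = os.path.join(directory, "truth.json")
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = p

    run_config = {
        "samples": [
            {
                "id": lib.sample_id,
                "treatment": lib.treatment,
                "mark": lib.mark,
                "tags": {
                    sp: f"tags_{lib.sample_id}_{sp}.bed" for sp in lib.tags_by_species
                },
            }
            for lib in experiment.samples
        ],
        "reference_sample": "control",
        "experimental_species": cfg.exp_species,
        "reference_species": cfg.ref_species,
        "genomes": {
            cfg.exp_species: f"{cfg.exp_species}.chrom.sizes",
            cfg.ref_species: f"{cfg.ref_species}.chrom.sizes",
        },
        "counting": {"mode": "restricted_regions", "regions": "h2av_regions.bed"},
        "marks": {cfg.mark: {"gap": 600}},
        "islands": {
            "window_width": 200,
            "e_value": 1.0,
            "effective_genome_fraction": 1.0,
            "null_mc_draws": 2000,
        },
        "preprocess": {"min_mapq": 25, "extension_length": 200, "bin_width": 32},
        "seed": cfg.seed,
    }
    import yaml

    p = os.path.join(directory, "config.yaml")
    with open(p, "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    paths["config"] = p
    return paths
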