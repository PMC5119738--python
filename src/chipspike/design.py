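"""Spike-in experimental-design arithmetic.

Helpers for choosing how much reference-species chromatin to add to each
ChIP reaction and what reference tag yield to expect at a planned sequencing
depth. The genome copy-number ratio between the experimental and reference
species (27 for human vs Drosophila euchromatin) converts chromatin mass to
genome copies: equal copy numbers need a mass ratio equal to the genome-size
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

#: human : Drosophila genome-size ratio used to equalize genome copy number.
DEFAULT_GENOME_COPY_RATIO = 27.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class DesignParams:
    """Inputs to a spike-in design report."""

    human_chromatin_mass: float  # µg of experimental chromatin per reaction
    spike_chromatin_mass: float  # µg of reference chromatin per reaction
    genome_copy_ratio: float = DEFAULT_GENOME_COPY_RATIO
    planned_total_tags: float = 50e6

    def __post_init__(self) -> None:
        _require_positive(
            human_chromatin_mass=self.human_chromatin_mass,
            spike_chromatin_mass=self.spike_chromatin_mass,
            genome_copy_ratio=self.genome_copy_ratio,
            planned_total_tags=self.planned_total_tags,
        )


def spike_mass_for_copy_equality(
    human_mass: float, genome_copy_ratio: float = DEFAULT_GENOME_COPY_RATIO
) -> float:
    """Reference chromatin mass (µg) giving equal genome copy number.

    With the reference genome ``genome_copy_ratio`` times smaller, copy-number
    equality needs mass ratio = genome_copy_ratio, i.e. mass / ratio.
    """
    _require_positive(human_mass=human_mass, genome_copy_ratio=genome_copy_ratio)
    return human_mass / genome_copy_ratio


def expected_reference_tags(
    total_tags: float, spike_mass: float, human_mass: float
) -> float:
    """Expected reference-species tag yield at a planned total depth.

    Assuming the antibodies precipitate the same amount of chromatin per unit
    input, the reference yield scales with the spike-to-experimental mass
    ratio: total_tags × spike_mass / human_mass.
    """
    _require_positive(total_tags=total_tags, spike_mass=spike_mass, human_mass=human_mass)
    return total_tags * spike_mass / human_mass


def mass_ratio(human_mass: float, spike_mass: float) -> float:
    """Experimental-to-reference chromatin mass ratio (the 'X : 1' figure)."""
    _require_positive(human_mass=human_mass, spike_mass=spike_mass)
    return human_mass / spike_mass


def design_report(params: DesignParams) -> dict:
    """All design quantities for one spike-in plan, as a flat dict."""
    return {
        "human_chromatin_mass_ug": params.human_chromatin_mass,
        "spike_chromatin_mass_ug": params.spike_chromatin_mass,
        "genome_copy_ratio": params.genome_copy_ratio,
        "planned_total_tags": params.planned_total_tags,
        "copy_equality_spike_mass_ug": spike_mass_for_copy_equality(
            params.human_chromatin_mass, params.genome_copy_ratio
        ),
        "mass_ratio": mass_ratio(params.human_chromatin_mass, params.spike_chromatin_mass),
        "expected_reference_tags": expected_reference_tags(
            params.planned_total_tags, params.spike_chromatin_mass, params.human_chromatin_mass
        ),
    }
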