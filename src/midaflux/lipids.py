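"""Fractional de novo lipogenesis (DNL) from lipid isotopomer envelopes.

Fatty-acid synthesis is a polymerization drawing hydrogen from body water,
so a newly made palmitate molecule carries deuterium on an effective number
of H positions set by the biosynthetic chemistry (default 22 of the 32
hydrogens, the field-standard effective value for palmitate).  The same
combinatorial envelope model and EM0/EM0max mixture arithmetic used for
peptides then gives the fraction of the palmitate pool made de novo during
the labeling period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ElementalComposition
from .mida import (
    IsotopeEnvelope,
    LabelingContext,
    PeptideKinetics,
    baseline_and_asymptote,
    em0_excess_and_max,
    fractional_synthesis,
    truncate_and_renormalize,
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid analyte: elemental composition plus effective 2H sites."""

    name: str
    composition: ElementalComposition
    n_sites: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_sites <= self.composition.H:
            raise ValueError(
                f"n_sites={self.n_sites} outside [0, {self.composition.H}] for {self.name}"
            )


PALMITATE = LipidSpecies(
    name="palmitate",
    composition=ElementalComposition(C=16, H=32, O=2),
    n_sites=22.0,
)


def dnl_fraction(
    measured: IsotopeEnvelope,
    context: LabelingContext,
    species: LipidSpecies = PALMITATE,
    k_max: int = 3,
) -> PeptideKinetics:
    """Fractional contribution of de novo synthesis to the lipid pool.

    The measured envelope is compared against the theoretical unlabeled
    baseline and the fully newly synthesized asymptote at the measured body
    water enrichment; f_DNL = EM0/EM0max with the usual mixture contract.
    """
    baseline, asymptote = baseline_and_asymptote(
        species.composition, species.n_sites, context, k_max
    )
    measured = truncate_and_renormalize(measured, k_max)
    em0, em0_max = em0_excess_and_max(measured, baseline, asymptote)
    return fractional_synthesis(em0, em0_max)
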