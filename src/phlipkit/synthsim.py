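"""Synthetic data emulating the study's two experimental inputs.

Two generators, both pure functions of their spec (seed included):

* :func:`generate_family` — an aligned peptide family around a template
  with a controlled per-position conservation probability, standing in for
  the membrane-insertion segments of the pHLIP variants behind the
  consensus design step.
* :func:`generate_biodist` — a raw gamma-counter biodistribution dataset
  whose analyzed %ID/g values are log-normally distributed around
  specified organ/timepoint means, standing in for the sacrificed-animal
  measurements. Counts are back-computed so that the full decay-correct +
  %ID/g pipeline recovers the specified distribution.

Log-normal noise is used for %ID/g because the quantity is strictly
positive and published SD/mean ratios are ~0.2; organ weights are drawn
from plausible murine ranges and are a documented fixture of the
generator, not a measured fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import AlignedFamily
from .radiometrics import (
    GA68_HALF_LIFE_MIN,
    BiodistTable,
    DoseReference,
    OrganMeasurement,
)
from .seqcore import AMINO_ACIDS, Peptide

__all__ = [
    "FamilySpec",
    "BiodistSpec",
    "DEFAULT_ORGAN_MEANS",
    "DEFAULT_ORGAN_CV",
    "ORGAN_WEIGHT_RANGES_G",
    "generate_family",
    "generate_biodist",
]


@dataclass(frozen=True)
class FamilySpec:
    """Family generator settings.

    Each member copies the template residue with probability
    ``conservation`` per position, otherwise one of the 19 alternative
    residues uniformly at random.
    """

    template: Peptide
    conservation: float = 0.8
    n_members: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")


def generate_family(spec: FamilySpec) -> AlignedFamily:
    """Draw a deterministic aligned family around the template."""
    rng = np.random.default_rng(spec.seed)
    template = spec.template.sequence
    L = len(template)
    members = []
    for i in range(spec.n_members):
        keep = rng.random(L) < spec.conservation
        residues = list(template)
        for pos in np.nonzero(~keep)[0]:
            alternatives = [a for a in AMINO_ACIDS if a != template[pos]]
            residues[pos] = alternatives[rng.integers(len(alternatives))]
        members.append(Peptide(id=f"synth{i:04d}", sequence="".join(residues)))
    return AlignedFamily(
        members=tuple(members),
        alignment_note=(
            f"synthetic family: template={spec.template.id} "
            f"conservation={spec.conservation} seed={spec.seed}"
        ),
    )


#: Organ x timepoint (min) mean %ID/g defaults for the tracer cohort:
#: tumor, liver and blood at 1, 2 and 4 h post injection.
DEFAULT_ORGAN_MEANS: Mapping[tuple[str, float], float] = {
    ("tumor", 60.0): 5.94,
    ("tumor", 120.0): 6.72,
    ("tumor", 240.0): 4.54,
    ("liver", 60.0): 20.49,
    ("liver", 120.0): 14.46,
    ("liver", 240.0): 10.22,
    ("blood", 60.0): 19.61,
    ("blood", 120.0): 8.23,
    ("blood", 240.0): 3.38,
}

#: Per-organ coefficient of variation (SD/mean at the 1 h timepoint).
DEFAULT_ORGAN_CV: Mapping[str, float] = {
    "tumor": 0.21,
    "liver": 0.18,
    "blood": 0.20,
}

#: Plausible murine sample weights (g); a generator fixture, not data.
ORGAN_WEIGHT_RANGES_G: Mapping[str, tuple[float, float]] = {
    "tumor": (0.2, 0.8),
    "liver": (0.8, 1.4),
    "blood": (0.1, 0.5),
}
_DEFAULT_WEIGHT_RANGE = (0.1, 1.0)


@dataclass(frozen=True)
class BiodistSpec:
    """Biodistribution generator settings.

    ``organ_means`` maps ``(organ, timepoint_min)`` to the target mean
    %ID/g; ``organ_cv`` gives each organ's coefficient of variation.
    """

    organ_means: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MEANS)
    )
    organ_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_CV)
    )
    n_animals: int = 3
    dose_counts: float = 1_000_000.0
    half_life: float = GA68_HALF_LIFE_MIN
    group: str = "tracer"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.organ_means:
            raise ValueError("organ_means must not be empty")
        for key, mean in self.organ_means.items():
            if mean <= 0:
                raise ValueError(f"organ mean must be > 0 ({key}: {mean})")
        for organ, cv in self.organ_cv.items():
            if cv <= 0:
                raise ValueError(f"CV must be > 0 ({organ}: {cv})")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.dose_counts <= 0:
            raise ValueError("dose_counts must be > 0")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_biodist(spec: BiodistSpec) -> BiodistTable:
    """Draw a deterministic raw-counts biodistribution dataset.

    For each organ x timepoint, ``n_animals`` true %ID/g values are drawn
    log-normally with the specified mean and CV; measured counts are then
    back-computed through the physical decay so that decay-corrected
    analysis recovers exactly those values.
    """
    rng = np.random.default_rng(spec.seed)
    dose = DoseReference(
        injected_counts_equivalent=spec.dose_counts,
        calibration_note=f"synthetic standard, seed={spec.seed}",
    )
    measurements = []
    for (organ, timepoint), mean in sorted(spec.organ_means.items()):
        cv = spec.organ_cv.get(organ, 0.2)
        mu, sigma = _lognormal_params(mean, cv)
        lo, hi = ORGAN_WEIGHT_RANGES_G.get(organ, _DEFAULT_WEIGHT_RANGE)
        for animal in range(spec.n_animals):
            pid_g = float(rng.lognormal(mu, sigma))
            weight = float(rng.uniform(lo, hi))
            # invert the analysis pipeline: counts measured at sacrifice
            counts_at_injection = pid_g / 100.0 * spec.dose_counts * weight
            counts = counts_at_injection / 2.0 ** (timepoint / spec.half_life)
            measurements.append(
                OrganMeasurement(
                    animal_id=f"{spec.group}-t{int(timepoint)}-{animal:03d}",
                    organ=organ,
                    counts=counts,
                    weight=weight,
                    time_post_injection=timepoint,
                    group=spec.group,
                )
            )
    return BiodistTable(
        measurements=tuple(measurements),
        dose=dose,
        isotope_half_life=spec.half_life,
    )
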