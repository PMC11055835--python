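"""Quantification of gamma-counter radiotracer experiments.

Covers the bookkeeping around a biodistribution study of a Ga-68 labeled
peptide: physical decay correction back to injection time, percent
injected dose per gram of tissue (%ID/g), per-organ/per-timepoint cohort
summaries (mean +/- sample SD), group comparison with Levene's test and
one-way ANOVA, serum protein-bound fraction from an acetonitrile crash,
and radiochemical yield/purity arithmetic.

Whether published %ID/g tables are decay-corrected is often unstated;
:func:`tidy_percent_id` therefore emits both a corrected and an
uncorrected column, explicitly labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GA68_HALF_LIFE_MIN",
    "OrganMeasurement",
    "DoseReference",
    "BiodistTable",
    "decay_correct",
    "percent_id_per_gram",
    "tidy_percent_id",
    "cohort_summary",
    "compare_groups",
    "bound_fraction",
    "radiochemical_accounting",
    "read_measurements_csv",
]

#: Physical half-life of Ga-68 in minutes.
GA68_HALF_LIFE_MIN: float = 67.71

#: Required columns of the tidy measurements CSV.
CSV_COLUMNS = ("animal_id", "group", "timepoint_min", "organ", "counts_cpm", "weight_g")


class RadiometricsError(ValueError):
    pass


@dataclass(frozen=True)
class OrganMeasurement:
    """One organ from one animal on the gamma counter."""

    animal_id: str
    organ: str
    counts: float  # counts per minute at measurement time
    weight: float  # grams
    time_post_injection: float  # minutes
    group: str = ""

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise RadiometricsError(f"negative counts for {self.animal_id}/{self.organ}")
        if self.weight <= 0:
            raise RadiometricsError(f"non-positive weight for {self.animal_id}/{self.organ}")
        if self.time_post_injection < 0:
            raise RadiometricsError("negative time post injection")


@dataclass(frozen=True)
class DoseReference:
    """Counts-equivalent standard representing 100% of the injected dose.

    In practice an aliquot of the injectate counted on the same gamma
    counter at injection time; its preparation is the user's calibration.
    """

    injected_counts_equivalent: float
    calibration_note: str = ""

    def __post_init__(self) -> None:
        if self.injected_counts_equivalent <= 0:
            raise RadiometricsError("dose reference counts must be > 0")


@dataclass(frozen=True)
class BiodistTable:
    """A cohort's measurements plus its dose reference and isotope."""

    measurements: tuple[OrganMeasurement, ...]
    dose: DoseReference
    isotope_half_life: float = GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.isotope_half_life <= 0:
            raise RadiometricsError("half-life must be > 0")
        object.__setattr__(self, "measurements", tuple(self.measurements))


def decay_correct(counts: float, elapsed: float, half_life: float) -> float:
    """Reference measured counts back in time: ``counts * 2**(elapsed/half_life)``."""
    if half_life <= 0:
        raise RadiometricsError("half-life must be > 0")
    if elapsed < 0:
        raise RadiometricsError("elapsed time must be >= 0")
    return counts * 2.0 ** (elapsed / half_life)


def percent_id_per_gram(
    m: OrganMeasurement,
    dose: DoseReference,
    half_life: float = GA68_HALF_LIFE_MIN,
    correct_decay: bool = True,
) -> float:
    """Percent of the injected dose per gram of tissue.

    ``100 * counts_at_injection_time / dose_counts / weight_g`` where the
    organ counts are decay-corrected from sacrifice back to injection time
    (set ``correct_decay=False`` for the uncorrected column).
    """
    counts = m.counts
    if correct_decay:
        counts = decay_correct(counts, m.time_post_injection, half_life)
    return 100.0 * counts / dose.injected_counts_equivalent / m.weight


def tidy_percent_id(table: BiodistTable) -> pd.DataFrame:
    """Tidy per-measurement %ID/g table (one row per organ per animal).

    Columns include both ``pid_g_corrected`` (decay-corrected to injection
    time) and ``pid_g_uncorrected``.
    """
    rows = []
    for m in table.measurements:
        rows.append(
            {
                "animal_id": m.animal_id,
                "group": m.group,
                "timepoint_min": m.time_post_injection,
                "organ": m.organ,
                "counts_cpm": m.counts,
                "weight_g": m.weight,
                "pid_g_corrected": percent_id_per_gram(
                    m, table.dose, table.isotope_half_life, correct_decay=True
                ),
                "pid_g_uncorrected": percent_id_per_gram(
                    m, table.dose, table.isotope_half_life, correct_decay=False
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=list(CSV_COLUMNS) + ["pid_g_corrected", "pid_g_uncorrected"],
    )


def cohort_summary(
    table: BiodistTable, value: str = "pid_g_corrected"
) -> pd.DataFrame:
    """Mean +/- sample SD per organ x timepoint (ddof=1; SD is NaN at n=1)."""
    tidy = tidy_percent_id(table)
    grouped = (
        tidy.groupby(["organ", "timepoint_min"])[value]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return grouped


def compare_groups(*groups: Sequence[float]) -> tuple[float, float, float]:
    """Levene's test (center=mean) and one-way ANOVA across >= 2 groups.

    Returns ``(levene_p, anova_F, anova_p)``. Raises if any group has fewer
    than 2 values or all values are identical (zero variance).
    """
    if len(groups) < 2:
        raise RadiometricsError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise RadiometricsError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise RadiometricsError("zero variance: all values identical")
    levene_stat, levene_p = stats.levene(*arrays, center="mean")
    anova_f, anova_p = stats.f_oneway(*arrays)
    return float(levene_p), float(anova_f), float(anova_p)


def bound_fraction(supernatant_counts: float, sediment_counts: float) -> float:
    """Serum-protein-bound percentage after an acetonitrile crash.

    Protein-bound activity precipitates with the pellet, so the bound
    fraction is ``100 * sediment / (sediment + supernatant)``.
    """
    if supernatant_counts < 0 or sediment_counts < 0:
        raise RadiometricsError("counts must be >= 0")
    total = supernatant_counts + sediment_counts
    if total == 0:
        raise RadiometricsError("no activity in either fraction")
    return 100.0 * sediment_counts / total


def radiochemical_accounting(
    product_activity: float,
    total_activity: float,
    main_peak_area: float,
    total_peak_area: float,
) -> tuple[float, float]:
    """Radiochemical yield and purity percentages.

    Yield = 100 * purified product activity / starting activity;
    purity = 100 * main radio-HPLC peak area / total peak area.
    """
    if total_activity <= 0 or total_peak_area <= 0:
        raise RadiometricsError("denominators must be > 0")
    return (
        100.0 * product_activity / total_activity,
        100.0 * main_peak_area / total_peak_area,
    )


def read_measurements_csv(
    path, dose: DoseReference, half_life: float = GA68_HALF_LIFE_MIN
) -> BiodistTable:
    """Read the tidy measurements CSV schema into a :class:`BiodistTable`.

    Required columns: animal_id, group, timepoint_min, organ, counts_cpm,
    weight_g. Missing columns raise with the offending names.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RadiometricsError(f"measurements CSV missing column(s): {missing}")
    measurements = tuple(
        OrganMeasurement(
            animal_id=str(r.animal_id),
            organ=str(r.organ),
            counts=float(r.counts_cpm),
            weight=float(r.weight_g),
            time_post_injection=float(r.timepoint_min),
            group=str(r.group),
        )
        for r in df.itertuples()
    )
    return BiodistTable(measurements=measurements, dose=dose, isotope_half_life=half_life)
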